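"""Contracted Gaussian basis sets.

Standard published exponents/contraction coefficients for the small bases the
backend supports (STO-3G and 6-31G, elements H/C/N/O).  Cartesian p shells;
angular momenta above p are not used by these sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry

# element -> list of (angular momentum, exponents, coefficients)
_STO3G_SP_S = [-0.09996723, 0.39951283, 0.70011547]
_STO3G_SP_P = [0.15591627, 0.60768372, 0.39195739]
_STO3G_1S = [0.15432897, 0.53532814, 0.44463454]

BASIS_SETS: dict[str, dict[str, list[tuple[int, list[float], list[float]]]]] = {
    "sto-3g": {
        "H": [(0, [3.42525091, 0.62391373, 0.16885540], _STO3G_1S)],
        "C": [
            (0, [71.6168370, 13.0450960, 3.5305122], _STO3G_1S),
            (0, [2.9412494, 0.6834831, 0.2222899], _STO3G_SP_S),
            (1, [2.9412494, 0.6834831, 0.2222899], _STO3G_SP_P),
        ],
        "N": [
            (0, [99.1061690, 18.0523120, 4.8856602], _STO3G_1S),
            (0, [3.7804559, 0.8784966, 0.2857144], _STO3G_SP_S),
            (1, [3.7804559, 0.8784966, 0.2857144], _STO3G_SP_P),
        ],
        "O": [
            (0, [130.7093200, 23.8088610, 6.4436083], _STO3G_1S),
            (0, [5.0331513, 1.1695961, 0.3803890], _STO3G_SP_S),
            (1, [5.0331513, 1.1695961, 0.3803890], _STO3G_SP_P),
        ],
    },
    "6-31g": {
        "H": [
            (0, [18.7311370, 2.8253937, 0.6401217],
             [0.03349460, 0.23472695, 0.81375733]),
            (0, [0.1612778], [1.0]),
        ],
        "C": [
            (0, [3047.5249, 457.36951, 103.94869, 29.210155, 9.2866630,
                 3.1639270],
             [0.0018347, 0.0140373, 0.0688426, 0.2321844, 0.4679413,
              0.3623120]),
            (0, [7.8682724, 1.8812885, 0.5442493],
             [-0.1193324, -0.1608542, 1.1434564]),
            (1, [7.8682724, 1.8812885, 0.5442493],
             [0.0689991, 0.3164240, 0.7443083]),
            (0, [0.1687144], [1.0]),
            (1, [0.1687144], [1.0]),
        ],
        "N": [
            (0, [4173.5110, 627.45790, 142.90210, 40.234330, 13.032690,
                 4.6032470],
             [0.0018348, 0.0139950, 0.0685870, 0.2322410, 0.4690700,
              0.3604550]),
            (0, [11.626358, 2.7162800, 0.7722180],
             [-0.1149610, -0.1691180, 1.1458520]),
            (1, [11.626358, 2.7162800, 0.7722180],
             [0.0675800, 0.3239070, 0.7408950]),
            (0, [0.2120313], [1.0]),
            (1, [0.2120313], [1.0]),
        ],
        "O": [
            (0, [5484.6717, 825.23495, 188.04696, 52.964500, 16.897570,
                 5.7996353],
             [0.0018311, 0.0139501, 0.0684451, 0.2327143, 0.4701930,
              0.3585209]),
            (0, [15.539616, 3.5999336, 1.0137618],
             [-0.1107775, -0.1480263, 1.1307670]),
            (1, [15.539616, 3.5999336, 1.0137618],
             [0.0708743, 0.3397528, 0.7271586]),
            (0, [0.2700058], [1.0]),
            (1, [0.2700058], [1.0]),
        ],
    },
}

# Cartesian component exponents per angular momentum (x, y, z powers).
ANGULAR_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
}


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, lmn: tuple[int, int, int]) -> float:
    """Normalization constant of a Cartesian Gaussian primitive."""
    l, m, n = lmn
    L = l + m + n
    num = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (L / 2.0)
    den = np.sqrt(_double_factorial(2 * l - 1) * _double_factorial(2 * m - 1)
                  * _double_factorial(2 * n - 1))
    return num / den


@dataclass(frozen=True)
class Shell:
    """One contracted shell on one center."""

    l: int
    center: np.ndarray        # Bohr
    exponents: np.ndarray
    coefficients: np.ndarray  # contraction coefficients incl. primitive norms
    atom_index: int

    @property
    def n_functions(self) -> int:
        return len(ANGULAR_COMPONENTS[self.l])


class BasisSet:
    """All shells for a molecule, with AO bookkeeping.

    AO ordering: atoms in input order; per atom, shells in basis-definition
    order; per p shell, components x, y, z.
    """

    def __init__(self, geometry: Geometry, name: str):
        key = name.lower()
        if key not in BASIS_SETS:
            raise KeyError(
                f"unknown basis {name!r}; available: {sorted(BASIS_SETS)}")
        table = BASIS_SETS[key]
        self.name = key
        self.geometry = geometry
        self.shells: list[Shell] = []
        coords = geometry.coords_bohr()
        for ia, elem in enumerate(geometry.atoms):
            if elem not in table:
                raise KeyError(f"basis {name!r} has no element {elem}")
            for (l, exps, coefs) in table[elem]:
                if l not in ANGULAR_COMPONENTS:
                    raise NotImplementedError("only s and p shells supported")
                exps_a = np.asarray(exps, float)
                # fold primitive norms into coefficients, then normalize the
                # contracted function (norm is component-independent within
                # a shell for pure s/p)
                lmn0 = ANGULAR_COMPONENTS[l][0]
                c = np.asarray(coefs, float) * np.array(
                    [primitive_norm(a, lmn0) for a in exps_a])
                # contracted self-overlap for normalization
                s = 0.0
                for ci, ai in zip(c, exps_a):
                    for cj, aj in zip(c, exps_a):
                        s += ci * cj * _prim_self_overlap(ai, aj, lmn0)
                c = c / np.sqrt(s)
                self.shells.append(Shell(l, coords[ia], exps_a, c, ia))
        self.ao_offsets = np.cumsum(
            [0] + [sh.n_functions for sh in self.shells])
        self.n_ao = int(self.ao_offsets[-1])

    def ao_atom_indices(self) -> np.ndarray:
        """Atom index owning each AO (for Mulliken populations)."""
        out = np.empty(self.n_ao, dtype=int)
        for k, sh in enumerate(self.shells):
            out[self.ao_offsets[k]:self.ao_offsets[k + 1]] = sh.atom_index
        return out


def _prim_self_overlap(a: float, b: float, lmn: tuple[int, int, int]) -> float:
    """<g_a|g_b> for two primitives with the same center and angular part."""
    l, m, n = lmn
    p = a + b
    pref = (np.pi / p) ** 1.5
    val = pref
    for k in (l, m, n):
        val *= _double_factorial(2 * k - 1) / (2.0 * p) ** k
    return val
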