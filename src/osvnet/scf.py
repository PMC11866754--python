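"""Mean-field backend interface: restricted Hartree–Fock and Pipek–Mezey
localization of the correlated occupied orbitals.

The backend contract is narrow — :func:`run_mean_field` returns a fully
populated :class:`ScfContext` holding orbitals, Fock/overlap matrices and an
MO-integral provider; everything downstream (OSV features, MP2 labels) touches
only that container, so an alternative electronic-structure engine can be
swapped in by producing the same object.  All energies are in Hartree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg

from .basis import BasisSet
from .geometry import CORE_ORBITALS, Geometry
from .integrals import eri_tensor, one_electron_integrals


class ScfError(RuntimeError):
    pass


@dataclass
class ScfContext:
    """Converged closed-shell mean-field quantities for one molecule."""

    geometry: Geometry
    basis_name: str
    n_occ: int                      # correlated occupied orbitals
    n_virt: int
    frozen_core: int
    mo_coeff_occ: np.ndarray        # (n_ao, n_occ), canonical, core excluded
    mo_coeff_virt: np.ndarray       # (n_ao, n_virt)
    eps_occ: np.ndarray             # canonical ε_i of correlated occupieds
    eps_virt: np.ndarray            # canonical ε_a
    fock_ao: np.ndarray
    overlap_ao: np.ndarray
    e_hf: float
    eri_provider: Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
                           np.ndarray]
    ao_atom_indices: np.ndarray

    def eri_ovov(self, c_occ: np.ndarray | None = None) -> np.ndarray:
        """MO integrals (ia|jb) for occupieds `c_occ` (default: canonical)."""
        co = self.mo_coeff_occ if c_occ is None else c_occ
        return self.eri_provider(co, self.mo_coeff_virt, co,
                                 self.mo_coeff_virt)


@dataclass
class LocalizedOrbitals:
    """Pipek–Mezey localized correlated occupied orbitals."""

    c_lmo: np.ndarray       # (n_ao, n_occ)
    fock_lmo: np.ndarray    # occupied Fock block in the LMO basis
    metric: float           # PM functional value Σ_i Σ_A Q_A(i)^2

    @property
    def f_diag(self) -> np.ndarray:
        return np.diag(self.fock_lmo)


def run_mean_field(geometry: Geometry, basis_name: str,
                   conv_tol: float = 1e-10, max_cycles: int = 200,
                   frozen_core: bool | int = True) -> ScfContext:
    """Converge RHF and package all quantities the featurizer needs.

    `frozen_core=True` freezes the standard chemical core (1s on C/N/O);
    an integer freezes exactly that many lowest canonical occupieds.
    """
    if geometry.spin_multiplicity != 1:
        raise ScfError("only closed-shell singlets are supported")
    if geometry.n_electrons % 2:
        raise ScfError(f"odd electron count ({geometry.n_electrons})")
    if geometry.min_interatomic_distance() < 1e-3:
        raise ScfError("overlapping atoms (distance ~ 0)")

    basis = BasisSet(geometry, basis_name)
    S, T, V = one_electron_integrals(basis)
    eri = eri_tensor(basis)
    hcore = T + V
    n_elec = geometry.n_electrons
    nocc_total = n_elec // 2
    n_ao = basis.n_ao
    if nocc_total > n_ao:
        raise ScfError("basis too small for electron count")

    # symmetric orthogonalization (S is positive definite for sane geometries)
    s_eval, s_evec = np.linalg.eigh(S)
    if s_eval.min() < 1e-8:
        raise ScfError("near-singular AO overlap; check geometry/basis")
    X = s_evec @ np.diag(s_eval ** -0.5) @ s_evec.T

    def fock_matrix(P):
        J = np.einsum("mnls,ls->mn", eri, P, optimize=True)
        K = np.einsum("mlns,ls->mn", eri, P, optimize=True)
        return hcore + J - 0.5 * K

    def density(F):
        e, c = np.linalg.eigh(X.T @ F @ X)
        C = X @ c
        Cocc = C[:, :nocc_total]
        return 2.0 * Cocc @ Cocc.T, e, C

    P, _, _ = density(hcore)
    e_old = 0.0
    diis_f: list[np.ndarray] = []
    diis_r: list[np.ndarray] = []
    converged = False
    for _ in range(max_cycles):
        F = fock_matrix(P)
        # DIIS on the orthonormal-basis error matrix
        err = X.T @ (F @ P @ S - S @ P @ F) @ X
        diis_f.append(F)
        diis_r.append(err)
        if len(diis_f) > 8:
            diis_f.pop(0)
            diis_r.pop(0)
        if len(diis_f) > 1:
            m = len(diis_f)
            Bm = -np.ones((m + 1, m + 1))
            Bm[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    Bm[i, j] = np.vdot(diis_r[i], diis_r[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                w = np.linalg.solve(Bm, rhs)[:m]
                F = sum(wi * fi for wi, fi in zip(w, diis_f))
            except np.linalg.LinAlgError:
                pass
        P_new, mo_energy, C = density(F)
        e_elec = 0.5 * np.sum(P_new * (hcore + fock_matrix(P_new)))
        e_tot = e_elec + geometry.nuclear_repulsion()
        dP = np.max(np.abs(P_new - P))
        P = P_new
        if abs(e_tot - e_old) < conv_tol and dP < np.sqrt(conv_tol):
            converged = True
            break
        e_old = e_tot
    if not converged:
        raise ScfError(
            f"SCF failed to converge for {geometry.atoms} in {basis_name} "
            f"after {max_cycles} cycles")

    # final consistent eigenpair: fock_ao is rebuilt from the converged
    # density and the exported orbitals/energies diagonalize exactly that
    # matrix (keeps rotation-invariance checks at machine precision)
    F = fock_matrix(P)
    _, mo_energy, C = density(F)
    if frozen_core is True:
        ncore = sum(CORE_ORBITALS[a] for a in geometry.atoms)
    else:
        ncore = int(frozen_core)
    if ncore >= nocc_total:
        raise ScfError("frozen core removes all occupied orbitals")
    n_occ = nocc_total - ncore
    n_virt = n_ao - nocc_total

    def eri_provider(c1, c2, c3, c4):
        return np.einsum("mnls,mi,na,lj,sb->iajb", eri, c1, c2, c3, c4,
                         optimize=True)

    return ScfContext(
        geometry=geometry, basis_name=basis.name, n_occ=n_occ, n_virt=n_virt,
        frozen_core=ncore,
        mo_coeff_occ=C[:, ncore:nocc_total].copy(),
        mo_coeff_virt=C[:, nocc_total:].copy(),
        eps_occ=mo_energy[ncore:nocc_total].copy(),
        eps_virt=mo_energy[nocc_total:].copy(),
        fock_ao=F, overlap_ao=S, e_hf=float(e_tot),
        eri_provider=eri_provider,
        ao_atom_indices=basis.ao_atom_indices())


# --------------------------------------------------------------- localization

def _mulliken_charges(C: np.ndarray, S: np.ndarray,
                      ao_atoms: np.ndarray, n_atoms: int) -> np.ndarray:
    """Q[A, i] = Σ_{μ∈A} Σ_ν C_μi S_μν C_νi (gross Mulliken population)."""
    SC = S @ C
    contrib = C * SC  # (n_ao, n_mo)
    Q = np.zeros((n_atoms, C.shape[1]))
    np.add.at(Q, ao_atoms, contrib)
    return Q


def pipek_mezey_metric(C: np.ndarray, scf: ScfContext) -> float:
    """Σ_i Σ_A Q_A(i)^2 — the functional PM localization maximizes."""
    Q = _mulliken_charges(C, scf.overlap_ao, scf.ao_atom_indices,
                          scf.geometry.n_atoms)
    return float(np.sum(Q ** 2))


def localize_occupied(scf: ScfContext, conv_tol: float = 1e-10,
                      max_sweeps: int = 200) -> LocalizedOrbitals:
    """Pipek–Mezey localization of the correlated occupieds (Jacobi sweeps).

    Deterministic convention: LMOs ordered by descending largest Mulliken
    population (ties broken by owning atom index, then population vector);
    sign fixed so the largest-magnitude AO coefficient is positive.
    """
    C = scf.mo_coeff_occ.copy()
    n_occ = C.shape[1]
    S = scf.overlap_ao
    ao_atoms = scf.ao_atom_indices
    n_atoms = scf.geometry.n_atoms

    if n_occ > 1:
        metric = pipek_mezey_metric(C, scf)
        for sweep in range(max_sweeps):
            for s in range(n_occ - 1):
                for t in range(s + 1, n_occ):
                    pair = C[:, [s, t]]
                    Q = _mulliken_charges(pair, S, ao_atoms, n_atoms)
                    Qs, Qt = Q[:, 0], Q[:, 1]
                    SC_s = S @ pair[:, 0]
                    SC_t = S @ pair[:, 1]
                    cross = pair[:, 0] * SC_t + pair[:, 1] * SC_s
                    Qst = np.zeros(n_atoms)
                    np.add.at(Qst, ao_atoms, 0.5 * cross)
                    Ast = float(np.sum(Qst ** 2 - 0.25 * (Qs - Qt) ** 2))
                    Bst = float(np.sum(Qst * (Qs - Qt)))
                    if Ast ** 2 + Bst ** 2 < 1e-24:
                        continue
                    gamma = 0.25 * np.arctan2(Bst, -Ast)
                    cg, sg = np.cos(gamma), np.sin(gamma)
                    new_s = cg * pair[:, 0] + sg * pair[:, 1]
                    new_t = -sg * pair[:, 0] + cg * pair[:, 1]
                    C[:, s] = new_s
                    C[:, t] = new_t
            new_metric = pipek_mezey_metric(C, scf)
            if abs(new_metric - metric) < conv_tol:
                break
            metric = new_metric
        else:
            raise ScfError(
                f"Pipek–Mezey localization did not converge in {max_sweeps} "
                "sweeps")

    # ordering + sign convention
    Q = _mulliken_charges(C, S, ao_atoms, n_atoms)
    max_pop = Q.max(axis=0)
    max_atom = Q.argmax(axis=0)
    order = sorted(range(n_occ),
                   key=lambda i: (-round(max_pop[i], 8), max_atom[i],
                                  tuple(np.round(-Q[:, i], 8))))
    C = C[:, order]
    for i in range(n_occ):
        k = int(np.argmax(np.abs(C[:, i])))
        if C[k, i] < 0:
            C[:, i] *= -1.0

    fock_lmo = C.T @ scf.fock_ao @ C
    return LocalizedOrbitals(c_lmo=C, fock_lmo=fock_lmo,
                             metric=pipek_mezey_metric(C, scf))
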