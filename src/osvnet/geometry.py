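"""Molecular geometries and XYZ I/O.

Coordinates are stored in Ångström; conversion to Bohr happens only at the
integral layer.  Only closed-shell neutral/charged singlets are supported by
the mean-field backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ANGSTROM_TO_BOHR = 1.8897261254578281
HARTREE_TO_KCALMOL = 627.509474

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10,
}

#: 1s cores frozen for first-row heavy atoms; H/He have no core.
CORE_ORBITALS = {"H": 0, "He": 0, "Li": 1, "Be": 1, "B": 1, "C": 1, "N": 1,
                 "O": 1, "F": 1, "Ne": 1}


@dataclass(frozen=True)
class Geometry:
    """A molecular geometry: element symbols + Cartesian coordinates (Å)."""

    atoms: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Å
    charge: int = 0
    spin_multiplicity: int = 1
    comment: str = field(default="", compare=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.atoms) != coords.shape[0]:
            raise ValueError("atoms and coords length mismatch")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        for a in self.atoms:
            if a not in ATOMIC_NUMBERS:
                raise ValueError(f"unsupported element {a!r}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[a] for a in self.atoms], dtype=int)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    def coords_bohr(self) -> np.ndarray:
        return self.coords * ANGSTROM_TO_BOHR

    def min_interatomic_distance(self) -> float:
        if self.n_atoms < 2:
            return np.inf
        d = np.linalg.norm(self.coords[:, None] - self.coords[None, :], axis=-1)
        return float(d[np.triu_indices(self.n_atoms, 1)].min())

    def nuclear_repulsion(self) -> float:
        """Point-charge repulsion energy in Hartree."""
        z = self.atomic_numbers.astype(float)
        r = self.coords_bohr()
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e

    def to_xyz(self) -> str:
        lines = [str(self.n_atoms), self.comment]
        for a, (x, y, z) in zip(self.atoms, self.coords):
            lines.append(f"{a} {x:.10f} {y:.10f} {z:.10f}")
        return "\n".join(lines) + "\n"


def read_xyz(path: str | Path, charge: int = 0,
             spin_multiplicity: int = 1) -> Geometry:
    """Read a standard XYZ file (count line, comment line, atom lines)."""
    lines = Path(path).read_text().strip().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file: {path}")
    try:
        n = int(lines[0].split()[0])
        body = lines[2:2 + n]
        comment = lines[1] if len(lines) > 1 else ""
    except (ValueError, IndexError):
        # headerless variant: atom lines only
        n = len(lines)
        body = lines
        comment = ""
    atoms, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ line: {ln!r}")
        atoms.append(parts[0].capitalize())
        coords.append([float(p) for p in parts[1:4]])
    if len(atoms) != n:
        raise ValueError(f"XYZ header promises {n} atoms, found {len(atoms)}")
    return Geometry(tuple(atoms), np.array(coords), charge, spin_multiplicity,
                    comment=comment)


def write_xyz(geom: Geometry, path: str | Path) -> None:
    Path(path).write_text(geom.to_xyz())
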