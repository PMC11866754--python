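"""Exact MP2 correlation energies and their decomposition into localized
orbital-pair energies e_ij.

The pair energies are the training labels: the total correlation energy
E_c = Σ_{i≤j} e_ij (off-diagonal entries stored with their summed ij+ji
weight), and rotation invariance of MP2 under occupied-occupied rotations
guarantees the decomposition is exact.  Higher-level labels (e.g. coupled
cluster pair energies computed elsewhere) can be ingested from TSV files but
are never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scf import LocalizedOrbitals, ScfContext


@dataclass(frozen=True, order=True)
class PairKey:
    """Unordered occupied-orbital pair, stored with i <= j."""

    i: int
    j: int

    def __post_init__(self):
        if not (0 <= self.i <= self.j):
            raise ValueError(f"PairKey requires 0 <= i <= j, got {self}")

    @property
    def is_diagonal(self) -> bool:
        return self.i == self.j


@dataclass
class PairEnergyTable:
    """Map PairKey -> e_ij (Hartree) plus the total correlation energy."""

    entries: dict[PairKey, float]
    e_corr: float
    level: str = "mp2-internal"
    meta: dict = field(default_factory=dict)

    def __getitem__(self, key: PairKey) -> float:
        return self.entries[key]

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self):
        return self.entries.keys()

    def sum(self) -> float:
        return float(sum(self.entries.values()))

    def check_keys(self, keys) -> None:
        """Raise if `keys` and the table's keys differ, naming offenders."""
        have = set(self.entries)
        want = set(keys)
        if have != want:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise KeyError(
                f"pair-key mismatch: missing {missing[:10]} "
                f"(n={len(missing)}), unexpected {extra[:10]} (n={len(extra)})")


def canonical_mp2(scf: ScfContext):
    """Closed-shell canonical MP2.

    Returns (E_c, t2, ovov) with t2[i,a,j,b] = (ia|jb)/(ε_i+ε_j−ε_a−ε_b)
    over the correlated occupieds and ovov the MO integrals (ia|jb).
    """
    ovov = scf.eri_ovov()
    eo, ev = scf.eps_occ, scf.eps_virt
    denom = (eo[:, None, None, None] - ev[None, :, None, None]
             + eo[None, None, :, None] - ev[None, None, None, :])
    if np.min(np.abs(denom)) < 1e-8:
        raise RuntimeError("degenerate occupied-virtual gap in MP2")
    t2 = ovov / denom
    e_corr = float(np.einsum("iajb,iajb->", t2, 2.0 * ovov
                             - ovov.transpose(0, 3, 2, 1)))
    return e_corr, t2, ovov


def lmo_pair_energies(scf: ScfContext, lmos: LocalizedOrbitals
                      ) -> PairEnergyTable:
    """Exact pair correlation energies in the LMO basis.

    Canonical amplitudes and integrals are rotated into the localized
    occupied basis; each unordered pair i<=j stores the full (ij + ji)
    contribution so the plain sum of entries equals E_c.
    """
    e_corr, t2, ovov = canonical_mp2(scf)
    # U maps canonical occupied -> LMO: c_lmo = mo_coeff_occ @ U
    s_c = scf.mo_coeff_occ.T @ scf.overlap_ao @ lmos.c_lmo
    t2_l = np.einsum("iajb,ik,jl->kalb", t2, s_c, s_c, optimize=True)
    k_l = np.einsum("iajb,ik,jl->kalb", ovov, s_c, s_c, optimize=True)
    contra = 2.0 * k_l - k_l.transpose(0, 3, 2, 1)
    pair_e = np.einsum("iajb,iajb->ij", t2_l, contra, optimize=True)
    n = scf.n_occ
    entries: dict[PairKey, float] = {}
    for i in range(n):
        for j in range(i, n):
            val = pair_e[i, j] if i == j else pair_e[i, j] + pair_e[j, i]
            entries[PairKey(i, j)] = float(val)
    return PairEnergyTable(entries=entries, e_corr=e_corr,
                           level="mp2-internal",
                           meta={"basis": scf.basis_name,
                                 "frozen_core": scf.frozen_core})


# ------------------------------------------------------------------ label IO

def save_labels(table: PairEnergyTable, path: str | Path) -> None:
    """Write a TSV label table: header, one row per pair, E_c footer."""
    lines = ["i\tj\te_ij_hartree"]
    for key in sorted(table.entries):
        lines.append(f"{key.i}\t{key.j}\t{table.entries[key]:.16e}")
    lines.append(f"#E_corr\t{table.e_corr:.16e}\t{table.level}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_external_labels(path: str | Path) -> PairEnergyTable:
    """Read a pair-energy label table written by :func:`save_labels` (or by
    an external program following the same schema)."""
    text = Path(path).read_text().strip()
    if not text:
        raise ValueError(f"empty label file: {path}")
    entries: dict[PairKey, float] = {}
    e_corr = None
    level = "external-file"
    for ln, line in enumerate(text.splitlines()):
        if ln == 0 and line.lower().startswith("i\t"):
            continue
        if line.startswith("#E_corr"):
            parts = line.split("\t")
            e_corr = float(parts[1])
            if len(parts) > 2:
                level = parts[2]
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed label line {ln}: {line!r}")
        key = PairKey(int(parts[0]), int(parts[1]))
        if key in entries:
            raise ValueError(f"duplicate pair {key} in {path}")
        entries[key] = float(parts[2])
    if not entries:
        raise ValueError(f"label file {path} holds no pair rows")
    if e_corr is None:
        e_corr = float(sum(entries.values()))
    return PairEnergyTable(entries=entries, e_corr=e_corr, level=level)
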