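"""Orbital-specific-virtual (OSV) domains and the four-channel pseudo-energy
descriptors.

For each localized occupied orbital i, the diagonal semicanonical MP2
amplitude matrix

    t_ii^{ab} = -(ia|ib) / (ε_a + ε_b - 2 f_ii)

is SVD-factorized; the leading singular vectors Q rotate the canonical
virtual space into a compact OSV set specific to that orbital.  A kept pair
ij is then described by a (4, n_osv, n_osv) tensor of Hadamard products
K̃ ∘ (2T̃ - T̃ᵀ), one channel per excitation character:

    vt  (i μ̄_i | j ν̄_j)   vertical
    ex  (i μ̄_j | j ν̄_i)   exchange
    ct1 (i μ̄_i | j ν̄_i)   charge transfer into domain i
    ct2 (i μ̄_j | j ν̄_j)   charge transfer into domain j

The element sum of the vt channel is a crude estimate of the exact pair
correlation energy; the network learns the accurate mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry
from .mp2 import PairKey
from .scf import LocalizedOrbitals, ScfContext, localize_occupied, \
    run_mean_field

CHANNELS = ("vt", "ex", "ct1", "ct2")

#: default OSV truncation (pair-screening) threshold
DEFAULT_OSV_CUTOFF = 3.2e-5
#: default number of OSVs kept per localized orbital
DEFAULT_N_OSV = 8


class DegeneracyError(ArithmeticError):
    """Raised when an energy denominator vanishes (near-degenerate system)."""


@dataclass
class OsvDomain:
    """Truncated OSV rotation for one localized occupied orbital."""

    lmo_index: int
    q: np.ndarray                # (n_virt, n_osv), orthonormal columns
    singular_values: np.ndarray  # descending, length n_osv
    fock_osv_diag: np.ndarray    # diag(qᵀ F_virt q), Hartree

    @property
    def n_osv(self) -> int:
        return self.q.shape[1]


@dataclass
class PairFeature:
    """The (4, n_osv, n_osv) pseudo-energy descriptor of one kept pair."""

    key: PairKey
    tensor: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.tensor, float)
        if t.ndim != 3 or t.shape[0] != 4 or t.shape[1] != t.shape[2]:
            raise ValueError(f"expected (4, n, n) tensor, got {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite feature tensor")
        self.tensor = t

    @property
    def n_osv(self) -> int:
        return self.tensor.shape[1]

    def flat(self) -> np.ndarray:
        """Channel-major, then row-major flattening (the dataset layout)."""
        return self.tensor.reshape(-1)


def diagonal_semicanonical_amplitudes(scf: ScfContext,
                                      lmos: LocalizedOrbitals,
                                      i: int,
                                      ovov_lmo: np.ndarray | None = None
                                      ) -> np.ndarray:
    """t_ii^{ab} = -(ia|ib)/(ε_a + ε_b - 2 f_ii) for LMO i (symmetric)."""
    if not 0 <= i < scf.n_occ:
        raise IndexError(f"LMO index {i} out of range")
    if ovov_lmo is None:
        ovov_lmo = scf.eri_ovov(lmos.c_lmo)
    k_ii = ovov_lmo[i, :, i, :]
    f_ii = lmos.fock_lmo[i, i]
    denom = scf.eps_virt[:, None] + scf.eps_virt[None, :] - 2.0 * f_ii
    if np.min(np.abs(denom)) < 1e-10:
        raise DegeneracyError(
            f"vanishing semicanonical denominator for LMO {i}")
    return -k_ii / denom


def build_osv_domain(t_ii: np.ndarray, n_osv: int, scf: ScfContext,
                     lmos: LocalizedOrbitals, lmo_index: int = 0
                     ) -> OsvDomain:
    """Keep the `n_osv` leading singular vectors of t_ii as the OSV basis.

    Deterministic post-processing: singular values sorted descending, and
    each vector's sign fixed so its first significant component is positive.
    """
    n_virt = t_ii.shape[0]
    if not 1 <= n_osv <= n_virt:
        raise ValueError(f"n_osv={n_osv} outside [1, n_virt={n_virt}]")
    u, s, _ = np.linalg.svd(t_ii, full_matrices=False)
    order = np.argsort(-s, kind="stable")
    u, s = u[:, order], s[order]
    q = u[:, :n_osv].copy()
    for c in range(q.shape[1]):
        nz = np.flatnonzero(np.abs(q[:, c]) > 1e-8)
        ref = nz[0] if nz.size else int(np.argmax(np.abs(q[:, c])))
        if q[ref, c] < 0:
            q[:, c] *= -1.0
    fock_osv_diag = np.einsum("am,a,am->m", q, scf.eps_virt, q)
    return OsvDomain(lmo_index=lmo_index, q=q,
                     singular_values=s[:n_osv].copy(),
                     fock_osv_diag=fock_osv_diag)


def osv_cross_overlap(dom_i: OsvDomain, dom_j: OsvDomain) -> np.ndarray:
    """OSV cross-overlap block q_iᵀ S_virt q_j.

    The domains are expressed in the orthonormal canonical-virtual basis, in
    which S_virt is the identity.
    """
    return dom_i.q.T @ dom_j.q

def pair_keep_decision(dom_i: OsvDomain, dom_j: OsvDomain,
                       scf: ScfContext, cutoff: float = DEFAULT_OSV_CUTOFF,
                       statistic: str = "max_singular") -> bool:
    """Keep pair ij iff its OSV spaces overlap above `cutoff`.

    Diagonal pairs are always kept.  `statistic` selects the overlap
    functional: the largest singular value of the cross-overlap block
    (default) or its Frobenius norm.
    """
    if dom_i.lmo_index == dom_j.lmo_index:
        return True
    block = osv_cross_overlap(dom_i, dom_j)
    if statistic == "max_singular":
        stat = float(np.linalg.svd(block, compute_uv=False)[0]) \
            if min(block.shape) else 0.0
    elif statistic == "frobenius":
        stat = float(np.linalg.norm(block))
    else:
        raise ValueError(f"unknown screening statistic {statistic!r}")
    return stat >= cutoff


def channel_exchange_integrals(scf: ScfContext, lmos: LocalizedOrbitals,
                               dom_i: OsvDomain, dom_j: OsvDomain,
                               ovov_lmo: np.ndarray | None = None):
    """The four OSV-basis exchange-integral blocks K̃ for pair (i, j).

    Channel (μ̄, ν̄) index sets: vt (μ̄_i, ν̄_j), ex (μ̄_j, ν̄_i),
    ct1 (μ̄_i, ν̄_i), ct2 (μ̄_j, ν̄_j); each is a two-sided rotation of the
    canonical-virtual block K_ij^{ab} = (ia|jb).
    """
    i, j = dom_i.lmo_index, dom_j.lmo_index
    if ovov_lmo is None:
        ovov_lmo = scf.eri_ovov(lmos.c_lmo)
    k_ab = ovov_lmo[i, :, j, :]
    qi, qj = dom_i.q, dom_j.q
    return {
        "vt": qi.T @ k_ab @ qj,
        "ex": qj.T @ k_ab @ qi,
        "ct1": qi.T @ k_ab @ qi,
        "ct2": qj.T @ k_ab @ qj,
    }


def channel_pseudo_amplitudes(k_channels: dict, f_ii: float, f_jj: float,
                              dom_i: OsvDomain, dom_j: OsvDomain) -> dict:
    """Semicanonical pseudo-amplitudes T̃ = -K̃ / (f_μ̄μ̄ + f_ν̄ν̄ - f_ii - f_jj).

    The denominator is written virtual-minus-occupied, exactly parallel to
    the diagonal amplitudes t_ii = -(ia|ib)/(ε_a + ε_b - 2 f_ii); the OSV
    Fock diagonals match each channel's row/column OSV sets.
    """
    fock = {"vt": (dom_i.fock_osv_diag, dom_j.fock_osv_diag),
            "ex": (dom_j.fock_osv_diag, dom_i.fock_osv_diag),
            "ct1": (dom_i.fock_osv_diag, dom_i.fock_osv_diag),
            "ct2": (dom_j.fock_osv_diag, dom_j.fock_osv_diag)}
    out = {}
    for ch, k in k_channels.items():
        f_mu, f_nu = fock[ch]
        denom = f_mu[:, None] + f_nu[None, :] - f_ii - f_jj
        if np.min(np.abs(denom)) < 1e-10:
            raise DegeneracyError(
                f"vanishing pseudo-amplitude denominator in channel {ch}")
        out[ch] = -k / denom
    return out


def pair_feature_tensor(k_channels: dict, t_channels: dict,
                        key: PairKey) -> PairFeature:
    """Assemble ẽ_ij = K̃ ∘ (2T̃ - T̃ᵀ) with channel order (vt, ex, ct1, ct2).

    Transpose convention: swapping the two OSV indices of the vt channel
    lands in the ex index set (and vice versa), so those two channels are
    each other's transpose partners; the ct channels transpose within their
    own square block.  This keeps every channel gauge-invariant under OSV
    sign flips.
    """
    partner = {"vt": "ex", "ex": "vt", "ct1": "ct1", "ct2": "ct2"}
    planes = []
    for ch in CHANNELS:
        contra = 2.0 * t_channels[ch] - t_channels[partner[ch]].T
        planes.append(k_channels[ch] * contra)
    return PairFeature(key=key, tensor=np.stack(planes))


@dataclass
class FeatureSet:
    """All kept pair descriptors of one molecule plus provenance metadata."""

    features: list[PairFeature]
    n_occ: int
    n_osv: int
    cutoff: float
    basis: str
    screened_out: list[PairKey] = field(default_factory=list)
    e_hf: float = np.nan

    @property
    def keys(self) -> list[PairKey]:
        return [f.key for f in self.features]

    def diagonal(self) -> list[PairFeature]:
        return [f for f in self.features if f.key.is_diagonal]

    def offdiagonal(self) -> list[PairFeature]:
        return [f for f in self.features if not f.key.is_diagonal]


def featurize_context(scf: ScfContext, lmos: LocalizedOrbitals,
                      n_osv: int = DEFAULT_N_OSV,
                      cutoff: float = DEFAULT_OSV_CUTOFF,
                      statistic: str = "max_singular") -> FeatureSet:
    """Build OSV domains and pair descriptors from converged orbitals."""
    n_osv_eff = min(n_osv, scf.n_virt)
    ovov_lmo = scf.eri_ovov(lmos.c_lmo)
    domains = []
    for i in range(scf.n_occ):
        t_ii = diagonal_semicanonical_amplitudes(scf, lmos, i, ovov_lmo)
        domains.append(build_osv_domain(t_ii, n_osv_eff, scf, lmos, i))
    f_diag = lmos.f_diag
    features, screened = [], []
    for i in range(scf.n_occ):
        for j in range(i, scf.n_occ):
            key = PairKey(i, j)
            if not pair_keep_decision(domains[i], domains[j], scf, cutoff,
                                      statistic):
                screened.append(key)
                continue
            k_ch = channel_exchange_integrals(scf, lmos, domains[i],
                                              domains[j], ovov_lmo)
            t_ch = channel_pseudo_amplitudes(k_ch, f_diag[i], f_diag[j],
                                             domains[i], domains[j])
            features.append(pair_feature_tensor(k_ch, t_ch, key))
    return FeatureSet(features=features, n_occ=scf.n_occ, n_osv=n_osv_eff,
                      cutoff=cutoff, basis=scf.basis_name,
                      screened_out=screened, e_hf=scf.e_hf)


def featurize_molecule(geometry: Geometry, basis: str,
                       n_osv: int = DEFAULT_N_OSV,
                       cutoff: float = DEFAULT_OSV_CUTOFF,
                       frozen_core: bool | int = True,
                       statistic: str = "max_singular"):
    """Full pipeline: SCF → localization → OSV pair descriptors.

    Returns (FeatureSet, ScfContext, LocalizedOrbitals); deterministic given
    the geometry, basis and the ordering conventions.
    """
    scf = run_mean_field(geometry, basis, frozen_core=frozen_core)
    lmos = localize_occupied(scf)
    fs = featurize_context(scf, lmos, n_osv=n_osv, cutoff=cutoff,
                           statistic=statistic)
    return fs, scf, lmos
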