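"""Deterministic synthetic fixtures.

Two families:

* **Perturbed conformers** — Gaussian Cartesian displacements of a reference
  geometry (thermal-ensemble stand-in) with a minimum interatomic distance
  enforced by resampling, for exercising the full quantum pipeline.
* **Synthetic pair regimes** — (4, n, n) feature tensors drawn from a
  declared Gaussian-mixture distribution with labels from a fixed smooth
  saturating map of the weighted channel sums.  A "shifted" regime moves the
  feature distribution (heavier long-range tail, shifted channel means) while
  keeping the mapping itself unchanged, so small→large transfer becomes a
  pure covariate-shift problem.

Everything is bitwise reproducible from (seed, parameters).  The label map is
fixed in code and versioned; changing it is a breaking change to the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .geometry import Geometry
from .models import PairDataset
from .mp2 import PairKey

LABEL_MAP_VERSION = 1

WATER_MONOMER = Geometry(
    ("O", "H", "H"),
    np.array([[0.0, 0.0, 0.1173],
              [0.0, 0.7572, -0.4692],
              [0.0, -0.7572, -0.4692]]),
    comment="water monomer, near-equilibrium")

#: hydrogen-bonded water dimer, O-O ~ 2.91 A
WATER_DIMER = Geometry(
    ("O", "H", "H", "O", "H", "H"),
    np.array([[-1.551007, -0.114520, 0.0],
              [-1.934259, 0.762503, 0.0],
              [-0.599677, 0.040712, 0.0],
              [1.350625, 0.111469, 0.0],
              [1.680398, -0.373741, -0.758561],
              [1.680398, -0.373741, 0.758561]]),
    comment="water dimer, hydrogen bonded")


def perturbed_conformers(base_geometry: Geometry, n_conformers: int,
                         sigma_angstrom: float, seed: int,
                         min_distance: float = 0.7,
                         max_resample: int = 1000) -> list[Geometry]:
    """IID Gaussian Cartesian displacements of every atom (σ in Å)."""
    if sigma_angstrom < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_conformers):
        for attempt in range(max_resample):
            disp = rng.normal(0.0, sigma_angstrom,
                              size=base_geometry.coords.shape) \
                if sigma_angstrom > 0 else 0.0
            geom = Geometry(base_geometry.atoms,
                            base_geometry.coords + disp,
                            base_geometry.charge,
                            base_geometry.spin_multiplicity,
                            comment=f"conformer {k} sigma={sigma_angstrom}")
            if geom.min_interatomic_distance() >= min_distance:
                out.append(geom)
                break
        else:
            raise RuntimeError(
                f"resampling budget exhausted for conformer {k} "
                f"(sigma={sigma_angstrom})")
    return out


@dataclass(frozen=True)
class SyntheticRegime:
    """Feature distribution + fixed label map for one synthetic population.

    Features: each channel c of the (4, n_osv, n_osv) tensor has iid entries
    from a two-component Gaussian mixture: the bulk N(mean_c, sigma_c²) with
    probability 1 − tail_weight, and a long-range tail component
    N(mean_c + tail_shift_c, (tail_scale·sigma_c)²) otherwise.  Diagonal
    pairs have their channel means scaled by `diag_scale`.

    Labels: with channel sums s_c, and s = Σ_c w_c s_c,

        e = -depth · (1 + erf(gain·(s - pivot))) / 2 + noise

    a smooth saturating map (labels in (-depth, 0)), plus Gaussian noise σ.
    """

    n_osv: int = 4
    channel_means: tuple = (-0.004, -0.002, 0.001, 0.001)
    channel_sigmas: tuple = (0.004, 0.003, 0.002, 0.002)
    tail_weight: float = 0.0
    tail_scale: float = 3.0
    tail_shift: tuple = (-0.006, -0.003, 0.0, 0.0)
    diag_scale: float = 2.0
    channel_weights: tuple = (1.0, 0.6, 0.25, 0.25)
    gain: float = 8.0
    pivot: float = -0.05
    depth: float = 0.03
    noise_sigma: float = 1e-5
    seed: int = 0

    def _moments(self, diagonal: bool):
        """Mean/variance of s = Σ_c w_c s_c per mixture component."""
        n2 = self.n_osv ** 2
        w = np.asarray(self.channel_weights)
        m = np.asarray(self.channel_means) * (self.diag_scale if diagonal
                                              else 1.0)
        sg = np.asarray(self.channel_sigmas)
        ts = np.asarray(self.tail_shift)
        mean_bulk = float(n2 * np.sum(w * m))
        var_bulk = float(n2 * np.sum(w ** 2 * sg ** 2))
        mean_tail = float(n2 * np.sum(w * (m + ts)))
        var_tail = float(n2 * np.sum(w ** 2 * (self.tail_scale * sg) ** 2))
        return (mean_bulk, var_bulk), (mean_tail, var_tail)

    def label_of(self, tensors: np.ndarray) -> np.ndarray:
        """Noise-free labels of a (n_pairs, 4, n, n) feature array."""
        s = np.einsum("pcij,c->p", tensors,
                      np.asarray(self.channel_weights))
        return -self.depth * 0.5 * (1.0 + erf(self.gain * (s - self.pivot)))

    def analytic_label_mean(self, diagonal: bool = False) -> float:
        """Closed-form E[e] (noise-free): for S ~ N(M, V),
        E[erf(g(S - p))] = erf(g(M - p) / sqrt(1 + 2 g² V))."""
        out = 0.0
        g = self.gain
        for weight, (M, V) in zip(
                (1.0 - self.tail_weight, self.tail_weight),
                self._moments(diagonal)):
            if weight == 0.0:
                continue
            e = erf(g * (M - self.pivot) / np.sqrt(1.0 + 2.0 * g * g * V))
            out += weight * (-self.depth * 0.5 * (1.0 + e))
        return float(out)


def synthetic_pair_dataset(regime: SyntheticRegime, n_pairs: int,
                           diag_fraction: float = 0.25,
                           seed: int | None = None) -> PairDataset:
    """Draw `n_pairs` synthetic pair descriptors + labels from a regime.

    The first ``round(diag_fraction·n_pairs)`` samples are tagged as diagonal
    pairs (PairKey(i, i)); the rest as off-diagonal.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(regime.seed if seed is None else seed)
    n = regime.n_osv
    n_diag = int(round(diag_fraction * n_pairs))
    tensors = np.empty((n_pairs, 4, n, n))
    means = np.asarray(regime.channel_means)
    sigmas = np.asarray(regime.channel_sigmas)
    shifts = np.asarray(regime.tail_shift)
    for p in range(n_pairs):
        scale = regime.diag_scale if p < n_diag else 1.0
        in_tail = rng.random() < regime.tail_weight
        m = means * scale + (shifts if in_tail else 0.0)
        s = sigmas * (regime.tail_scale if in_tail else 1.0)
        tensors[p] = m[:, None, None] + s[:, None, None] \
            * rng.standard_normal((4, n, n))
    y = regime.label_of(tensors)
    if regime.noise_sigma > 0:
        y = y + rng.normal(0.0, regime.noise_sigma, size=n_pairs)
    keys = [PairKey(p, p) if p < n_diag else PairKey(p, p + 1)
            for p in range(n_pairs)]
    X = tensors.reshape(n_pairs, -1)
    mask = np.zeros(n_pairs, bool)
    mask[:n_diag] = True
    ds = PairDataset(X, y, keys)
    ds.diag_mask = mask
    return ds


#: default covariate shift standing in for small→large transfer: the bulk of
#: pairs becomes weaker (channel means/spreads compressed, as remote pairs
#: dominate in large systems) while a heavy, far-out tail of strongly
#: interacting long-range configurations appears that the bulk-trained model
#: has never seen.
DEFAULT_SHIFT = {"scale": 0.3, "tail_weight": 0.5, "tail_scale": 5.0,
                 "tail_shift": (-0.008, -0.004, 0.002, 0.002)}


def shifted_regime(regime: SyntheticRegime,
                   shift_spec: dict | None = None) -> SyntheticRegime:
    """Shift the feature distribution, keeping the label map unchanged.

    Recognized keys: `scale` (multiplies channel means and sigmas),
    `mean_shift` (added to channel means), `tail_weight`, `tail_scale`,
    `tail_shift`, `seed`.
    """
    spec = dict(DEFAULT_SHIFT if shift_spec is None else shift_spec)
    means = np.asarray(regime.channel_means, float)
    sigmas = np.asarray(regime.channel_sigmas, float)
    kwargs: dict = {}
    if "scale" in spec:
        f = float(spec["scale"])
        if not np.isfinite(f):
            raise ValueError("shift magnitudes must be finite")
        means = means * f
        sigmas = sigmas * f
        kwargs["channel_sigmas"] = tuple(sigmas)
    if "mean_shift" in spec:
        ms = np.asarray(spec["mean_shift"], float)
        if not np.all(np.isfinite(ms)):
            raise ValueError("shift magnitudes must be finite")
        means = means + ms
    kwargs["channel_means"] = tuple(means)
    for key in ("tail_weight", "tail_scale", "seed"):
        if key in spec:
            kwargs[key] = type(getattr(regime, key))(spec[key])
    if "tail_shift" in spec:
        kwargs["tail_shift"] = tuple(float(v) for v in spec["tail_shift"])
    return replace(regime, **kwargs)
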