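"""Network and error diagnostics.

* per-layer Frobenius ratios ‖ΔW‖_F/‖W0‖_F of a fine-tuned model (how much
  each pretrained layer was adjusted; the residual head is reported as an
  extra slot against the base output layer);
* kernel-density summaries of per-pair prediction errors — the symmetric,
  zero-centred shape of this distribution is what lets pair errors cancel in
  the total-energy sum instead of accumulating;
* MAE reports in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde, skew

from .finetune import FineTunedPairMLP
from .geometry import HARTREE_TO_KCALMOL
from .mp2 import PairEnergyTable, PairKey


@dataclass
class LayerDeltaStats:
    """‖ΔW‖_F/‖W0‖_F per weight-bearing layer plus the residual-head slot."""

    ratios: np.ndarray
    labels: list[str]
    pair_type: str = "unspecified"


@dataclass
class ErrorDensity:
    deviations: np.ndarray      # per-pair signed errors, Hartree
    bandwidth: float            # Scott-rule KDE bandwidth (0 if degenerate)
    mean: float
    median: float
    skewness: float

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        if self.bandwidth == 0.0:
            raise ValueError("degenerate (zero-spread) deviation set")
        return gaussian_kde(self.deviations)(grid)


def layer_frobenius_ratios(tuned: FineTunedPairMLP,
                           pair_type: str = "unspecified") -> LayerDeltaStats:
    """Frobenius-norm ratio of the weight adjustment in every layer.

    For LoRA methods ΔW = B·A; for full fine-tuning ΔW = W_tuned − W0; for
    bias-only methods all ratios are zero.  The final slot reports
    ‖W^R‖/‖W_out0‖ for the residual head (zero when no head is attached).
    """
    base_W = tuned.base.weights_
    ad = tuned.adapters_
    if ad.has_lora():
        deltas = [bk @ ak for ak, bk in zip(ad.lora_A, ad.lora_B)]
    elif tuned.method == "full":
        deltas = [wt - w0 for wt, w0 in zip(tuned.weights_, base_W)]
    else:
        deltas = [np.zeros_like(w) for w in base_W]
    ratios = [np.linalg.norm(d) / np.linalg.norm(w0)
              for d, w0 in zip(deltas, base_W)]
    head_norm = np.linalg.norm(ad.head_W) if ad.has_head() else 0.0
    ratios.append(head_norm / np.linalg.norm(base_W[-1]))
    labels = [f"layer_{k + 1}" for k in range(len(base_W))] + ["residual_head"]
    return LayerDeltaStats(ratios=np.asarray(ratios), labels=labels,
                           pair_type=pair_type)


def pair_error_density(pred: dict[PairKey, float],
                       ref: PairEnergyTable) -> ErrorDensity:
    """Signed deviations pred − ref with a Scott-rule KDE summary."""
    ref.check_keys(pred.keys())
    keys = sorted(pred)
    dev = np.array([pred[k] - ref[k] for k in keys])
    spread = dev.std()
    bw = float(spread * len(dev) ** (-1.0 / 5.0)) if spread > 0 else 0.0
    return ErrorDensity(deviations=dev, bandwidth=bw,
                        mean=float(dev.mean()), median=float(np.median(dev)),
                        skewness=float(skew(dev)) if spread > 0 else 0.0)


def mae_report(pred_totals: dict, ref_totals: dict,
               unit: str = "kcal/mol") -> dict:
    """Per-system absolute errors (Hartree in, kcal/mol out by default)."""
    missing = set(ref_totals) ^ set(pred_totals)
    if missing:
        raise KeyError(f"unmatched systems: {sorted(missing)[:10]}")
    factor = {"kcal/mol": HARTREE_TO_KCALMOL, "hartree": 1.0}[unit]
    rows = {k: (pred_totals[k] - ref_totals[k]) * factor
            for k in sorted(pred_totals)}
    errs = np.array(list(rows.values()))
    return {"MAE": float(np.mean(np.abs(errs))),
            "max_error": float(np.max(np.abs(errs))),
            "unit": unit,
            "per_system": rows}


def total_error_scaling(n_values, sigma: float, seed: int,
                        n_repeats: int = 64) -> dict:
    """Monte-Carlo total-energy error |Σ errors| for iid zero-mean per-pair
    errors of scale σ, at several pair counts N.

    For unbiased symmetric errors the RMS total error is σ√N; a constant
    per-pair bias b instead gives exactly N·b.  Returns the measured RMS
    totals and the fitted log-log slope.
    """
    rng = np.random.default_rng(seed)
    rms = []
    for n in n_values:
        tot = [abs(rng.normal(0.0, sigma, size=n).sum())
               for _ in range(n_repeats)]
        rms.append(float(np.sqrt(np.mean(np.square(tot)))))
    slope = float(np.polyfit(np.log(np.asarray(n_values, float)),
                             np.log(rms), 1)[0])
    return {"n": list(n_values), "rms_total": rms, "slope": slope,
            "expected": [sigma * np.sqrt(n) for n in n_values]}
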