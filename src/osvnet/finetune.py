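"""Residual / low-rank fine-tuning of a pretrained pair-energy model.

Methods (all supervised with the exact pair energies of the fine-tuning
molecules, MAE loss):

``full``
    retrain every weight and bias of the base network (no adapters).
``bitfit`` / ``bitfit_r``
    tune only the bias terms b0 (weights bitwise frozen); the ``_r`` variant
    additionally trains a residual head.
``lora_r`` / ``reslora_r``
    freeze W0 and b0 and learn per-layer low-rank updates ΔW = B·A together
    with a residual head Δe^R read from the last hidden activation;
    ``reslora_r`` additionally feeds each dimension-matched LoRA block the
    sum of the previous and current layer inputs.
``delta_ml``
    baseline: a fresh network trained on the residuals e_exact − e^P
    (see :class:`DeltaMLRegressor`).

A just-initialized tuned model reproduces the base model bitwise (A and the
head start at zero), and parameters outside a method's trainable set are
never touched.  The base model's standardizer is reused, never refitted.
"""

from __future__ import annotations

from copy import deepcopy
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import FINETUNE_SCHEDULE, PairMLPRegressor
from .nn import Adapters, forward, make_lora, train_loop

METHODS = ("full", "bitfit", "bitfit_r", "lora_r", "reslora_r", "delta_ml")


@dataclass(frozen=True)
class FineTuneSpec:
    """Configuration of one fine-tuning run."""

    method: str = "lora_r"
    rank: int = 1
    schedule: tuple = FINETUNE_SCHEDULE
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"choose from {METHODS}")
        if self.method in ("lora_r", "reslora_r") and self.rank < 1:
            raise ValueError("LoRA rank must be >= 1")


class FineTunedPairMLP(RegressorMixin, BaseEstimator):
    """A base :class:`PairMLPRegressor` plus method-specific adapters.

    `initialize()` attaches the adapters without training (outputs equal the
    base bitwise); `fit(X, y)` trains the method's parameter set on exact
    pair energies (Hartree).  An empty schedule leaves the model unchanged.
    """

    def __init__(self, base: PairMLPRegressor, method: str = "lora_r",
                 rank: int = 1, schedule: tuple = FINETUNE_SCHEDULE,
                 batch_size: int = 64, seed: int = 0):
        self.base = base
        self.method = method
        self.rank = rank
        self.schedule = schedule
        self.batch_size = batch_size
        self.seed = seed

    # ------------------------------------------------------------ assembly
    def initialize(self) -> "FineTunedPairMLP":
        if self.method == "delta_ml":
            raise ValueError("delta_ml is trained via DeltaMLRegressor")
        check_is_fitted(self.base, "weights_")
        rng = np.random.default_rng(self.seed)
        spec = self.base.spec_
        W0, b0 = self.base.weights_, self.base.biases_
        if self.method == "full":
            self.weights_ = deepcopy(W0)
            self.biases_ = deepcopy(b0)
            self.adapters_ = Adapters()
            self.trainable_ = {"W": True, "b": True}
        else:
            self.weights_ = W0              # shared, frozen
            self.biases_ = b0
            width = spec.hidden_width
            head_W = np.zeros((1, width))
            head_b = np.zeros(1)
            if self.method in ("lora_r", "reslora_r"):
                A, B = make_lora(spec, self.rank, rng,
                                 shortcut=self.method == "reslora_r")
                self.adapters_ = Adapters(
                    lora_A=A, lora_B=B,
                    shortcut=self.method == "reslora_r",
                    head_W=head_W, head_b=head_b)
                self.trainable_ = {"lora": True, "head": True}
            elif self.method in ("bitfit", "bitfit_r"):
                delta_b = [np.zeros_like(bk) for bk in b0]
                ad = Adapters(delta_b=delta_b)
                self.trainable_ = {"delta_b": True}
                if self.method == "bitfit_r":
                    ad.head_W, ad.head_b = head_W, head_b
                    self.trainable_["head"] = True
                self.adapters_ = ad
        self.n_features_in_ = self.base.n_features_in_
        self.log_ = None
        return self

    # ------------------------------------------------------------- training
    def fit(self, X, y):
        if not hasattr(self, "adapters_"):
            self.initialize()
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X/y length mismatch")
        if not self.schedule or X.shape[0] == 0:
            return self
        std = self.base.standardizer_
        Xs = std.transform_X(X)
        ys = std.transform_y(y)
        rng = np.random.default_rng(self.seed + 1)
        self.log_ = train_loop(self.weights_, self.biases_, Xs, ys,
                               self.adapters_, self.trainable_,
                               self.schedule, self.batch_size, rng)
        return self

    # ----------------------------------------------------------- prediction
    def predict(self, X):
        check_is_fitted(self, "adapters_")
        X = np.asarray(X, float)
        std = self.base.standardizer_
        out = forward(self.weights_, self.biases_, std.transform_X(X),
                      self.adapters_)
        return std.inverse_y(out.ravel())

    def effective_weights(self) -> list[np.ndarray]:
        """W0 + B·A per layer (for network diagnostics)."""
        check_is_fitted(self, "adapters_")
        if self.adapters_.has_lora():
            return [w + bk @ ak for w, ak, bk in
                    zip(self.weights_, self.adapters_.lora_A,
                        self.adapters_.lora_B)]
        return [w.copy() for w in self.weights_]


# ------------------------------------------------------------- spec surface

def attach_residual_head(base: PairMLPRegressor,
                         seed: int = 0) -> FineTunedPairMLP:
    """Residual pair-correction head only (used by bitfit_r and for tests)."""
    return FineTunedPairMLP(base, method="bitfit_r", seed=seed).initialize()


def attach_lora(base: PairMLPRegressor, rank: int,
                with_res_shortcut: bool = False,
                seed: int = 0) -> FineTunedPairMLP:
    method = "reslora_r" if with_res_shortcut else "lora_r"
    return FineTunedPairMLP(base, method=method, rank=rank,
                            seed=seed).initialize()


def select_bitfit(base: PairMLPRegressor, with_residual_head: bool = False,
                  seed: int = 0) -> FineTunedPairMLP:
    method = "bitfit_r" if with_residual_head else "bitfit"
    return FineTunedPairMLP(base, method=method, seed=seed).initialize()


def finetune(model: FineTunedPairMLP, X, y,
             spec: FineTuneSpec | None = None) -> FineTunedPairMLP:
    """Train an assembled tuned model on exact pair-energy labels."""
    if spec is not None:
        model.schedule = spec.schedule
        model.batch_size = spec.batch_size
    return model.fit(X, y)


class DeltaMLRegressor(RegressorMixin, BaseEstimator):
    """Δ-ML baseline: a fresh network learns e_exact − e^P.

    Prediction adds the base model's output back, so the combined prediction
    is base + Δ by construction.
    """

    def __init__(self, base: PairMLPRegressor, seed: int = 0,
                 **mlp_kwargs):
        self.base = base
        self.seed = seed
        self.mlp_kwargs = mlp_kwargs

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        residual = y - self.base.predict(X)
        self.delta_model_ = PairMLPRegressor(seed=self.seed,
                                             **self.mlp_kwargs)
        self.delta_model_.fit(X, residual)
        return self

    def predict(self, X):
        check_is_fitted(self, "delta_model_")
        return self.base.predict(X) + self.delta_model_.predict(X)


def train_delta_ml(X, y, base: PairMLPRegressor, seed: int = 0,
                   **mlp_kwargs) -> DeltaMLRegressor:
    return DeltaMLRegressor(base, seed=seed, **mlp_kwargs).fit(X, y)


# ----------------------------------------------------------- bookkeeping

def count_trainable(model: FineTunedPairMLP) -> dict:
    """Exact trainable / base parameter counts and their ratio."""
    check_is_fitted(model, "adapters_")
    base_total = sum(w.size for w in model.base.weights_) \
        + sum(bk.size for bk in model.base.biases_)
    t = model.trainable_
    ad = model.adapters_
    n = 0
    if t.get("W"):
        n += sum(w.size for w in model.weights_)
    if t.get("b"):
        n += sum(bk.size for bk in model.biases_)
    if t.get("delta_b"):
        n += sum(d.size for d in ad.delta_b)
    if t.get("lora"):
        n += sum(a.size for a in ad.lora_A) + sum(bb.size for bb in ad.lora_B)
    if t.get("head"):
        n += ad.head_W.size + ad.head_b.size
    return {"trainable": int(n), "total_base": int(base_total),
            "fraction": n / base_total}
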