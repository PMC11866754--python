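"""Base pair-energy regressors (scikit-learn style).

The pair functional maps the flattened (4, n, n) pseudo-energy descriptor of
an occupied-orbital pair to its exact pair correlation energy (Hartree), and
the molecular correlation energy is the plain sum of pair predictions:

    E_c = Σ_{i<=j} e_ij^P,    E_tot = E_HF + E_c

Diagonal (i == j) and off-diagonal pairs are handled by two separate MLPs
because their energy distributions differ systematically.  Training minimizes
the mean absolute error over pairs with equal weight — individual pairs are
supervised directly, the total energy never is, which is what makes per-pair
errors cancel rather than accumulate in the sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .mp2 import PairEnergyTable, PairKey
from .nn import (Adapters, NetworkSpec, Standardizer, TrainLog, forward,
                 init_base_params, train_loop)
from .osv import FeatureSet, PairFeature

#: training-schedule default: 1000 epochs split over two Adam learning rates
BASE_SCHEDULE = ((500, 1e-3), (500, 1e-4))
FINETUNE_SCHEDULE = ((200, 1e-5), (800, 1e-6))


@dataclass
class PairDataset:
    """Standardizable feature matrix + labels for one pair population."""

    X: np.ndarray                      # (n_pairs, 4*n_osv^2)
    y: np.ndarray                      # (n_pairs,), Hartree
    keys: list = field(default_factory=list)
    train_mask: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("feature/label count mismatch")

    def __len__(self):
        return self.X.shape[0]


def split_pair_data(feature_sets: list[FeatureSet],
                    labels: list[PairEnergyTable]
                    ) -> tuple[PairDataset, PairDataset]:
    """Assemble (diagonal, off-diagonal) datasets from featurized molecules.

    Every kept pair must have a label; mismatches raise with the offending
    keys listed.
    """
    Xd, yd, kd, Xo, yo, ko = [], [], [], [], [], []
    for m, (fs, tab) in enumerate(zip(feature_sets, labels)):
        tab.check_keys(fs.keys + fs.screened_out)
        for f in fs.features:
            row = f.flat()
            if f.key.is_diagonal:
                Xd.append(row)
                yd.append(tab[f.key])
                kd.append((m, f.key))
            else:
                Xo.append(row)
                yo.append(tab[f.key])
                ko.append((m, f.key))
    return (PairDataset(np.array(Xd), np.array(yd), kd),
            PairDataset(np.array(Xo), np.array(yo), ko))


class PairMLPRegressor(RegressorMixin, BaseEstimator):
    """MLP pair-energy regressor with MAE loss (one pair population).

    Parameters mirror the reference training protocol: 10 hidden layers of
    50 ReLU units, Adam with batch size 64, a two-stage learning-rate
    schedule, and element-wise feature / scalar label standardization fitted
    on the training split only.  Deterministic for a fixed `seed`.
    """

    def __init__(self, n_hidden_layers: int = 10, hidden_width: int = 50,
                 activation: str = "relu",
                 schedule: tuple = BASE_SCHEDULE, batch_size: int = 64,
                 validation_fraction: float = 0.1, seed: int = 0,
                 standardize: bool = True):
        self.n_hidden_layers = n_hidden_layers
        self.hidden_width = hidden_width
        self.activation = activation
        self.schedule = schedule
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        if X.shape[0] < 1:
            raise ValueError("empty training set")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.seed)

        n = X.shape[0]
        n_val = int(round(self.validation_fraction * n)) \
            if self.validation_fraction else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            raise ValueError("validation split leaves no training data")
        self.standardizer_ = Standardizer()
        if self.standardize and len(tr_idx) >= 2:
            self.standardizer_.fit(X[tr_idx], y[tr_idx])
        else:
            self.standardizer_.feature_mean = np.zeros(X.shape[1])
            self.standardizer_.feature_scale = np.ones(X.shape[1])
            self.standardizer_.label_mean = 0.0
            self.standardizer_.label_scale = 1.0
        Xs = self.standardizer_.transform_X(X)
        ys = self.standardizer_.transform_y(y)

        self.spec_ = NetworkSpec(input_dim=X.shape[1],
                                 n_hidden_layers=self.n_hidden_layers,
                                 hidden_width=self.hidden_width,
                                 activation=self.activation, seed=self.seed)
        self.weights_, self.biases_ = init_base_params(self.spec_, rng)
        Xv = Xs[val_idx] if n_val else None
        yv = ys[val_idx] if n_val else None
        self.log_ = train_loop(self.weights_, self.biases_, Xs[tr_idx],
                               ys[tr_idx], None, {"W": True, "b": True},
                               self.schedule, self.batch_size, rng,
                               X_val=Xv, y_val=yv)
        self.train_mae_ = self.log_.train_loss[-1] if self.log_.train_loss \
            else np.nan
        self.val_mae_ = self.log_.val_loss[-1] if self.log_.val_loss \
            else np.nan
        return self

    def predict(self, X):
        """Pair energies in Hartree (de-standardized)."""
        check_is_fitted(self, "weights_")
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected (n, {self.n_features_in_}) features, "
                f"got {X.shape}")
        out = forward(self.weights_, self.biases_,
                      self.standardizer_.transform_X(X))
        return self.standardizer_.inverse_y(out.ravel())

    def predict_standardized(self, X):
        check_is_fitted(self, "weights_")
        return forward(self.weights_, self.biases_,
                       self.standardizer_.transform_X(X)).ravel()


def fit_standardizer(train_features: np.ndarray,
                     train_labels: np.ndarray) -> Standardizer:
    """Standardization statistics from the training split only."""
    return Standardizer().fit(train_features, train_labels)


def train_base(diag_data: PairDataset, offdiag_data: PairDataset,
               n_repeats: int = 3, seed: int = 0,
               **estimator_kwargs) -> tuple[PairMLPRegressor,
                                            PairMLPRegressor]:
    """Train the diagonal and off-diagonal base models.

    Runs `n_repeats` seeded repetitions per population and keeps the model
    with the lowest validation MAE (standardized units).
    """
    out = []
    for data in (diag_data, offdiag_data):
        if len(data) == 0:
            raise ValueError("empty pair dataset")
        best = None
        for r in range(n_repeats):
            est = PairMLPRegressor(seed=seed + 1000 * r, **estimator_kwargs)
            est.fit(data.X, data.y)
            score = est.val_mae_ if np.isfinite(est.val_mae_) \
                else est.train_mae_
            if best is None or score < best[0]:
                best = (score, est)
        out.append(best[1])
    return out[0], out[1]


@dataclass
class PairEnergyFunctional:
    """Diagonal + off-diagonal regressors acting as one energy functional."""

    model_diag: PairMLPRegressor
    model_offdiag: PairMLPRegressor

    def predict_pairs(self, features: FeatureSet | list[PairFeature]
                      ) -> dict[PairKey, float]:
        feats = features.features if isinstance(features, FeatureSet) \
            else list(features)
        if not feats:
            return {}
        out: dict[PairKey, float] = {}
        for is_diag, model in ((True, self.model_diag),
                               (False, self.model_offdiag)):
            sel = [f for f in feats if f.key.is_diagonal == is_diag]
            if not sel:
                continue
            X = np.stack([f.flat() for f in sel])
            pred = model.predict(X)
            for f, p in zip(sel, pred):
                out[f.key] = float(p)
        return out

    def predict_total(self, pair_predictions: dict[PairKey, float],
                      e_hf: float | None = None):
        """E_c = Σ predictions; screened-out pairs contribute exactly 0."""
        e_c = float(sum(pair_predictions.values()))
        if e_hf is None:
            return e_c
        return e_c, e_hf + e_c


def predict_pairs(model_d: PairMLPRegressor, model_o: PairMLPRegressor,
                  features) -> dict[PairKey, float]:
    return PairEnergyFunctional(model_d, model_o).predict_pairs(features)


def predict_total(pair_predictions: dict[PairKey, float],
                  e_hf: float | None = None):
    return PairEnergyFunctional(None, None).predict_total(pair_predictions,
                                                          e_hf)
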