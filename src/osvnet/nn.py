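"""Feed-forward network engine for the pair-energy functional.

A deliberately small, dependency-free MLP implementation (numpy forward +
manual reverse-mode gradients, Adam optimizer) supporting the adapters used
for fine-tuning:

* low-rank weight updates ΔW = B·A per layer (A zero-init, B He-uniform), so
  every effective weight is W0 + B·A with W0 frozen;
* an optional input shortcut feeding x^{n-1} + x^n to the LoRA branch of
  dimension-matched layers (W0 still sees x^n);
* a residual head, a linear map from the last hidden activation added to the
  scalar output, zero-initialized;
* additive bias offsets (bias-only fine-tuning) leaving b0 untouched.

At initialization every adapter contributes exactly zero, so an adapted
network reproduces the base network bitwise.  Training minimizes the mean
absolute error over pairs with equal weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one pair-energy MLP."""

    input_dim: int
    n_hidden_layers: int = 10
    hidden_width: int = 50
    activation: str = "relu"
    seed: int = 0

    def layer_dims(self) -> list[tuple[int, int]]:
        """(d_in, d_out) of every weight-bearing layer, input to output."""
        dims = [self.input_dim] + [self.hidden_width] * self.n_hidden_layers
        return list(zip(dims, dims[1:])) + [(self.hidden_width, 1)]


def he_uniform(rng: np.random.Generator, d_out: int, d_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / d_in)
    return rng.uniform(-limit, limit, size=(d_out, d_in))


def init_base_params(spec: NetworkSpec, rng: np.random.Generator):
    """He-uniform weights, zero biases."""
    W, b = [], []
    for d_in, d_out in spec.layer_dims():
        W.append(he_uniform(rng, d_out, d_in))
        b.append(np.zeros(d_out))
    return W, b


@dataclass
class Adapters:
    """Fine-tuning degrees of freedom attached to a frozen base network."""

    lora_A: list[np.ndarray] | None = None   # (r, d_in) per layer, zero-init
    lora_B: list[np.ndarray] | None = None   # (d_out, r) per layer
    shortcut: bool = False                    # ResLoRA input shortcut
    head_W: np.ndarray | None = None          # (1, hidden_width)
    head_b: np.ndarray | None = None          # (1,)
    delta_b: list[np.ndarray] | None = None   # additive bias offsets

    def has_lora(self) -> bool:
        return self.lora_A is not None

    def has_head(self) -> bool:
        return self.head_W is not None


def make_lora(spec: NetworkSpec, rank: int, rng: np.random.Generator,
              shortcut: bool) -> tuple[list[np.ndarray], list[np.ndarray]]:
    dims = spec.layer_dims()
    if rank < 1:
        raise ValueError("LoRA rank must be >= 1")
    hidden_min = min(min(d) for d in dims[:-1])
    if rank > hidden_min:
        raise ValueError(
            f"LoRA rank {rank} exceeds smallest hidden dimension "
            f"{hidden_min}")
    A, B = [], []
    for d_in, d_out in dims:
        r_eff = min(rank, d_in, d_out)   # the scalar output layer caps at 1
        A.append(np.zeros((r_eff, d_in)))
        B.append(he_uniform(rng, d_out, r_eff))
    return A, B


def _shortcut_applies(k: int, dims: list[tuple[int, int]]) -> bool:
    """Shortcut only between dimension-matched layers (never the first)."""
    return k > 0 and dims[k][0] == dims[k - 1][0]


def forward(W, b, X, adapters: Adapters | None = None, cache: bool = False):
    """Forward pass; returns predictions (n, 1) and, optionally, the
    per-layer inputs/pre-activations needed for backprop."""
    ad = adapters or Adapters()
    L = len(W)
    dims = [(w.shape[1], w.shape[0]) for w in W]
    x = np.asarray(X, float)
    xs = [x]          # layer inputs x^0 .. x^{L-1}, then final z appended
    zs = []
    x_prev = None
    for k in range(L):
        z = x @ W[k].T + b[k]
        if ad.delta_b is not None:
            z = z + ad.delta_b[k]
        if ad.has_lora():
            lx = x + x_prev if (ad.shortcut and _shortcut_applies(k, dims)) \
                else x
            z = z + (lx @ ad.lora_A[k].T) @ ad.lora_B[k].T
        x_prev = x
        if k < L - 1:
            x = np.maximum(z, 0.0)
            xs.append(x)
        zs.append(z)
    out = zs[-1]
    if ad.has_head():
        out = out + xs[-1] @ ad.head_W.T + ad.head_b
    if cache:
        return out, (xs, zs)
    return out


def backward(W, b, X, y, adapters: Adapters | None, trainable: dict):
    """Mean-absolute-error loss and gradients for the trainable tensors.

    `trainable` flags: {"W", "b", "lora", "head", "delta_b"}.  Returns
    (loss, grads) with grads keyed like the parameter containers.
    """
    ad = adapters or Adapters()
    L = len(W)
    dims = [(w.shape[1], w.shape[0]) for w in W]
    y = np.asarray(y, float).reshape(-1, 1)
    pred, (xs, zs) = forward(W, b, X, ad, cache=True)
    n = y.shape[0]
    resid = pred - y
    loss = float(np.mean(np.abs(resid)))
    g_out = np.sign(resid) / n

    grads = {
        "W": [None] * L, "b": [None] * L,
        "A": [None] * L, "B": [None] * L,
        "head_W": None, "head_b": None, "delta_b": [None] * L,
    }
    dx = [np.zeros_like(xi) for xi in xs]      # grads wrt layer inputs
    if ad.has_head():
        if trainable.get("head"):
            grads["head_W"] = g_out.T @ xs[-1]
            grads["head_b"] = g_out.sum(axis=0)
        dx[L - 1] += g_out @ ad.head_W
    dz = g_out                                  # output layer is linear
    for k in range(L - 1, -1, -1):
        if trainable.get("W"):
            grads["W"][k] = dz.T @ xs[k]
        if trainable.get("b") or trainable.get("delta_b"):
            gb = dz.sum(axis=0)
            if trainable.get("b"):
                grads["b"][k] = gb
            if trainable.get("delta_b"):
                grads["delta_b"][k] = gb
        dx[k] += dz @ W[k]
        if ad.has_lora():
            sc = ad.shortcut and _shortcut_applies(k, dims)
            lx = xs[k] + xs[k - 1] if sc else xs[k]
            if trainable.get("lora"):
                grads["B"][k] = dz.T @ (lx @ ad.lora_A[k].T)
                grads["A"][k] = ad.lora_B[k].T @ dz.T @ lx
            dlx = (dz @ ad.lora_B[k]) @ ad.lora_A[k]
            dx[k] += dlx
            if sc:
                dx[k - 1] += dlx
        if k > 0:
            dz = dx[k] * (zs[k - 1] > 0.0)
    return loss, grads


class Adam:
    """Standard Adam over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainLog:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def _collect(trainable: dict, W, b, ad: Adapters):
    """Flat view of the trainable arrays and a matching grad extractor."""
    params, getters = [], []
    if trainable.get("W"):
        params += W
        getters += [("W", k) for k in range(len(W))]
    if trainable.get("b"):
        params += b
        getters += [("b", k) for k in range(len(b))]
    if trainable.get("lora"):
        params += ad.lora_A + ad.lora_B
        getters += [("A", k) for k in range(len(ad.lora_A))]
        getters += [("B", k) for k in range(len(ad.lora_B))]
    if trainable.get("delta_b"):
        params += ad.delta_b
        getters += [("delta_b", k) for k in range(len(ad.delta_b))]
    if trainable.get("head"):
        params += [ad.head_W, ad.head_b]
        getters += [("head_W", None), ("head_b", None)]
    return params, getters


def train_loop(W, b, X, y, adapters: Adapters | None, trainable: dict,
               schedule, batch_size: int, rng: np.random.Generator,
               X_val=None, y_val=None, log_every: int = 1) -> TrainLog:
    """Mini-batch Adam training of the MAE pair loss, in place.

    `schedule` is a sequence of (epochs, learning_rate) stages; the Adam
    moments persist across stages.
    """
    ad = adapters or Adapters()
    params, getters = _collect(trainable, W, b, ad)
    if not params:
        raise ValueError("no trainable parameters selected")
    opt = Adam(params)
    n = X.shape[0]
    log = TrainLog()
    epoch = 0
    for n_epochs, lr in schedule:
        for _ in range(n_epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = perm[start:start + batch_size]
                loss, grads = backward(W, b, X[idx], y[idx], ad, trainable)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, "
                        f"batch {start // batch_size}")
                flat = [grads[name][k] if k is not None else grads[name]
                        for name, k in getters]
                opt.step(flat, lr)
                losses.append(loss)
            epoch += 1
            if epoch % log_every == 0:
                log.epochs.append(epoch)
                log.train_loss.append(float(np.mean(losses)))
                if X_val is not None and len(X_val):
                    pv = forward(W, b, X_val, ad)
                    log.val_loss.append(
                        float(np.mean(np.abs(pv.ravel() - y_val.ravel()))))
    return log


class Standardizer:
    """Element-wise feature and scalar label standardization.

    Zero-variance elements have their scale clamped to 1 (with a warning) so
    the transform stays invertible.
    """

    def __init__(self):
        self.feature_mean = None
        self.feature_scale = None
        self.label_mean = None
        self.label_scale = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Standardizer":
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training pairs to standardize")
        self.feature_mean = X.mean(axis=0)
        scale = X.std(axis=0)
        n_zero = int(np.sum(scale < 1e-12))
        if n_zero:
            warnings.warn(f"{n_zero} zero-variance feature elements; "
                          "scale clamped to 1", stacklevel=2)
        self.feature_scale = np.where(scale < 1e-12, 1.0, scale)
        self.label_mean = float(y.mean())
        ls = float(y.std())
        if ls < 1e-12:
            warnings.warn("zero-variance labels; scale clamped to 1",
                          stacklevel=2)
            ls = 1.0
        self.label_scale = ls
        return self

    def transform_X(self, X) -> np.ndarray:
        return (np.asarray(X, float) - self.feature_mean) / self.feature_scale

    def inverse_X(self, Xs) -> np.ndarray:
        return np.asarray(Xs, float) * self.feature_scale + self.feature_mean

    def transform_y(self, y) -> np.ndarray:
        return (np.asarray(y, float) - self.label_mean) / self.label_scale

    def inverse_y(self, ys) -> np.ndarray:
        return np.asarray(ys, float) * self.label_scale + self.label_mean
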