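"""Fine-tuning family: identities, freeze contracts, capacity, Δ-ML."""

import numpy as np
import pytest

from osvnet.finetune import (DeltaMLRegressor, FineTunedPairMLP,
                             FineTuneSpec, attach_lora, attach_residual_head,
                             count_trainable, select_bitfit, train_delta_ml)
from osvnet.models import PairMLPRegressor
from osvnet.nn import Adapters, forward

ALL_METHODS = ("full", "bitfit", "bitfit_r", "lora_r", "reslora_r")


@pytest.mark.parametrize("method", ALL_METHODS)
def test_initialized_tuned_model_reproduces_base_bitwise(method, tiny_base):
    base, X, _ = tiny_base
    tuned = FineTunedPairMLP(base, method=method, rank=2).initialize()
    assert np.array_equal(tuned.predict(X), base.predict(X))


@pytest.mark.parametrize("method,frozen", [
    ("lora_r", "weights"), ("reslora_r", "weights"),
    ("bitfit", "weights"), ("bitfit_r", "weights"),
])
def test_freeze_contracts_hold_bitwise_after_tuning(method, frozen,
                                                    tiny_base):
    base, X, y = tiny_base
    w_before = [w.copy() for w in base.weights_]
    b_before = [bk.copy() for bk in base.biases_]
    tuned = FineTunedPairMLP(base, method=method, rank=1,
                             schedule=((5, 1e-3),), seed=0)
    tuned.fit(X, y)
    for w0, w1 in zip(w_before, base.weights_):
        assert np.array_equal(w0, w1)          # W frozen for all four
    for b0, b1 in zip(b_before, base.biases_):
        assert np.array_equal(b0, b1)          # b0 itself never mutated


def test_zero_epochs_leave_model_unchanged(tiny_base):
    base, X, y = tiny_base
    tuned = FineTunedPairMLP(base, method="lora_r", schedule=(), seed=0)
    tuned.fit(X, y)
    assert np.array_equal(tuned.predict(X), base.predict(X))


def test_finetuning_reduces_training_loss(tiny_base):
    base, X, y = tiny_base
    y_shift = y + 0.005
    before = float(np.mean(np.abs(base.predict(X) - y_shift)))
    tuned = FineTunedPairMLP(base, method="lora_r", rank=1,
                             schedule=((60, 1e-3),), seed=0).fit(X, y_shift)
    after = float(np.mean(np.abs(tuned.predict(X) - y_shift)))
    assert after < before


def test_hand_set_residual_head_adds_activation_component(tiny_base):
    """Head W^R = e1, b^R = 0.1 adds activation_1 + 0.1 (standardized)."""
    base, X, _ = tiny_base
    tuned = attach_residual_head(base)
    width = base.spec_.hidden_width
    tuned.adapters_.head_W = np.zeros((1, width))
    tuned.adapters_.head_W[0, 0] = 1.0
    tuned.adapters_.head_b = np.array([0.1])
    Xs = base.standardizer_.transform_X(X[:4])
    _, (xs, _) = forward(base.weights_, base.biases_, Xs, None, cache=True)
    act1 = xs[-1][:, 0]
    expected_std = forward(base.weights_, base.biases_, Xs).ravel() \
        + act1 + 0.1
    expected = base.standardizer_.inverse_y(expected_std)
    assert np.allclose(tuned.predict(X[:4]), expected, atol=1e-12)


def test_zeroing_trained_head_recovers_base(tiny_base):
    base, X, y = tiny_base
    tuned = FineTunedPairMLP(base, method="bitfit_r",
                             schedule=((5, 1e-3),), seed=0).fit(X, y)
    tuned.adapters_.head_W[:] = 0.0
    tuned.adapters_.head_b[:] = 0.0
    tuned.adapters_.delta_b = [np.zeros_like(d)
                               for d in tuned.adapters_.delta_b]
    assert np.array_equal(tuned.predict(X), base.predict(X))


def test_shortcut_forward_matches_hand_computation():
    """Two equal-width layers with hand-set weights: the LoRA branch of the
    second layer must consume x^0 + x^1."""
    rng = np.random.default_rng(0)
    W = [np.array([[1.0, -1.0], [0.5, 0.5]]), np.array([[2.0, 1.0]])]
    b = [np.array([0.1, -0.1]), np.array([0.05])]
    A = [np.zeros((1, 2)), np.array([[0.3, -0.2]])]
    B = [np.ones((2, 1)), np.array([[0.7]])]
    ad = Adapters(lora_A=A, lora_B=B, shortcut=True)
    x0 = np.array([[0.4, 0.9]])
    z1 = x0 @ W[0].T + b[0] + (x0 @ A[0].T) @ B[0].T   # first layer: no sum
    x1 = np.maximum(z1, 0.0)
    lx = x1 + x0                                        # shortcut input
    z2 = x1 @ W[1].T + b[1] + (lx @ A[1].T) @ B[1].T
    out = forward(W, b, x0, ad)
    assert np.allclose(out, z2, atol=1e-14)


def test_full_rank_lora_matches_full_finetuning_capacity(tiny_base):
    """With rank = hidden width, LoRA can express any ΔW: after identical
    short training runs the losses agree within 10%."""
    base, X, y = tiny_base
    y_t = y + 0.01 * np.tanh(X[:, 0])
    width = base.spec_.hidden_width
    losses = {}
    for method, rank in (("full", 1), ("lora_r", width)):
        tuned = FineTunedPairMLP(base, method=method, rank=rank,
                                 schedule=((150, 1e-3),), seed=0).fit(X, y_t)
        losses[method] = float(np.mean(np.abs(tuned.predict(X) - y_t)))
    assert losses["lora_r"] <= losses["full"] * 1.1


# ----------------------------------------------------------- bookkeeping

def test_trainable_parameter_counts_by_construction(reference_base_256):
    base = reference_base_256
    counts = {m: count_trainable(FineTunedPairMLP(base, method=m,
                                                  rank=1).initialize())
              for m in ALL_METHODS}
    assert counts["full"]["fraction"] == 1.0
    assert counts["bitfit"]["trainable"] == 501      # Σ layer widths
    # r(d_in + d_out) per layer + head (50 + 1): 306 + 900 + 51 + 51
    assert counts["lora_r"]["trainable"] == 1308
    assert counts["reslora_r"]["trainable"] == 1308
    assert counts["bitfit_r"]["trainable"] == 501 + 51
    assert counts["lora_r"]["total_base"] == 35851


def test_lora_rank_exceeding_hidden_dimension_rejected(tiny_base):
    base, _, _ = tiny_base
    with pytest.raises(ValueError, match="rank"):
        attach_lora(base, rank=21)


def test_spec_method_roster_is_closed():
    with pytest.raises(ValueError, match="unknown method"):
        FineTuneSpec(method="adalora")


# ----------------------------------------------------------------- delta-ML

def test_delta_ml_combined_prediction_is_base_plus_delta(tiny_base):
    base, X, y = tiny_base
    model = train_delta_ml(X, y + 0.003, base, seed=0, n_hidden_layers=2,
                           hidden_width=10, schedule=((30, 1e-3),))
    combined = model.predict(X)
    assert np.allclose(combined,
                       base.predict(X) + model.delta_model_.predict(X),
                       atol=1e-12)


def test_delta_ml_on_zero_residuals_stays_near_base(tiny_base):
    """A perfect base gives all-zero residual labels; the Δ network must
    learn ≈ 0 on its (clamped, unit) label scale."""
    base, X, _ = tiny_base
    y_perfect = base.predict(X)
    with pytest.warns(UserWarning, match="zero-variance labels"):
        model = train_delta_ml(X, y_perfect, base, seed=0,
                               n_hidden_layers=2, hidden_width=10,
                               schedule=((200, 1e-3), (100, 1e-4)))
    dev = np.abs(model.predict(X) - y_perfect)
    assert np.mean(dev) < 0.02      # standardized units (scale clamped to 1)
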