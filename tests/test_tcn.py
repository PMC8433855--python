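"""Dilated causal convolution, residual blocks and the assembled TCN:
oracle equivalence, exact causality, length preservation, receptive field."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respredict import ConfigurationError, TCNConfig, TCNModel, causal_dilated_conv, receptive_field, tcn_forward
from respredict.tcn import _ResidualBlock, measure_receptive_field


def brute_force_dilated_conv(x, kernel, d):
    """Independent double-loop evaluation of y[t] = sum_i kernel[i]*x[t-i*d]."""
    T, k = len(x), len(kernel)
    y = np.zeros(T)
    for t in range(T):
        for i in range(k):
            j = t - i * d
            if j >= 0:
                y[t] += kernel[i] * x[j]
    return y


def test_hand_computed_example():
    # current tap + one past tap at dilation 2
    np.testing.assert_allclose(
        causal_dilated_conv([1, 2, 3, 4], [1, 1], d=2), [1, 2, 4, 6])


def test_identity_kernel():
    x = np.arange(10.0)
    for d in (1, 3, 7):
        np.testing.assert_array_equal(causal_dilated_conv(x, [1.0], d), x)


def test_empty_input_rejected():
    with pytest.raises(ConfigurationError):
        causal_dilated_conv([], [1.0], 1)


@given(st.integers(0, 2**32 - 1), st.integers(1, 5), st.integers(1, 8), st.integers(1, 64))
@settings(max_examples=100, deadline=None)
def test_conv_matches_brute_force_oracle(seed, k, d, T):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=T)
    kernel = rng.normal(size=k)
    np.testing.assert_allclose(
        causal_dilated_conv(x, kernel, d), brute_force_dilated_conv(x, kernel, d),
        atol=1e-12)


def _zeroed_block(channels=4, activation="relu", use_residual=True):
    cfg = TCNConfig(n_layers=1, filter_size=3, input_channels=channels,
                    channels_per_layer=channels, activation=activation,
                    use_residual=use_residual, input_window=8)
    block = _ResidualBlock(channels, channels, cfg, dilation=1,
                           rng=np.random.default_rng(0), name="b")
    for conv, _, _ in block.stages:
        conv.W.value[...] = 0.0
        conv.b.value[...] = 0.0
    return block


def test_residual_block_with_zero_branch_identity_activation():
    x = np.random.default_rng(1).normal(size=(2, 8, 4))
    out = _zeroed_block(activation="identity").forward(x)
    np.testing.assert_array_equal(out, x)  # O = Act(X + 0) = X


def test_residual_block_with_zero_branch_relu():
    x = np.random.default_rng(2).normal(size=(2, 8, 4))
    out = _zeroed_block(activation="relu").forward(x)
    np.testing.assert_array_equal(out, np.maximum(x, 0.0))


def test_residual_block_matches_primitive_composition():
    """A random small block equals an independent re-composition of the
    primitive ops: per-channel dilated conv sums, activation, skip add."""
    cfg = TCNConfig(n_layers=1, filter_size=3, input_channels=2,
                    channels_per_layer=2, activation="relu", input_window=12,
                    convs_per_block=2, seed=9)
    block = _ResidualBlock(2, 2, cfg, dilation=2, rng=np.random.default_rng(9), name="b")
    x = np.random.default_rng(3).normal(size=(1, 12, 2))

    def conv_by_oracle(conv, xin):
        out = np.zeros((12, conv.c_out))
        for o in range(conv.c_out):
            for c in range(conv.c_in):
                out[:, o] += brute_force_dilated_conv(xin[0, :, c], conv.W.value[:, c, o], conv.d)
            out[:, o] += conv.b.value[o]
        return out[None]

    f = x
    for conv, _, _ in block.stages:
        f = np.maximum(conv_by_oracle(conv, f), 0.0)
    expected = np.maximum(x + f, 0.0)
    np.testing.assert_allclose(block.forward(x), expected, atol=1e-12)


def test_shape_mismatch_without_projection_rejected():
    model = TCNModel(TCNConfig(n_layers=2, filter_size=3, input_window=10,
                               input_channels=9, channels_per_layer=8))
    with pytest.raises(ConfigurationError):
        model.forward(np.zeros((1, 10, 4)))  # wrong channel count
    with pytest.raises(ConfigurationError):
        model.forward(np.zeros((1, 7, 9)))   # wrong window length


def test_network_causality_exact():
    """Perturbing inputs at positions > t leaves every level's features at
    positions <= t unchanged, exactly."""
    cfg = TCNConfig(n_layers=3, filter_size=3, input_window=32, input_channels=4,
                    channels_per_layer=8, seed=5)
    model = TCNModel(cfg)
    rng = np.random.default_rng(7)
    x = rng.normal(size=(1, 32, 4))
    t = 17  # 0-based: positions t+1.. are the future
    x2 = x.copy()
    x2[:, t + 1:, :] += rng.normal(size=x2[:, t + 1:, :].shape)
    _, hidden_a = model.forward(x, return_hidden=True)
    _, hidden_b = model.forward(x2, return_hidden=True)
    for ha, hb in zip(hidden_a, hidden_b):
        np.testing.assert_array_equal(ha[:, :t + 1, :], hb[:, :t + 1, :])


def test_hidden_layers_preserve_length():
    cfg = TCNConfig(n_layers=4, filter_size=5, input_window=20, input_channels=9,
                    channels_per_layer=8)
    model = TCNModel(cfg)
    _, hidden = model.forward(np.zeros((2, 20, 9)), return_hidden=True)
    assert [h.shape[1] for h in hidden] == [20] * 4


def test_seeded_model_is_deterministic():
    cfg = TCNConfig(n_layers=2, filter_size=3, input_window=10, input_channels=6,
                    channels_per_layer=8, seed=42)
    x = np.random.default_rng(0).normal(size=(10, 6))
    np.testing.assert_array_equal(TCNModel(cfg).predict(x), TCNModel(cfg).predict(x))
    assert not np.array_equal(
        TCNModel(cfg).predict(x),
        TCNModel(dataclasses.replace(cfg, seed=43)).predict(x))


def test_zeroed_readout_predicts_its_bias():
    cfg = TCNConfig(n_layers=2, filter_size=3, input_window=10, input_channels=6,
                    channels_per_layer=8, seed=1)
    model = TCNModel(cfg)
    model.readout.W.value[...] = 0.0
    model.readout.b.value[...] = (1.0, 2.0, 3.0)
    rng = np.random.default_rng(5)
    for _ in range(3):
        np.testing.assert_array_equal(model.predict(rng.normal(size=(10, 6))), [1.0, 2.0, 3.0])


def test_tcn_forward_functional_surface():
    cfg = TCNConfig(n_layers=1, filter_size=2, input_window=5, input_channels=3,
                    channels_per_layer=4, seed=0)
    model = TCNModel(cfg)
    w = np.random.default_rng(1).normal(size=(5, 3))
    np.testing.assert_array_equal(tcn_forward(model, w), model.predict(w))


@pytest.mark.parametrize("cfg, expected", [
    (TCNConfig(n_layers=1, filter_size=2, convs_per_block=1), 2),
    (TCNConfig(n_layers=5, filter_size=9), 497),
    (TCNConfig(n_layers=4, filter_size=1), 1),
    (TCNConfig(n_layers=3, filter_size=3), 29),
])
def test_receptive_field_closed_form(cfg, expected):
    assert receptive_field(cfg) == expected


@pytest.mark.parametrize("n, k, convs", [(2, 3, 2), (3, 2, 1), (4, 3, 2), (5, 9, 2)])
def test_receptive_field_agrees_with_probe(n, k, convs):
    cfg = TCNConfig(n_layers=n, filter_size=k, convs_per_block=convs,
                    input_channels=3, channels_per_layer=4, seed=0)
    assert measure_receptive_field(cfg) == receptive_field(cfg)


def test_residual_toggle_changes_only_projection_parameters():
    kw = dict(n_layers=3, filter_size=3, input_window=10, input_channels=9,
              channels_per_layer=8, seed=0)
    with_res = TCNModel(TCNConfig(use_residual=True, **kw))
    without = TCNModel(TCNConfig(use_residual=False, **kw))
    # only level 1 needs a 1x1 projection (9 -> 8 channels): 9*8 + 8 params
    assert with_res.n_parameters - without.n_parameters == 9 * 8 + 8


def test_gradients_match_finite_differences():
    cfg = TCNConfig(n_layers=2, filter_size=3, input_window=8, input_channels=2,
                    channels_per_layer=3, seed=3, activation="identity")
    model = TCNModel(cfg)
    rng = np.random.default_rng(4)
    x = rng.normal(size=(4, 8, 2))
    y = rng.normal(size=(4, 3))
    model.loss_and_grads(x, y)
    eps = 1e-6
    for p in model.params()[:4]:
        flat = p.value.ravel()
        g = p.grad.ravel()
        for idx in (0, flat.size // 2):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = float(np.mean((model.forward(x) - y) ** 2))
            flat[idx] = orig - eps
            lm = float(np.mean((model.forward(x) - y) ** 2))
            flat[idx] = orig
            assert g[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-8)


def test_checkpoint_round_trip(tmp_path):
    cfg = TCNConfig(n_layers=2, filter_size=3, input_window=10, input_channels=6,
                    channels_per_layer=8, seed=8)
    model = TCNModel(cfg)
    x = np.random.default_rng(2).normal(size=(10, 6))
    path = tmp_path / "m.npz"
    model.save(path)
    loaded = TCNModel.load(path)
    np.testing.assert_array_equal(loaded.predict(x), model.predict(x))
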