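"""Temporal convolutional network for respiratory motion forecasting.

The network stacks residual levels of dilated causal convolutions. Level
l (1-based) uses dilation d = dilation_base**(l-1), so the lowest level
samples every input and deeper levels reach exponentially further back.
Each level applies ``convs_per_block`` causal convolutions (each followed
by an activation and optional dropout) and, when residual connections are
enabled, adds the level's input back before a final activation:

    O = Activation(X + F(X)),

with a 1x1 projection on the skip path when channel counts differ.
Every hidden layer preserves the temporal length of the input window, and
no output at time t depends on any input later than t. The prediction is
a linear readout of the final time step's feature vector, emitting the
(SI, AP, LR) tumor position jointly.

With two convolutions per level and dilation base 2, the receptive field
is 1 + 2*(k-1)*(2**n - 1) samples — 497 for the selected n=5, k=9, which
far exceeds the selected 15-sample input window; the padded zeros simply
fill the unused history.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ._checkpoint import load_checkpoint, restore_params, save_checkpoint
from ._layers import CausalConv1d, Dropout, Linear, Param, make_activation
from .errors import ConfigurationError


@dataclass(frozen=True)
class TCNConfig:
    """Architecture and initialization hyperparameters.

    Defaults are the grid-search-selected values: 5 residual levels,
    filter size 9, 15-sample input window.
    """

    n_layers: int = 5
    filter_size: int = 9
    input_window: int = 15
    input_channels: int = 9
    channels_per_layer: int = 32
    dilation_base: int = 2
    convs_per_block: int = 2
    dropout_rate: float = 0.0
    use_residual: bool = True
    activation: str = "relu"
    output_dim: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1 or self.filter_size < 1 or self.input_window < 1:
            raise ConfigurationError("n_layers, filter_size and input_window must be >= 1")
        if self.dilation_base < 1 or self.convs_per_block < 1:
            raise ConfigurationError("dilation_base and convs_per_block must be >= 1")
        if self.channels_per_layer < 1 or self.input_channels < 1:
            raise ConfigurationError("channel counts must be >= 1")

    def dilation(self, level: int) -> int:
        """Dilation of 1-based level ``level``: base**(level-1)."""
        return self.dilation_base ** (level - 1)


def causal_dilated_conv(x, kernel, d: int) -> np.ndarray:
    """Single-channel dilated causal convolution.

    y[t] = sum_{i=0..k-1} kernel[i] * x[t - i*d], with x[j] = 0 for j < 1
    (zero left-padding), so the output has the input's length and never
    reads the future.
    """
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ConfigurationError("x must be a non-empty 1-D sequence")
    if kernel.ndim != 1 or kernel.size == 0 or d < 1:
        raise ConfigurationError("kernel must be non-empty and d >= 1")
    T, k = x.size, kernel.size
    xp = np.concatenate([np.zeros((k - 1) * d), x])
    y = np.zeros(T)
    for i in range(k):
        start = (k - 1) * d - i * d
        y += kernel[i] * xp[start:start + T]
    return y


class _ResidualBlock:
    """One level: F = [causal conv -> activation -> dropout] * convs_per_block,
    combined as Activation(skip + F(x)) (or Activation(F(x)) in ablation mode)."""

    def __init__(self, c_in: int, c_out: int, config: TCNConfig, dilation: int,
                 rng: np.random.Generator, name: str):
        self.use_residual = config.use_residual
        self.stages = []
        ci = c_in
        for j in range(config.convs_per_block):
            conv = CausalConv1d(ci, c_out, config.filter_size, dilation, rng,
                                name=f"{name}.conv{j}")
            self.stages.append((conv, make_activation(config.activation),
                                Dropout(config.dropout_rate, rng)))
            ci = c_out
        self.proj = None
        if self.use_residual and c_in != c_out:
            self.proj = CausalConv1d(c_in, c_out, 1, 1, rng, name=f"{name}.proj")
        self.out_act = make_activation(config.activation)

    def params(self) -> list[Param]:
        ps = []
        for conv, _, _ in self.stages:
            ps.extend(conv.params())
        if self.proj is not None:
            ps.extend(self.proj.params())
        return ps

    def forward(self, x, train=False):
        f = x
        for conv, act, drop in self.stages:
            f = drop.forward(act.forward(conv.forward(f, train), train), train)
        if self.use_residual:
            skip = self.proj.forward(x, train) if self.proj is not None else x
            pre = skip + f
        else:
            pre = f
        return self.out_act.forward(pre, train)

    def backward(self, dy):
        dpre = self.out_act.backward(dy)
        df = dpre
        for conv, act, drop in reversed(self.stages):
            df = conv.backward(act.backward(drop.backward(df)))
        if self.use_residual:
            dskip = self.proj.backward(dpre) if self.proj is not None else dpre
            return df + dskip
        return df


class TCNModel:
    """Assembled network; weights initialized from ``config.seed``."""

    def __init__(self, config: TCNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks: list[_ResidualBlock] = []
        c_in = config.input_channels
        for level in range(1, config.n_layers + 1):
            self.blocks.append(
                _ResidualBlock(c_in, config.channels_per_layer, config,
                               config.dilation(level), rng, name=f"level{level}")
            )
            c_in = config.channels_per_layer
        self.readout = Linear(config.channels_per_layer, config.output_dim, rng, name="readout")

    # -- inference ---------------------------------------------------------

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for b in self.blocks:
            ps.extend(b.params())
        ps.extend(self.readout.params())
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def _check_window(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.config.input_window or x.shape[2] != self.config.input_channels:
            raise ConfigurationError(
                f"expected windows of shape (batch, {self.config.input_window}, "
                f"{self.config.input_channels}), got {np.asarray(x).shape}"
            )
        return x

    def forward(self, windows, train: bool = False, return_hidden: bool = False):
        """Predict (SI, AP, LR) for a batch of windows; optionally return
        every level's hidden sequence (for causality probing)."""
        x = self._check_window(windows)
        hidden = []
        for block in self.blocks:
            x = block.forward(x, train)
            hidden.append(x)
        self._last_shape = x.shape
        out = self.readout.forward(x[:, -1, :], train)
        if return_hidden:
            return out, hidden
        return out

    def predict(self, window) -> np.ndarray:
        """Deterministic inference for one window -> 3-vector (mm, normalized units)."""
        return self.forward(window)[0]

    # -- training ----------------------------------------------------------

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backprop from d(loss)/d(prediction); returns d(loss)/d(input window)."""
        dlast = self.readout.backward(dout)
        dx = np.zeros(self._last_shape)
        dx[:, -1, :] = dlast
        for block in reversed(self.blocks):
            dx = block.backward(dx)
        return dx

    def loss_and_grads(self, windows: np.ndarray, targets: np.ndarray) -> float:
        """Mean-squared-error cost; leaves gradients accumulated in params."""
        self.zero_grad()
        pred = self.forward(windows, train=True)
        r = pred - targets
        loss = float(np.mean(r * r))
        self.backward(2.0 * r / r.size)
        return loss

    def input_gradient(self, window) -> np.ndarray:
        """Gradient of the summed outputs w.r.t. one input window (inference mode)."""
        self.zero_grad()
        out = self.forward(window, train=False)
        return self.backward(np.ones_like(out))[0]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        save_checkpoint(path, "tcn", dataclasses.asdict(self.config), self.params())

    @classmethod
    def load(cls, path) -> "TCNModel":
        kind, cfg, arrays = load_checkpoint(path)
        if kind != "tcn":
            raise ConfigurationError(f"checkpoint holds a {kind!r} model, not a TCN")
        model = cls(TCNConfig(**cfg))
        restore_params(model.params(), arrays)
        return model


def tcn_forward(model: TCNModel, window) -> np.ndarray:
    """Functional forward pass: one (t_delay, C) window -> 3-vector."""
    return model.predict(window)


def receptive_field(config: TCNConfig) -> int:
    """Span of past samples that can influence one output (closed form).

    Each convolution at dilation d widens the field by (k-1)*d; summing
    over convs_per_block convolutions per level and dilations
    base**(0..n-1) gives 1 + convs_per_block*(k-1)*(base**n - 1)/(base - 1)
    (n*(k-1)*convs_per_block + 1 when base == 1).
    """
    k, n, b = config.filter_size, config.n_layers, config.dilation_base
    span = n if b == 1 else (b**n - 1) // (b - 1)
    return 1 + config.convs_per_block * (k - 1) * span


def measure_receptive_field(config: TCNConfig) -> int:
    """Measure the receptive field on an assembled network by an input probe.

    Builds the architecture with identity activations and constant positive
    weights (so no contribution can cancel or be gated off), feeds a window
    longer than the predicted field, and finds the earliest input position
    whose gradient on the final output is non-zero.
    """
    T = receptive_field(config) + 8
    probe_cfg = dataclasses.replace(config, activation="identity", dropout_rate=0.0,
                                    input_window=T)
    model = TCNModel(probe_cfg)
    for p in model.params():
        p.value[...] = 0.01
    grad = model.input_gradient(np.zeros((T, config.input_channels)))
    influential = np.flatnonzero(np.abs(grad).sum(axis=1) > 0)
    return T - int(influential[0])
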