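"""Stacked long short-term memory baseline.

Each unit carries a memory cell c_t gated by input (i), forget (f) and
output (o) logistic gates:

    i, f, o = sigmoid(W_x x_t + W_h h_{t-1} + b)     (per-gate slices)
    g       = tanh(...)                              (candidate)
    c_t     = f * c_{t-1} + i * g
    h_t     = o * tanh(c_t)

Layers are stacked (layer l consumes layer l-1's hidden sequence); states
are zeroed at the start of every window, so windows are independent. The
prediction is a linear readout of the top layer's final hidden state.
Vanilla unit throughout: no peepholes, no dropout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ._checkpoint import load_checkpoint, restore_params, save_checkpoint
from ._layers import Linear, Param
from .errors import ConfigurationError


@dataclass(frozen=True)
class LSTMConfig:
    """Defaults are the grid-search-selected values: 2 layers, 200 hidden
    units, 20-sample input window."""

    n_layers: int = 2
    hidden_units: int = 200
    input_window: int = 20
    input_channels: int = 9
    output_dim: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_units < 1 or self.input_window < 1:
            raise ConfigurationError("n_layers, hidden_units and input_window must be >= 1")


@dataclass
class LSTMLayerParams:
    """Gate weights of one layer; the 4H gate axis is ordered (i, f, g, o)."""

    Wx: Param  # (c_in, 4H)
    Wh: Param  # (H, 4H)
    b: Param   # (4H,)

    @property
    def hidden_units(self) -> int:
        return self.Wh.value.shape[0]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def lstm_step(x_t, h_prev, c_prev, params: LSTMLayerParams):
    """One gated update: (x_t, h_{t-1}, c_{t-1}) -> (h_t, c_t).

    Accepts single vectors or (batch, dim) arrays.
    """
    x_t, h_prev, c_prev = (np.asarray(a, dtype=float) for a in (x_t, h_prev, c_prev))
    H = params.hidden_units
    if x_t.shape[-1] != params.Wx.value.shape[0] or h_prev.shape[-1] != H or c_prev.shape[-1] != H:
        raise ConfigurationError(
            f"dimension mismatch: x{x_t.shape}, h{h_prev.shape}, c{c_prev.shape} "
            f"vs Wx{params.Wx.value.shape}, Wh{params.Wh.value.shape}"
        )
    z = x_t @ params.Wx.value + h_prev @ params.Wh.value + params.b.value
    i = _sigmoid(z[..., :H])
    f = _sigmoid(z[..., H:2 * H])
    g = np.tanh(z[..., 2 * H:3 * H])
    o = _sigmoid(z[..., 3 * H:])
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


class LSTMModel:
    """Stacked LSTM with linear readout; weights initialized from config.seed."""

    def __init__(self, config: LSTMConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        H = config.hidden_units
        self.layers: list[LSTMLayerParams] = []
        c_in = config.input_channels
        for l in range(config.n_layers):
            Wx = Param(f"layer{l}.Wx", rng.normal(0.0, 1.0 / np.sqrt(c_in), size=(c_in, 4 * H)))
            Wh = Param(f"layer{l}.Wh", rng.normal(0.0, 1.0 / np.sqrt(H), size=(H, 4 * H)))
            b = Param(f"layer{l}.b", np.zeros(4 * H))
            b.value[H:2 * H] = 1.0  # forget-gate bias: start remembering
            self.layers.append(LSTMLayerParams(Wx, Wh, b))
            c_in = H
        self.readout = Linear(H, config.output_dim, rng, name="readout")

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for lp in self.layers:
            ps.extend([lp.Wx, lp.Wh, lp.b])
        ps.extend(self.readout.params())
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def _check_window(self, x):
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

    def run_layer(self, layer_index: int, x_seq: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Run one layer over a (B, T, c_in) sequence from zero states,
        returning the (B, T, H) hidden sequence."""
        lp = self.layers[layer_index]
        B, T, _ = x_seq.shape
        H = lp.hidden_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        for t in range(T):
            x_t = x_seq[:, t, :]
            z = x_t @ lp.Wx.value + h @ lp.Wh.value + lp.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            if cache is not None:
                cache.append((x_t, h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            hs[:, t, :] = h
        return hs

    def forward(self, windows, train: bool = False):
        x = self._check_window(windows)
        self._caches = []
        for l in range(len(self.layers)):
            cache: list = []
            x = self.run_layer(l, x, cache if train else None)
            self._caches.append(cache)
        self._top_hidden_shape = x.shape
        return self.readout.forward(x[:, -1, :], train)

    def predict(self, window) -> np.ndarray:
        return self.forward(window)[0]

    def _backward_layer(self, layer_index: int, dh_seq: np.ndarray) -> np.ndarray:
        """Backpropagate through time for one layer given gradients on its
        hidden outputs; accumulates parameter gradients, returns gradients
        on the layer's input sequence."""
        lp = self.layers[layer_index]
        cache = self._caches[layer_index]
        B, T, H = dh_seq.shape
        dx_seq = np.empty((B, T, lp.Wx.value.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, c_new = cache[t]
            tanh_c = np.tanh(c_new)
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            lp.Wx.grad += x_t.T @ dz
            lp.Wh.grad += h_prev.T @ dz
            lp.b.grad += dz.sum(axis=0)
            dx_seq[:, t, :] = dz @ lp.Wx.value.T
            dh_next = dz @ lp.Wh.value.T
        return dx_seq

    def loss_and_grads(self, windows: np.ndarray, targets: np.ndarray) -> float:
        self.zero_grad()
        pred = self.forward(windows, train=True)
        r = pred - targets
        loss = float(np.mean(r * r))
        dlast = self.readout.backward(2.0 * r / r.size)
        dh_seq = np.zeros(self._top_hidden_shape)
        dh_seq[:, -1, :] = dlast
        for l in reversed(range(len(self.layers))):
            dh_seq = self._backward_layer(l, dh_seq)
        return loss

    def save(self, path) -> None:
        save_checkpoint(path, "lstm", dataclasses.asdict(self.config), self.params())

    @classmethod
    def load(cls, path) -> "LSTMModel":
        kind, cfg, arrays = load_checkpoint(path)
        if kind != "lstm":
            raise ConfigurationError(f"checkpoint holds a {kind!r} model, not an LSTM")
        model = cls(LSTMConfig(**cfg))
        restore_params(model.params(), arrays)
        return model


def lstm_forward(model: LSTMModel, window) -> np.ndarray:
    """Functional forward pass: one (t_delay, C) window -> 3-vector."""
    return model.predict(window)


def parameter_count(config: LSTMConfig) -> int:
    """Closed-form parameter count: sum over layers of 4H(c_in + H + 1)
    plus the readout's H*output_dim + output_dim."""
    H = config.hidden_units
    total = 0
    c_in = config.input_channels
    for _ in range(config.n_layers):
        total += 4 * H * (c_in + H + 1)
        c_in = H
    total += H * config.output_dim + config.output_dim
    return total
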