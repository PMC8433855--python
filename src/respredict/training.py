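"""Model optimization (Adam, MSE cost) and full-factorial grid search.

Training minimizes the mean-squared error between predicted and true
tumor positions on normalized channels, using Adam with the standard
exponential-decay rates (0.9, 0.999) and epsilon 1e-8, stopping when the
minibatch cost drops to the cost threshold or the maximum iteration count
is reached — whichever comes first. Everything is reproducible from the
seeds: model initialization from the model config's seed, batch order
from the training options' seed.

Hyperparameter tuning enumerates the FULL factorial product of the grid
axes (never one axis at a time with the others fixed) and scores each
point by mean validation 3D RMSE over the tuning fractions, using a
temporal holdout: the last fifth of each training segment is validation
and never touches a parameter update.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TrainingError
from .lstm import LSTMConfig, LSTMModel
from .signal_io import Fraction
from .tcn import TCNConfig, TCNModel
from .windowing import (
    Normalizer,
    Segment,
    WindowSpec,
    WindowedDataset,
    make_pairs,
    split_train_test,
)


@dataclass(frozen=True)
class TrainOptions:
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    max_iterations: int = 2000
    cost_threshold: float = 0.0
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.cost_threshold < 0:
            raise ConfigurationError("cost_threshold must be nonnegative")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params, opts: TrainOptions):
        self.params = list(params)
        self.opts = opts
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        o = self.opts
        self.t += 1
        b1t = 1.0 - o.adam_beta1**self.t
        b2t = 1.0 - o.adam_beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= o.adam_beta1
            m += (1.0 - o.adam_beta1) * p.grad
            v *= o.adam_beta2
            v += (1.0 - o.adam_beta2) * p.grad**2
            p.value -= o.learning_rate * (m / b1t) / (np.sqrt(v / b2t) + o.adam_epsilon)


class _BatchSampler:
    """Deterministic minibatch order: shuffled epochs, no replacement."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch = min(batch_size, n)
        self.rng = rng
        self.order = rng.permutation(n)
        self.ptr = 0

    def next(self) -> np.ndarray:
        if self.ptr + self.batch > self.n:
            self.order = self.rng.permutation(self.n)
            self.ptr = 0
        idx = self.order[self.ptr:self.ptr + self.batch]
        self.ptr += self.batch
        return idx


def train(model, dataset: WindowedDataset, opts: TrainOptions):
    """Optimize ``model`` in place on a (normalized) windowed dataset.

    Returns ``(model, history)`` where ``history[i]`` is the minibatch MSE
    cost at iteration i+1. Raises :class:`TrainingError` at the first
    non-finite cost.
    """
    if len(dataset) == 0:
        raise ConfigurationError("cannot train on an empty dataset")
    rng = np.random.default_rng(opts.seed)
    sampler = _BatchSampler(len(dataset), opts.batch_size, rng)
    optimizer = Adam(model.params(), opts)
    history: list[float] = []
    for it in range(1, opts.max_iterations + 1):
        idx = sampler.next()
        loss = model.loss_and_grads(dataset.inputs[idx], dataset.targets[idx])
        if not math.isfinite(loss):
            raise TrainingError(f"non-finite cost at iteration {it}", iteration=it)
        optimizer.step()
        history.append(loss)
        if loss <= opts.cost_threshold:
            break
    return model, history


def build_model(family: str, config=None, **overrides):
    """Construct a TCN or LSTM from a config (or the family defaults)."""
    family = family.lower()
    if family == "tcn":
        cfg = config or TCNConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        return TCNModel(cfg)
    if family == "lstm":
        cfg = config or LSTMConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        return LSTMModel(cfg)
    raise ConfigurationError(f"unknown model family {family!r} (expected 'tcn' or 'lstm')")


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpace:
    """Named axes of hyperparameter options; the search is their full product."""

    axes: dict[str, tuple]

    def __post_init__(self):
        object.__setattr__(
            self, "axes", {k: tuple(v) for k, v in self.axes.items()}
        )
        for name, options in self.axes.items():
            if len(options) == 0:
                raise ConfigurationError(f"grid axis {name!r} is empty")

    @property
    def n_points(self) -> int:
        return math.prod(len(v) for v in self.axes.values())

    def points(self):
        names = list(self.axes)
        for combo in itertools.product(*(self.axes[n] for n in names)):
            yield dict(zip(names, combo))


#: Grid axes used for tuning (4 axes per model family).
TCN_GRID = GridSpace({
    "n_layers": (4, 5, 6, 7, 8),
    "filter_size": (1, 3, 5, 7, 9),
    "input_window": (5, 10, 15, 20, 25),
    "learning_rate": (0.0001, 0.001, 0.005, 0.01, 0.1),
})

LSTM_GRID = GridSpace({
    "n_layers": (1, 2, 3, 4, 5),
    "learning_rate": (0.0001, 0.001, 0.005, 0.01, 0.1),
    "hidden_units": (10, 50, 100, 150, 200, 250),
    "input_window": (5, 10, 15, 20, 25),
})

_MODEL_KEYS = {"n_layers", "filter_size", "input_window", "hidden_units",
               "channels_per_layer", "use_residual", "convs_per_block", "dropout_rate"}


def split_point_config(family: str, point: dict, base_model_config=None,
                       base_train_options: TrainOptions | None = None):
    """Turn one grid point into a (model config, train options) pair."""
    model_over = {k: v for k, v in point.items() if k in _MODEL_KEYS}
    topts = base_train_options or TrainOptions()
    if "learning_rate" in point:
        topts = replace(topts, learning_rate=point["learning_rate"])
    if family == "tcn":
        cfg = replace(base_model_config or TCNConfig(), **model_over)
    else:
        cfg = replace(base_model_config or LSTMConfig(), **model_over)
    return cfg, topts


def holdout_split(train_segment: Segment, holdout_frac: float = 0.2) -> tuple[Segment, Segment]:
    """Temporal holdout: the last fraction of the training segment is
    validation and never reaches the optimizer."""
    L = len(train_segment)
    cut = max(1, int(round(L * (1.0 - holdout_frac))))
    if cut >= L:
        raise ConfigurationError("training segment too short for a validation holdout")
    fit = Segment(train_segment.inputs[:cut], train_segment.targets[:cut],
                  start_index=train_segment.start_index)
    val = Segment(train_segment.inputs[cut:], train_segment.targets[cut:],
                  start_index=train_segment.start_index + cut)
    return fit, val


def fit_on_segment(family: str, model_cfg, spec: WindowSpec, fit_seg: Segment,
                   topts: TrainOptions):
    """Normalize on ``fit_seg``, window it and train a fresh model.

    Returns (model, norm_x, norm_y, history); validation data are not an
    argument, so they cannot influence the trained weights.
    """
    norm_x = Normalizer.fit(fit_seg.inputs)
    norm_y = Normalizer.fit(fit_seg.targets)
    fit_norm = Segment(norm_x.apply(fit_seg.inputs), norm_y.apply(fit_seg.targets),
                       start_index=fit_seg.start_index)
    ds = make_pairs(fit_norm, spec)
    model = build_model(family, model_cfg,
                        input_window=spec.t_delay, input_channels=fit_seg.inputs.shape[1])
    model, history = train(model, ds, topts)
    return model, norm_x, norm_y, history


def _validation_rmse3d(model, norm_x: Normalizer, norm_y: Normalizer,
                       val_seg: Segment, spec: WindowSpec) -> float:
    val_norm = Segment(norm_x.apply(val_seg.inputs), norm_y.apply(val_seg.targets),
                       start_index=val_seg.start_index)
    ds = make_pairs(val_norm, spec)
    pred = norm_y.invert(model.forward(ds.inputs))
    true = val_seg.targets[ds.target_indices - val_seg.start_index]
    return float(np.sqrt(np.mean(np.sum((pred - true) ** 2, axis=1))))


def default_evaluator(family: str, spec: WindowSpec,
                      base_model_config=None, train_options: TrainOptions | None = None,
                      holdout_frac: float = 0.2):
    """Build the standard grid-point evaluator: temporal-holdout validation
    3D RMSE on one fraction's training segment."""

    def evaluate(point: dict, fraction: Fraction) -> float:
        cfg, topts = split_point_config(family, point, base_model_config, train_options)
        pspec = WindowSpec(t_delay=point.get("input_window", spec.t_delay),
                           t_ahead=spec.t_ahead, t_s=spec.t_s)
        train_seg, _ = split_train_test(fraction, pspec.t_s)
        fit_seg, val_seg = holdout_split(train_seg, holdout_frac)
        try:
            model, nx, ny, _ = fit_on_segment(family, cfg, pspec, fit_seg, topts)
        except TrainingError:
            return float("inf")  # diverged: worst possible score
        return _validation_rmse3d(model, nx, ny, val_seg, pspec)

    return evaluate


def _point_model_size(family: str, point: dict, base_model_config=None) -> int:
    cfg, _ = split_point_config(family, point, base_model_config)
    return build_model(family, cfg).n_parameters


def grid_search(family: str, space: GridSpace, tuning_fractions,
                spec: WindowSpec | None = None, evaluator=None,
                base_model_config=None, train_options: TrainOptions | None = None):
    """Full-factorial hyperparameter search.

    Every point of ``space`` is evaluated on every tuning fraction (score =
    validation 3D RMSE, mm); the best point minimizes the mean score, with
    ties broken by smaller model then lower learning rate. Returns
    ``(best_point, results)`` where ``results`` is a DataFrame with one row
    per grid point, per-fraction score columns and their mean.
    """
    tuning_fractions = list(tuning_fractions)
    if not tuning_fractions:
        raise ConfigurationError("grid search needs at least one tuning fraction")
    if evaluator is None:
        if spec is None:
            raise ConfigurationError("grid search needs a WindowSpec (or a custom evaluator)")
        evaluator = default_evaluator(family, spec, base_model_config, train_options)

    rows = []
    for point in space.points():
        scores = [float(evaluator(point, fr)) for fr in tuning_fractions]
        row = dict(point)
        for j, s in enumerate(scores):
            row[f"rmse3d_frac{j}"] = s
        row["mean_rmse3d"] = float(np.mean(scores))
        rows.append(row)
    results = pd.DataFrame(rows)

    def sort_key(i):
        row = rows[i]
        mean = row["mean_rmse3d"]
        size = _point_model_size(family, {k: row[k] for k in space.axes}, base_model_config)
        lr = row.get("learning_rate", 0.0)
        return (mean, size, lr)

    best_i = min(range(len(rows)), key=sort_key)
    best_point = {k: rows[best_i][k] for k in space.axes}
    return best_point, results
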