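"""Evaluation metrics, the no-prediction baseline, paired statistics, and
experiment drivers (model comparison, ahead-time sweep, marker subsets,
ablations).

Accuracy is reported as root-mean-square error between true and predicted
tumor positions over the test segment's evaluable range, per anatomical
direction and in 3D:

    RMSE_k  = sqrt( mean_t (T_k[t] - T'_k[t])^2 ),     k in {SI, AP, LR}
    RMSE_3D = sqrt( mean_t ||T[t] - T'[t]||^2 ),

so RMSE_3D^2 = RMSE_SI^2 + RMSE_AP^2 + RMSE_LR^2 exactly. The evaluable
range starts at t_start = t_s + t_delay + t_ahead (1-based) and ends at
the final sample t_end.

The *no-prediction* baseline models an uncompensated system: the position
reported at time t is the true tumor position at t - t_ahead, i.e. pure
latency error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateTestError
from .lstm import LSTMConfig
from .signal_io import DIRECTIONS, Fraction
from .tcn import TCNConfig
from .training import TrainOptions, fit_on_segment
from .windowing import (
    Segment,
    WindowSpec,
    fraction_to_arrays,
    make_pairs,
    split_train_test,
)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_aligned(true, pred):
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if true.shape != pred.shape:
        raise ConfigurationError(f"trace shapes differ: {true.shape} vs {pred.shape}")
    if true.size == 0:
        raise ConfigurationError("traces must be non-empty")
    if true.ndim == 1:
        true, pred = true[:, None], pred[:, None]
    return true, pred


def rmse_by_direction(true, pred) -> np.ndarray:
    """Per-direction RMSE (mm) over aligned (n, 3) traces."""
    true, pred = _check_aligned(true, pred)
    return np.sqrt(np.mean((true - pred) ** 2, axis=0))


def rmse_3d(true, pred) -> float:
    """Root mean (over time) squared 3D Euclidean error (mm)."""
    true, pred = _check_aligned(true, pred)
    return float(np.sqrt(np.mean(np.sum((true - pred) ** 2, axis=1))))


def correlation(true, pred) -> np.ndarray:
    """Product-moment correlation per direction; NaN where a trace is constant."""
    true, pred = _check_aligned(true, pred)
    if len(true) < 2:
        raise ConfigurationError("correlation needs at least 2 points")
    out = np.empty(true.shape[1])
    for k in range(true.shape[1]):
        a = true[:, k] - true[:, k].mean()
        b = pred[:, k] - pred[:, k].mean()
        denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
        if denom == 0.0:
            warnings.warn("correlation undefined for a constant trace; returning NaN")
            out[k] = np.nan
        else:
            out[k] = float(np.sum(a * b) / denom)
    return out


def percent_reduction(baseline_rmse: float, model_rmse: float) -> float:
    """100 * (1 - model/baseline): how much of the latency error the model removes."""
    if baseline_rmse <= 0:
        raise DegenerateTestError("percent reduction undefined for a zero baseline RMSE")
    return 100.0 * (1.0 - model_rmse / baseline_rmse)


def wilcoxon_paired(scores_a, scores_b):
    """Two-sided Wilcoxon signed-rank test on paired per-fraction scores.

    Zero differences are dropped and tied magnitudes mid-ranked; the exact
    null distribution is used for n <= 25, the normal approximation with
    continuity correction above.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("paired score vectors must be 1-D and equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateTestError("all paired differences are zero; test undefined")
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                             correction=(method == "approx"), method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                             correction=True, method="approx")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Prediction results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionResult:
    """Predicted vs true tumor trace over the evaluable test range."""

    fraction_id: str
    model_label: str
    t_ahead_samples: int
    t_ahead_ms: float
    target_indices: np.ndarray  # 1-based absolute sample indices
    predicted: np.ndarray       # (n, 3) mm
    true: np.ndarray            # (n, 3) mm

    def __post_init__(self):
        if self.predicted.shape != self.true.shape:
            raise ConfigurationError("predicted and true traces must be aligned")


@dataclass(frozen=True)
class EvalReport:
    """Per-direction and 3D RMSE (mm), correlations, and sample count."""

    rmse: dict          # {"SI": .., "AP": .., "LR": .., "3D": ..}
    corr: dict          # {"SI": .., "AP": .., "LR": ..}
    n_points: int
    fraction_id: str = ""
    model_label: str = ""


def evaluate_result(result: PredictionResult) -> EvalReport:
    per_dir = rmse_by_direction(result.true, result.predicted)
    corr = correlation(result.true, result.predicted)
    rmse = {d: float(per_dir[i]) for i, d in enumerate(DIRECTIONS)}
    rmse["3D"] = rmse_3d(result.true, result.predicted)
    return EvalReport(
        rmse=rmse,
        corr={d: float(corr[i]) for i, d in enumerate(DIRECTIONS)},
        n_points=len(result.true),
        fraction_id=result.fraction_id,
        model_label=result.model_label,
    )


def no_prediction_baseline(fraction: Fraction, spec: WindowSpec) -> PredictionResult:
    """Uncompensated system: report at time t the true position at t - t_ahead."""
    _, Y = fraction_to_arrays(fraction)
    n = fraction.n_samples
    t_start = spec.t_s + spec.t_delay + spec.t_ahead  # 1-based
    if t_start > n:
        raise ConfigurationError("test segment too short for this window spec")
    idx = np.arange(t_start, n + 1)
    predicted = Y[idx - 1 - spec.t_ahead]
    true = Y[idx - 1]
    return PredictionResult(
        fraction_id=fraction.fraction_id,
        model_label="no-prediction",
        t_ahead_samples=spec.t_ahead,
        t_ahead_ms=spec.ahead_ms(fraction.sampling_rate_hz),
        target_indices=idx,
        predicted=predicted,
        true=true,
    )


# ---------------------------------------------------------------------------
# Train-and-predict pipeline
# ---------------------------------------------------------------------------

def default_split_index(fraction: Fraction, test_duration_s: float = 30.0) -> int:
    """Leave the final ``test_duration_s`` seconds as the test segment."""
    n_test = int(round(test_duration_s * fraction.sampling_rate_hz))
    t_s = fraction.n_samples - n_test
    if t_s < 1:
        raise ConfigurationError("fraction shorter than the requested test duration")
    return t_s


def fit_predict(fraction: Fraction, family: str = "tcn", model_config=None,
                spec: WindowSpec | None = None,
                train_options: TrainOptions | None = None,
                marker_subset=None, label: str | None = None):
    """Train a model on the fraction's training segment and predict its test
    segment. Returns ``(PredictionResult, model, loss_history)``.

    Normalization statistics come from the training segment only; the test
    segment is windowed with the identical pair-construction formula.
    """
    if spec is None:
        t_delay = (model_config.input_window if model_config is not None
                   else (TCNConfig() if family == "tcn" else LSTMConfig()).input_window)
        spec = WindowSpec.from_ms(t_delay, 400.0, default_split_index(fraction),
                                  fraction.sampling_rate_hz)
    topts = train_options or TrainOptions()
    train_seg, test_seg = split_train_test(fraction, spec.t_s, marker_subset)
    model, norm_x, norm_y, history = fit_on_segment(family, model_config, spec,
                                                    train_seg, topts)
    test_norm = Segment(norm_x.apply(test_seg.inputs), norm_y.apply(test_seg.targets),
                        start_index=test_seg.start_index)
    ds = make_pairs(test_norm, spec)
    predicted = norm_y.invert(model.forward(ds.inputs))
    true = test_seg.targets[ds.target_indices - test_seg.start_index]
    result = PredictionResult(
        fraction_id=fraction.fraction_id,
        model_label=label or family,
        t_ahead_samples=spec.t_ahead,
        t_ahead_ms=spec.ahead_ms(fraction.sampling_rate_hz),
        target_indices=ds.target_indices,
        predicted=predicted,
        true=true,
    )
    return result, model, history


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

def _report_rows(reports: list[EvalReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"fraction_id": r.fraction_id, "model": r.model_label, "n_points": r.n_points}
        for d in (*DIRECTIONS, "3D"):
            row[f"rmse_{d}"] = r.rmse[d]
        for d in DIRECTIONS:
            row[f"corr_{d}"] = r.corr[d]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(cohort, spec_for: dict[str, WindowSpec],
                   model_configs: dict | None = None,
                   train_options: TrainOptions | None = None) -> pd.DataFrame:
    """Per-fraction RMSEs for the TCN, LSTM and no-prediction models.

    ``spec_for`` maps model label ('tcn'/'lstm') to its WindowSpec; the
    baseline uses the TCN's spec. Returns a tidy frame: one row per
    fraction x model, with per-direction and 3D RMSE columns.
    """
    if not cohort:
        raise ConfigurationError("empty cohort")
    model_configs = model_configs or {}
    reports = []
    for fraction in cohort:
        for family, spec in spec_for.items():
            res, _, _ = fit_predict(fraction, family, model_configs.get(family),
                                    spec, train_options)
            reports.append(evaluate_result(res))
        base_spec = spec_for.get("tcn", next(iter(spec_for.values())))
        reports.append(evaluate_result(no_prediction_baseline(fraction, base_spec)))
    return _report_rows(reports)


def ahead_time_sweep(cohort, ahead_ms_list, family: str = "tcn", model_config=None,
                     t_delay: int | None = None,
                     train_options: TrainOptions | None = None) -> pd.DataFrame:
    """Train/evaluate at each ahead time (given in ms) plus the baseline."""
    if not cohort:
        raise ConfigurationError("empty cohort")
    rows = []
    for fraction in cohort:
        rate = fraction.sampling_rate_hz
        td = t_delay or (model_config.input_window if model_config is not None
                         else TCNConfig().input_window)
        for ahead_ms in ahead_ms_list:
            spec = WindowSpec.from_ms(td, ahead_ms, default_split_index(fraction), rate)
            res, _, _ = fit_predict(fraction, family, model_config, spec, train_options)
            rep = evaluate_result(res)
            base = evaluate_result(no_prediction_baseline(fraction, spec))
            rows.append({
                "fraction_id": fraction.fraction_id,
                "ahead_ms": ahead_ms,
                "t_ahead_samples": spec.t_ahead,
                "model_rmse_3D": rep.rmse["3D"],
                "baseline_rmse_3D": base.rmse["3D"],
            })
    return pd.DataFrame(rows)


#: The marker-subset axis of the marker-count experiment.
MARKER_SUBSETS = ((1,), (2,), (3,), (1, 2), (1, 3), (2, 3), (1, 2, 3))


def marker_subset_experiment(cohort, subsets=MARKER_SUBSETS, family: str = "tcn",
                             model_config=None, spec: WindowSpec | None = None,
                             train_options: TrainOptions | None = None) -> pd.DataFrame:
    """Retrain with each marker subset (input channels = 3 * |subset|)."""
    if not cohort:
        raise ConfigurationError("empty cohort")
    rows = []
    for fraction in cohort:
        for subset in subsets:
            res, _, _ = fit_predict(fraction, family, model_config, spec, train_options,
                                    marker_subset=subset,
                                    label=f"{family}-EM{''.join(map(str, subset))}")
            rep = evaluate_result(res)
            row = {"fraction_id": fraction.fraction_id,
                   "subset": "".join(map(str, subset)), "n_markers": len(subset)}
            for d in (*DIRECTIONS, "3D"):
                row[f"rmse_{d}"] = rep.rmse[d]
            rows.append(row)
    return pd.DataFrame(rows)


def ablation_experiment(cohort, filter_sizes=(1, 3, 5, 7, 9), residual_options=(True, False),
                        base_config: TCNConfig | None = None,
                        spec: WindowSpec | None = None,
                        train_options: TrainOptions | None = None) -> pd.DataFrame:
    """Sweep filter size and toggle residual connections for the TCN."""
    if not cohort:
        raise ConfigurationError("empty cohort")
    base = base_config or TCNConfig()
    rows = []
    for fraction in cohort:
        for use_res in residual_options:
            for k in filter_sizes:
                cfg = replace(base, filter_size=k, use_residual=use_res)
                res, _, _ = fit_predict(fraction, "tcn", cfg, spec, train_options,
                                        label=f"tcn-k{k}-{'res' if use_res else 'nores'}")
                rep = evaluate_result(res)
                rows.append({"fraction_id": fraction.fraction_id, "filter_size": k,
                             "use_residual": use_res, "rmse_3D": rep.rmse["3D"]})
    return pd.DataFrame(rows)


def run_experiment(cohort, experiment: str, **kwargs) -> pd.DataFrame:
    """Dispatch one named experiment over a cohort of fractions."""
    drivers = {
        "compare": compare_models,
        "ahead": ahead_time_sweep,
        "markers": marker_subset_experiment,
        "ablation": ablation_experiment,
    }
    if experiment not in drivers:
        raise ConfigurationError(
            f"unknown experiment {experiment!r}; expected one of {sorted(drivers)}"
        )
    return drivers[experiment](cohort, **kwargs)


def summarize_rmse(table: pd.DataFrame, by, value_cols=None) -> pd.DataFrame:
    """Cohort aggregate: unweighted mean over fractions, grouped by ``by``."""
    value_cols = value_cols or [c for c in table.columns if c.startswith("rmse") or c.endswith("rmse_3D")]
    return table.groupby(by, sort=False)[value_cols].mean().reset_index()


def round_report(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Report rounding convention: RMSE to 2 decimals (mm)."""
    out = table.copy()
    num = out.select_dtypes(include=[np.number]).columns
    out[num] = out[num].round(decimals)
    return out
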