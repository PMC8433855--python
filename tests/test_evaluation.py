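"""Metrics vs direct-formula oracles, the no-prediction baseline closed form,
Wilcoxon vs exact enumeration, and experiment report shapes."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from respredict import (
    ConfigurationError,
    DegenerateTestError,
    SyntheticConfig,
    WindowSpec,
    correlation,
    no_prediction_baseline,
    percent_reduction,
    rmse_3d,
    rmse_by_direction,
    simulate_fraction,
    wilcoxon_paired,
)
from respredict.evaluation import evaluate_result, marker_subset_experiment, run_experiment
from respredict.signal_io import Fraction, MarkerTrace, TumorTrace

from conftest import fast_fraction, fast_tcn, fast_train_options, fast_window


# ---------------------------------------------------------------------------
# RMSE / correlation
# ---------------------------------------------------------------------------

def test_rmse_identical_traces_is_zero(rng):
    x = rng.normal(size=(30, 3))
    np.testing.assert_array_equal(rmse_by_direction(x, x), [0.0, 0.0, 0.0])
    assert rmse_3d(x, x) == 0.0


def test_rmse_constant_offset_closed_form(rng):
    x = rng.normal(size=(50, 3))
    y = x.copy()
    y[:, 0] += 2.0
    np.testing.assert_allclose(rmse_by_direction(x, y), [2.0, 0.0, 0.0], atol=1e-12)
    assert rmse_3d(x, y) == pytest.approx(2.0)
    y = x.copy()
    y[:, 0] += 3.0
    y[:, 1] += 4.0
    assert rmse_3d(x, y) == pytest.approx(5.0)  # Pythagorean offsets


def test_rmse_matches_direct_formula_oracle(rng):
    true = rng.normal(size=(20, 3))
    pred = rng.normal(size=(20, 3))
    for k in range(3):
        acc = sum((true[t, k] - pred[t, k]) ** 2 for t in range(20))
        assert rmse_by_direction(true, pred)[k] == pytest.approx(
            np.sqrt(acc / 20), abs=1e-12)


def test_rmse3d_is_root_sum_of_squares_of_directions(rng):
    for _ in range(20):
        true = rng.normal(size=(25, 3))
        pred = rng.normal(size=(25, 3))
        per = rmse_by_direction(true, pred)
        assert rmse_3d(true, pred) == pytest.approx(np.sqrt(np.sum(per**2)), abs=1e-12)
        assert rmse_3d(true, pred) >= per.max() - 1e-12


def test_rmse_shape_mismatch_rejected(rng):
    with pytest.raises(ConfigurationError):
        rmse_by_direction(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


def test_correlation_limits_and_oracle(rng):
    x = rng.normal(size=(40, 3))
    np.testing.assert_allclose(correlation(x, x), [1.0, 1.0, 1.0], atol=1e-12)
    centered = x - x.mean(axis=0)
    np.testing.assert_allclose(correlation(centered, -centered), [-1.0] * 3, atol=1e-12)
    pred = rng.normal(size=(40, 3))
    got = correlation(x, pred)
    for k in range(3):
        a, b = x[:, k], pred[:, k]
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert got[k] == pytest.approx(num / den, abs=1e-12)


def test_correlation_constant_trace_signals_nan(rng):
    x = rng.normal(size=(10, 3))
    pred = x.copy()
    pred[:, 2] = 1.0
    with pytest.warns(UserWarning):
        got = correlation(x, pred)
    assert np.isnan(got[2]) and np.isfinite(got[0])


# ---------------------------------------------------------------------------
# No-prediction baseline
# ---------------------------------------------------------------------------

def _sine_fraction(amplitude=5.0, period_s=4.0, n=2000, rate=25.0):
    t = np.arange(n) / rate
    si = amplitude * np.sin(2 * np.pi * t / period_s)
    tumor = np.column_stack([si, np.zeros(n), np.zeros(n)])
    marker = MarkerTrace(1, np.column_stack([si, np.zeros(n), np.zeros(n)]))
    return Fraction("sine", rate, (marker,), TumorTrace(tumor))


def test_baseline_zero_ahead_time_is_exact():
    fr = _sine_fraction()
    spec = WindowSpec(t_delay=15, t_ahead=0, t_s=1500)
    rep = evaluate_result(no_prediction_baseline(fr, spec))
    assert rep.rmse["3D"] == 0.0


def test_baseline_lagged_sine_closed_form():
    """For pure sine SI motion of amplitude A and period tau, reporting with
    lag delta gives RMSE_SI = A*sqrt(2)*|sin(pi*delta/tau)| over whole periods."""
    A, tau, rate = 5.0, 4.0, 25.0
    fr = _sine_fraction(A, tau, n=2000, rate=rate)
    t_ahead = 10  # delta = 0.4 s
    # evaluation range = exactly 10 whole periods: t_start..t_end covers 1000 samples
    spec = WindowSpec(t_delay=15, t_ahead=t_ahead, t_s=2000 - 1000 - 15 - t_ahead + 1)
    res = no_prediction_baseline(fr, spec)
    assert len(res.true) == 1000
    delta = t_ahead / rate
    expected = A * np.sqrt(2.0) * abs(np.sin(np.pi * delta / tau))
    assert evaluate_result(res).rmse["SI"] == pytest.approx(expected, rel=1e-9)


def test_baseline_rmse_grows_with_ahead_time():
    fr = simulate_fraction(SyntheticConfig(duration_s=80.0, seed=2))
    rmses = []
    for t_ahead in (2, 5, 10, 15, 20, 25):
        spec = WindowSpec(t_delay=15, t_ahead=t_ahead, t_s=1500)
        rmses.append(evaluate_result(no_prediction_baseline(fr, spec)).rmse["3D"])
    assert all(a < b for a, b in zip(rmses, rmses[1:]))


def test_baseline_alignment_starts_at_t_start():
    fr = _sine_fraction(n=200)
    spec = WindowSpec(t_delay=15, t_ahead=10, t_s=100)
    res = no_prediction_baseline(fr, spec)
    assert res.target_indices[0] == 100 + 15 + 10
    assert res.target_indices[-1] == 200
    np.testing.assert_array_equal(res.predicted[0], fr.tumor.positions[125 - 1 - 10])


# ---------------------------------------------------------------------------
# Percent reduction and Wilcoxon
# ---------------------------------------------------------------------------

def test_percent_reduction_published_arithmetic():
    assert round(percent_reduction(1.36, 0.67)) == 51
    assert round(percent_reduction(1.36, 0.73)) == 46
    assert percent_reduction(2.0, 2.0) == 0.0
    with pytest.raises(DegenerateTestError):
        percent_reduction(0.0, 1.0)


def exact_signed_rank_p(diffs):
    """Exhaustive two-sided signed-rank null: enumerate all sign assignments
    on the mid-ranked absolute differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        s = np.asarray(signs, dtype=bool)
        w = min(ranks[s].sum(), ranks[~s].sum())
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


def test_wilcoxon_all_positive_differences_minimal_p():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    b = a - 1.0
    stat, p = wilcoxon_paired(a, b)
    assert p == pytest.approx(2 / 2**6)  # 0.03125, smallest two-sided exact p at n=6


def test_wilcoxon_degenerate_when_identical():
    a = np.ones(8)
    with pytest.raises(DegenerateTestError):
        wilcoxon_paired(a, a)


@pytest.mark.parametrize("seed", range(6))
def test_wilcoxon_matches_exact_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 11))
    a = rng.normal(size=n)
    b = a + rng.normal(scale=0.8, size=n)
    stat, p = wilcoxon_paired(a, b)
    assert p == pytest.approx(exact_signed_rank_p(a - b), abs=1e-10)


# ---------------------------------------------------------------------------
# Experiment drivers (shape contracts on a tiny cohort)
# ---------------------------------------------------------------------------

def test_marker_subset_axis_is_seven_columns():
    from respredict.evaluation import MARKER_SUBSETS

    assert MARKER_SUBSETS == ((1,), (2,), (3,), (1, 2), (1, 3), (2, 3), (1, 2, 3))


def test_compare_report_shape_contract():
    cohort = [fast_fraction(s) for s in (0, 1)]
    spec = fast_window()
    opts = fast_train_options(0, max_iterations=20)
    cfg = fast_tcn(0, n_layers=2, filter_size=3, channels_per_layer=8)
    table = run_experiment(cohort, "compare", spec_for={"tcn": spec},
                           model_configs={"tcn": cfg}, train_options=opts)
    # 2 fractions x (1 model + baseline) rows
    assert len(table) == 4
    assert {"rmse_SI", "rmse_AP", "rmse_LR", "rmse_3D", "model"} <= set(table.columns)
    assert set(table["model"]) == {"tcn", "no-prediction"}


def test_marker_subset_experiment_channels(monkeypatch):
    cohort = [fast_fraction(3)]
    spec = fast_window()
    opts = fast_train_options(0, max_iterations=10)
    cfg = fast_tcn(0, n_layers=2, filter_size=3, channels_per_layer=8)
    table = marker_subset_experiment(cohort, subsets=((1,), (1, 2, 3)),
                                     model_config=cfg, spec=spec, train_options=opts)
    assert list(table["n_markers"]) == [1, 3]
    assert list(table["subset"]) == ["1", "123"]


def test_unknown_experiment_rejected():
    with pytest.raises(ConfigurationError):
        run_experiment([fast_fraction(0)], "dosimetry")


def test_empty_cohort_rejected():
    with pytest.raises(ConfigurationError):
        run_experiment([], "compare", spec_for={"tcn": fast_window()})
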