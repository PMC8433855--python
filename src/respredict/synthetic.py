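"""Synthetic respiratory-motion generator.

Emulates the statistical structure of CyberKnife Synchrony-style recordings:
quasi-periodic breathing with a flat exhale plateau and a sharp inhale peak,
superior-inferior-dominant tumor amplitude, slow baseline drift, external
marker channels driven by the same latent breathing signal (with per-marker
mechanical lag), and additive sensor noise.

The latent waveform over one breathing cycle of unit depth is

    b(s) = sin(pi * s) ** (2 p),   s in [0, 1),

which is 0 at the cycle boundaries (end-exhale) and 1 at mid-cycle
(peak inhale); larger shape exponents ``p`` flatten the exhale plateau and
sharpen the inhale. Cycle-to-cycle variability enters through a per-cycle
period (uniform +/- ``period_jitter_frac``) and depth (uniform +/-
``amplitude_jitter_frac``). The tumor trace in direction k is

    T_k(t) = A_k * b(t) + drift_k * t / 60 + eps,

and marker m in direction k is ``G[m,k] * b(t - lag_m) + eps`` with
independent noise per channel. All randomness flows from one seeded
generator per call; no global state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .signal_io import Fraction, MarkerTrace, TumorTrace


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated fraction. Units: mm, s, Hz."""

    duration_s: float = 210.0
    sampling_rate_hz: float = 25.0
    period_s: float = 4.0
    shape_exponent: int = 2
    tumor_amplitude_mm: tuple[float, float, float] = (10.0, 4.0, 3.0)
    drift_mm_per_min: tuple[float, float, float] = (1.0, 0.4, 0.3)
    period_jitter_frac: float = 0.05
    amplitude_jitter_frac: float = 0.08
    marker_gains: tuple[tuple[float, float, float], ...] = (
        (8.0, 3.0, 1.0),
        (6.0, 4.0, 1.5),
        (7.0, 2.5, 2.0),
    )
    marker_lag_s: tuple[float, ...] = (0.04, 0.12, 0.20)
    noise_sd_mm: float = 0.15
    seed: int = 0

    def __post_init__(self):
        scalars = {
            "duration_s": self.duration_s,
            "sampling_rate_hz": self.sampling_rate_hz,
            "period_s": self.period_s,
            "noise_sd_mm": self.noise_sd_mm,
        }
        for name, v in scalars.items():
            if not np.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0 or self.period_s <= 0:
            raise ConfigurationError("duration_s, sampling_rate_hz and period_s must be positive")
        if self.shape_exponent < 1:
            raise ConfigurationError("shape_exponent must be a positive integer")
        if self.noise_sd_mm < 0:
            raise ConfigurationError("noise_sd_mm must be nonnegative")
        for name, vec in (
            ("tumor_amplitude_mm", self.tumor_amplitude_mm),
            ("drift_mm_per_min", self.drift_mm_per_min),
            ("marker_lag_s", self.marker_lag_s),
        ):
            arr = np.asarray(vec, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"{name} must be finite")
        if np.any(np.asarray(self.tumor_amplitude_mm) < 0):
            raise ConfigurationError("tumor amplitudes must be nonnegative")
        for name, frac in (
            ("period_jitter_frac", self.period_jitter_frac),
            ("amplitude_jitter_frac", self.amplitude_jitter_frac),
        ):
            if not (0 <= frac < 1):
                raise ConfigurationError(f"{name} must lie in [0, 1), got {frac!r}")
        gains = np.asarray(self.marker_gains, dtype=float)
        if gains.ndim != 2 or gains.shape[1] != 3 or not 1 <= gains.shape[0] <= 3:
            raise ConfigurationError("marker_gains must be an (n_markers<=3, 3) matrix")
        if not np.all(np.isfinite(gains)):
            raise ConfigurationError("marker_gains must be finite")
        if len(self.marker_lag_s) != gains.shape[0]:
            raise ConfigurationError("marker_lag_s must have one entry per marker")

    @property
    def n_markers(self) -> int:
        return len(self.marker_gains)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


class _BreathingWaveform:
    """Piecewise cycle representation of the latent breathing signal b(t).

    Cycles cover [t_min, t_max]; b is evaluated at arbitrary times so the
    same realization can be read at marker-lagged time points.
    """

    def __init__(self, config: SyntheticConfig, rng: np.random.Generator, t_min: float, t_max: float):
        tau, pj, aj = config.period_s, config.period_jitter_frac, config.amplitude_jitter_frac
        # enough cycles to cover the span even if every period is shortest
        n_cycles = int(np.ceil((t_max - t_min) / (tau * (1 - pj)))) + 2
        u = rng.uniform(-1.0, 1.0, size=n_cycles)
        v = rng.uniform(-1.0, 1.0, size=n_cycles)
        self.periods = tau * (1.0 + pj * u)
        self.depths = 1.0 + aj * v
        starts = t_min + np.concatenate(([0.0], np.cumsum(self.periods[:-1])))
        self.starts = starts
        self.exponent = 2 * config.shape_exponent

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.starts, t, side="right") - 1, 0, len(self.starts) - 1)
        s = (t - self.starts[idx]) / self.periods[idx]
        return self.depths[idx] * np.sin(np.pi * s) ** self.exponent


def simulate_fraction(config: SyntheticConfig, fraction_id: str | None = None) -> Fraction:
    """Simulate one fraction; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate_hz
    max_lag = max((max(config.marker_lag_s), 0.0)) if config.marker_lag_s else 0.0

    wave = _BreathingWaveform(config, rng, t_min=-max_lag - 2 * config.period_s, t_max=t[-1] + config.period_s)
    b = wave(t)

    amp = np.asarray(config.tumor_amplitude_mm)
    drift = np.asarray(config.drift_mm_per_min)
    tumor = amp[None, :] * b[:, None] + drift[None, :] * (t[:, None] / 60.0)
    tumor = tumor + rng.normal(0.0, config.noise_sd_mm, size=tumor.shape) if config.noise_sd_mm > 0 else tumor

    gains = np.asarray(config.marker_gains)
    markers = []
    for m in range(config.n_markers):
        bm = wave(t - config.marker_lag_s[m])
        pos = gains[m][None, :] * bm[:, None]
        if config.noise_sd_mm > 0:
            pos = pos + rng.normal(0.0, config.noise_sd_mm, size=pos.shape)
        markers.append(MarkerTrace(marker_index=m + 1, positions=pos))

    return Fraction(
        fraction_id=fraction_id or f"synth-seed{config.seed}",
        sampling_rate_hz=config.sampling_rate_hz,
        markers=tuple(markers),
        tumor=TumorTrace(positions=tumor),
    )


@dataclass(frozen=True)
class CohortVariability:
    """Between-fraction parameter spreads (SDs of Gaussian perturbations)."""

    period_sd_s: float = 0.5
    amplitude_frac_sd: float = 0.2
    drift_sd_mm_per_min: float = 0.4


def simulate_cohort(
    n_fractions: int,
    base_config: SyntheticConfig | None = None,
    variability: CohortVariability | None = None,
    seed: int = 0,
) -> list[Fraction]:
    """Simulate a cohort of fractions with independently perturbed parameters.

    Each fraction's breathing period, amplitudes and drift are drawn around
    the base configuration; the whole cohort is deterministic given ``seed``.
    """
    if n_fractions < 1:
        raise ConfigurationError("n_fractions must be >= 1")
    base = base_config or SyntheticConfig()
    var = variability or CohortVariability()
    master = np.random.default_rng(seed)
    fractions = []
    for i in range(n_fractions):
        period = max(1.5, base.period_s + var.period_sd_s * master.standard_normal())
        amp_scale = max(0.1, 1.0 + var.amplitude_frac_sd * master.standard_normal())
        amps = tuple(float(a * amp_scale) for a in base.tumor_amplitude_mm)
        drift = tuple(
            float(d + var.drift_sd_mm_per_min * master.standard_normal())
            for d in base.drift_mm_per_min
        )
        child_seed = int(master.integers(0, 2**31 - 1))
        cfg = dataclasses.replace(
            base,
            period_s=float(period),
            tumor_amplitude_mm=amps,
            drift_mm_per_min=drift,
            seed=child_seed,
        )
        fractions.append(simulate_fraction(cfg, fraction_id=f"synth-{i:03d}"))
    return fractions
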