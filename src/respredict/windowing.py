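"""Train/test splitting, sliding-window pair construction and normalization.

The supervised arrangement: an input window of ``t_delay`` consecutive
external-marker samples (all markers, all three directions stacked as
channels) predicts the tumor position ``t_ahead`` samples after the window
ends. Sample indices are 1-based in documentation and reports, matching
the discrete-time convention t = 1..t_end; arrays are stored 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .signal_io import Fraction


@dataclass(frozen=True)
class WindowSpec:
    """Windowing geometry: input length, prediction horizon, split point (samples)."""

    t_delay: int
    t_ahead: int
    t_s: int

    def __post_init__(self):
        if self.t_delay < 1:
            raise ConfigurationError(f"t_delay must be >= 1, got {self.t_delay}")
        if self.t_ahead < 0:
            raise ConfigurationError(f"t_ahead must be >= 0, got {self.t_ahead}")
        if self.t_s < 1:
            raise ConfigurationError(f"t_s must be >= 1, got {self.t_s}")

    @classmethod
    def from_ms(cls, t_delay: int, ahead_ms: float, t_s: int, sampling_rate_hz: float) -> "WindowSpec":
        """Build a spec with the horizon given in milliseconds (400 ms -> 10 samples at 25 Hz)."""
        return cls(t_delay=t_delay, t_ahead=ms_to_samples(ahead_ms, sampling_rate_hz), t_s=t_s)

    def ahead_ms(self, sampling_rate_hz: float) -> float:
        return 1000.0 * self.t_ahead / sampling_rate_hz


def ms_to_samples(ahead_ms: float, sampling_rate_hz: float) -> int:
    return int(round(ahead_ms * sampling_rate_hz / 1000.0))


@dataclass(frozen=True)
class Segment:
    """A contiguous stretch of aligned input channels and tumor targets.

    ``start_index`` is the 1-based absolute index of the segment's first
    sample within its fraction, so windowed targets can report absolute
    sample positions.
    """

    inputs: np.ndarray   # (L, C) marker channels, mm (or normalized)
    targets: np.ndarray  # (L, 3) tumor (SI, AP, LR)
    start_index: int = 1

    def __post_init__(self):
        if len(self.inputs) != len(self.targets):
            raise ConfigurationError("segment inputs and targets must be aligned")

    def __len__(self) -> int:
        return len(self.inputs)


def fraction_to_arrays(fraction: Fraction, marker_subset=None) -> tuple[np.ndarray, np.ndarray]:
    """Stack marker channels into an (N, 3*m) input matrix and (N, 3) targets.

    ``marker_subset`` selects markers by their 1-based index (e.g. ``(1, 3)``);
    channel order follows the subset order, each marker contributing
    (SI, AP, LR).
    """
    by_index = {m.marker_index: m for m in fraction.markers}
    subset = tuple(marker_subset) if marker_subset is not None else tuple(sorted(by_index))
    missing = [i for i in subset if i not in by_index]
    if missing:
        raise ConfigurationError(f"fraction {fraction.fraction_id} has no marker(s) {missing}")
    X = np.hstack([by_index[i].positions for i in subset])
    return X, fraction.tumor.positions.copy()


def split_train_test(fraction: Fraction, t_s: int, marker_subset=None) -> tuple[Segment, Segment]:
    """Split at sample ``t_s``: train = samples 1..t_s, test = t_s+1..n."""
    n = fraction.n_samples
    if not 1 <= t_s < n:
        raise ConfigurationError(f"t_s must satisfy 1 <= t_s < n_samples={n}, got {t_s}")
    X, Y = fraction_to_arrays(fraction, marker_subset)
    train = Segment(X[:t_s], Y[:t_s], start_index=1)
    test = Segment(X[t_s:], Y[t_s:], start_index=t_s + 1)
    return train, test


@dataclass(frozen=True)
class WindowedDataset:
    """Supervised pairs: input windows and the tumor position each predicts."""

    inputs: np.ndarray          # (P, t_delay, C)
    targets: np.ndarray         # (P, 3)
    target_indices: np.ndarray  # (P,) absolute 1-based sample index of each target
    t_ahead: int

    def __len__(self) -> int:
        return len(self.inputs)


def make_pairs(segment: Segment, spec: WindowSpec) -> WindowedDataset:
    """Slide a stride-1 window over ``segment`` to build supervised pairs.

    With segment length L, produces L - t_delay - t_ahead + 1 pairs; pair j
    (1-based) uses input samples j..j+t_delay-1 and targets sample
    j + t_delay + t_ahead - 1, so the last pair's target is the segment's
    final sample and no input window reaches past target - t_ahead.
    """
    L = len(segment)
    min_len = spec.t_delay + spec.t_ahead
    n_pairs = L - min_len + 1
    if n_pairs < 1:
        raise ConfigurationError(
            f"segment of length {L} is too short for t_delay={spec.t_delay}, "
            f"t_ahead={spec.t_ahead}; need at least {min_len} samples"
        )
    windows = np.lib.stride_tricks.sliding_window_view(
        segment.inputs, spec.t_delay, axis=0
    )  # (L - t_delay + 1, C, t_delay)
    inputs = np.ascontiguousarray(np.swapaxes(windows[:n_pairs], 1, 2))
    target_pos = np.arange(n_pairs) + min_len - 1  # 0-based within segment
    targets = segment.targets[target_pos]
    target_indices = target_pos + segment.start_index
    return WindowedDataset(inputs=inputs, targets=targets,
                           target_indices=target_indices, t_ahead=spec.t_ahead)


@dataclass(frozen=True)
class Normalizer:
    """Per-channel affine standardization fitted on the training segment only.

    Constant channels get their scale clamped to 1 so apply() maps them to
    exactly zero and invert() remains well defined.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, data: np.ndarray, eps: float = 1e-12) -> "Normalizer":
        data = np.asarray(data, dtype=float)
        if data.size == 0:
            raise ConfigurationError("cannot fit a normalizer on an empty segment")
        mean = data.mean(axis=0)
        scale = data.std(axis=0)
        scale = np.where(scale < eps, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.scale

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.mean


def fit_normalizer(segment: Segment) -> tuple[Normalizer, Normalizer]:
    """Fit input- and target-channel normalizers on a training segment."""
    return Normalizer.fit(segment.inputs), Normalizer.fit(segment.targets)


def normalize_segment(segment: Segment, norm_x: Normalizer, norm_y: Normalizer) -> Segment:
    return Segment(norm_x.apply(segment.inputs), norm_y.apply(segment.targets),
                   start_index=segment.start_index)
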