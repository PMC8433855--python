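"""Per-fraction motion-trace data model and plain-text trace file I/O.

A *fraction* is one radiotherapy treatment session: synchronously sampled
positions of 1-3 external chest/abdomen markers and one internal tumor,
each resolved along the superior-inferior (SI), anterior-posterior (AP)
and left-right (LR) anatomical axes, in millimetres, at a fixed sampling
rate (25 Hz for CyberKnife Synchrony logs). Time is implicit: sample i
(1-based) corresponds to t = (i - 1) / sampling_rate_hz seconds.

File dialect
------------
Delimited text, one row per sample. ``#``-prefixed header lines carry
``fraction_id``, ``sampling_rate_hz`` and ``n_markers``, plus a ``columns``
line naming the data columns in their mandatory order::

    # fraction_id: demo
    # sampling_rate_hz: 25.0
    # n_markers: 3
    # columns: time M1_SI M1_AP M1_LR M2_SI M2_AP M2_LR M3_SI M3_AP M3_LR T_SI T_AP T_LR
    0 1.2 0.3 ...

Values are serialized with 17 significant digits so a write/read round
trip is bit-exact on float64 data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, TraceFormatError, TraceValidationError

#: Canonical anatomical direction order used in storage and every API.
DIRECTIONS = ("SI", "AP", "LR")

_FLOAT_FMT = "%.17g"


def _as_positions(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise TraceValidationError(
            f"positions must be an (n, 3) array of (SI, AP, LR) mm values, got shape {arr.shape}"
        )
    return arr


@dataclass(frozen=True)
class MarkerTrace:
    """Trajectory of one external marker, columns ordered (SI, AP, LR), mm."""

    marker_index: int
    positions: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positions", _as_positions(self.positions))

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class TumorTrace:
    """Internal tumor trajectory, columns ordered (SI, AP, LR), mm."""

    positions: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positions", _as_positions(self.positions))

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class Fraction:
    """One treatment fraction: aligned marker and tumor traces."""

    fraction_id: str
    sampling_rate_hz: float
    markers: tuple[MarkerTrace, ...]
    tumor: TumorTrace

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))
        findings = validate_fraction(self)
        if findings:
            raise TraceValidationError(
                "invalid fraction: " + "; ".join(f.message for f in findings)
            )

    @property
    def n_samples(self) -> int:
        return len(self.tumor)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds; sample 1 is t = 0."""
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class Finding:
    """One invariant violation discovered by :func:`validate_fraction`."""

    code: str
    message: str


def validate_fraction(fraction) -> list[Finding]:
    """Report every data-model invariant violated by ``fraction``.

    Total: never raises on malformed content; an empty list means valid.
    """
    findings: list[Finding] = []

    rate = getattr(fraction, "sampling_rate_hz", None)
    if not (isinstance(rate, (int, float)) and np.isfinite(rate) and rate > 0):
        findings.append(Finding("rate", f"sampling_rate_hz must be a positive finite number, got {rate!r}"))

    markers = list(getattr(fraction, "markers", []) or [])
    if not 1 <= len(markers) <= 3:
        findings.append(Finding("marker_count", f"expected 1-3 markers, got {len(markers)}"))
    seen: set[int] = set()
    for m in markers:
        idx = m.marker_index
        if idx not in (1, 2, 3):
            findings.append(Finding("marker_index", f"marker_index must be 1..3, got {idx}"))
        if idx in seen:
            findings.append(Finding("marker_index", f"duplicate marker_index {idx}"))
        seen.add(idx)

    tumor = getattr(fraction, "tumor", None)
    n = len(tumor) if tumor is not None else 0
    if n < 1:
        findings.append(Finding("n_samples", "fraction must contain at least one sample"))
    for m in markers:
        if len(m) != n:
            findings.append(
                Finding(
                    "length",
                    f"marker {m.marker_index} has {len(m)} samples but tumor has {n}",
                )
            )
    traces = [(f"marker {m.marker_index}", m.positions) for m in markers]
    if tumor is not None:
        traces.append(("tumor", tumor.positions))
    for name, pos in traces:
        if not np.all(np.isfinite(pos)):
            bad = int(np.argwhere(~np.isfinite(pos))[0][0]) + 1
            findings.append(Finding("finite", f"{name} trace has a non-finite value at row {bad}"))
    return findings


def _expected_columns(n_markers: int) -> list[str]:
    cols = ["time"]
    for m in range(1, n_markers + 1):
        cols += [f"M{m}_{d}" for d in DIRECTIONS]
    cols += [f"T_{d}" for d in DIRECTIONS]
    return cols


def read_fraction(path, expected_markers: int | None = None) -> Fraction:
    """Read and validate one fraction from a trace file.

    Parameters
    ----------
    path
        Trace file in the dialect documented at module level.
    expected_markers
        If given, the file's declared marker count must match; a mismatch
        raises :class:`ConfigurationError`.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"trace file not found: {path}")

    headers: dict[str, str] = {}
    data_rows: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    headers[key.strip()] = value.strip()
                continue
            data_rows.append((lineno, line))

    for key in ("sampling_rate_hz", "n_markers"):
        if key not in headers:
            raise TraceFormatError(f"{path}: missing required header '{key}'")
    try:
        rate = float(headers["sampling_rate_hz"])
        n_markers = int(headers["n_markers"])
    except ValueError as exc:
        raise TraceFormatError(f"{path}: malformed header value: {exc}") from exc
    fraction_id = headers.get("fraction_id", path.stem)

    if expected_markers is not None and n_markers != expected_markers:
        raise ConfigurationError(
            f"{path}: file declares {n_markers} markers but {expected_markers} were expected"
        )

    expected_cols = _expected_columns(n_markers)
    if "columns" in headers:
        declared = headers["columns"].split()
        if declared != expected_cols:
            missing = [c for c in expected_cols if c not in declared]
            if missing:
                raise TraceFormatError(f"{path}: missing column '{missing[0]}'")
            raise TraceFormatError(
                f"{path}: column order must be {' '.join(expected_cols)}, got {' '.join(declared)}"
            )

    if not data_rows:
        raise TraceValidationError(f"{path}: no data rows (n_samples must be >= 1)")

    n_cols = len(expected_cols)
    values = np.empty((len(data_rows), n_cols))
    for row_i, (lineno, line) in enumerate(data_rows):
        cells = line.split()
        if len(cells) != n_cols:
            raise TraceFormatError(
                f"{path}: line {lineno}: expected {n_cols} columns "
                f"({' '.join(expected_cols)}), got {len(cells)}"
            )
        for col_i, cell in enumerate(cells):
            try:
                v = float(cell)
            except ValueError as exc:
                raise TraceValidationError(
                    f"{path}: row {row_i + 1} (line {lineno}), column "
                    f"'{expected_cols[col_i]}': unparseable cell {cell!r}"
                ) from exc
            if not np.isfinite(v):
                raise TraceValidationError(
                    f"{path}: row {row_i + 1} (line {lineno}), column "
                    f"'{expected_cols[col_i]}': non-finite value"
                )
            values[row_i, col_i] = v

    markers = tuple(
        MarkerTrace(marker_index=m, positions=values[:, 1 + 3 * (m - 1): 1 + 3 * m])
        for m in range(1, n_markers + 1)
    )
    tumor = TumorTrace(positions=values[:, 1 + 3 * n_markers:])
    return Fraction(fraction_id=fraction_id, sampling_rate_hz=rate, markers=markers, tumor=tumor)


def write_fraction(fraction: Fraction, path) -> None:
    """Serialize ``fraction`` so that :func:`read_fraction` round-trips bit-exactly."""
    findings = validate_fraction(fraction)
    if findings:
        raise TraceValidationError(
            "refusing to write invalid fraction: " + "; ".join(f.message for f in findings)
        )
    path = Path(path)
    cols = _expected_columns(fraction.n_markers)
    times = fraction.times()
    blocks = [times[:, None]] + [m.positions for m in fraction.markers] + [fraction.tumor.positions]
    table = np.hstack(blocks)
    try:
        with open(path, "w") as fh:
            fh.write(f"# fraction_id: {fraction.fraction_id}\n")
            fh.write(f"# sampling_rate_hz: {_FLOAT_FMT % fraction.sampling_rate_hz}\n")
            fh.write(f"# n_markers: {fraction.n_markers}\n")
            fh.write(f"# columns: {' '.join(cols)}\n")
            for row in table:
                fh.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write trace file {path}: {exc}") from exc
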