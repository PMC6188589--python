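"""Extrasystolic coverage on a circular 24 h clock.

Coverage is the fraction of a record's duration lying within
``window_s`` (default 30 min) *after* at least one eligible
extrasystole. Each event at time ``t`` covers the half-open window
``[t, t + window_s)``; overlapping windows merge. By default the
recording is treated as a closed time loop: a window crossing the end
of the record wraps around to its beginning, so a single event always
covers exactly ``window_s`` seconds regardless of position. A no-wrap
mode truncates windows at the record end instead.

Records flagged not analyzable (atrial fibrillation, pacing, pervasive
arrhythmia) are assigned a coverage of 0 by convention, overall and per
type, while still reporting their observed event count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from escov.annotations_io import BeatSeries
from escov.classification import ELIGIBLE_CATEGORIES


@dataclass(frozen=True)
class CoverageConfig:
    """Coverage-window geometry: window length, record duration, wrap mode."""

    window_s: float = 1800.0
    duration_s: float = 86400.0
    wrap: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.window_s <= self.duration_s:
            raise ValueError(
                f"window_s must satisfy 0 < window_s <= duration_s, "
                f"got {self.window_s} vs {self.duration_s}"
            )


@dataclass
class CoverageResult:
    """Per-record extrasystolic coverage, overall and per type (fractions)."""

    record_id: str
    n_es: int
    coverage_all: float
    coverage_v: float
    coverage_s: float
    coverage_u: float
    analyzable: bool = True


def covered_intervals(
    event_times: Sequence[float] | np.ndarray, config: CoverageConfig = CoverageConfig()
) -> np.ndarray:
    """Merged union of post-event windows as disjoint half-open intervals.

    Returns an ``(k, 2)`` array of ``[start, end)`` pairs on
    ``[0, duration_s)``, sorted, disjoint and non-adjacent. Under wrap,
    a window crossing the record end contributes a tail piece and a
    head piece.
    """
    t = np.asarray(event_times, dtype=float)
    if t.size == 0:
        return np.empty((0, 2), dtype=float)
    if np.any((t < 0) | (t >= config.duration_s)):
        bad = t[(t < 0) | (t >= config.duration_s)][0]
        raise ValueError(f"event time {bad} outside [0, {config.duration_s})")
    d, w = config.duration_s, config.window_s
    starts = np.sort(t)
    ends = starts + w
    pieces: list[tuple[float, float]] = []
    for a, b in zip(starts, ends):
        if b <= d:
            pieces.append((a, b))
        elif config.wrap:
            pieces.append((a, d))
            pieces.append((0.0, b - d))
        else:
            pieces.append((a, d))
    pieces.sort()
    merged: list[list[float]] = []
    for a, b in pieces:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.asarray(merged, dtype=float)


def coverage_fraction(
    event_times: Sequence[float] | np.ndarray, config: CoverageConfig = CoverageConfig()
) -> float:
    """Total covered time divided by record duration; 0 for no events."""
    iv = covered_intervals(event_times, config)
    if iv.size == 0:
        return 0.0
    return float(np.sum(iv[:, 1] - iv[:, 0]) / config.duration_s)


def coverage_by_type(
    beats: BeatSeries,
    eligible: Sequence[tuple[float, str]],
    config: CoverageConfig | None = None,
) -> CoverageResult:
    """Coverage of one record overall and per extrasystole type.

    ``eligible`` holds (time_s, category) pairs with categories in
    {V, S, U}; erroneous detections (X) must already be filtered out.
    For a record flagged not analyzable every coverage is forced to 0
    while ``n_es`` reports the observed event count.
    """
    if config is None:
        config = CoverageConfig(duration_s=beats.duration_s)
    times = np.asarray([t for t, _ in eligible], dtype=float)
    labels = np.asarray([lab for _, lab in eligible], dtype="U1")
    bad = set(labels) - ELIGIBLE_CATEGORIES
    if bad:
        raise ValueError(
            f"eligible events must have labels in {sorted(ELIGIBLE_CATEGORIES)}; got {sorted(bad)}"
        )
    n_es = len(times)
    if not beats.analyzable:
        return CoverageResult(beats.record_id, n_es, 0.0, 0.0, 0.0, 0.0, analyzable=False)
    per_type = {
        lab: coverage_fraction(times[labels == lab], config) for lab in ("V", "S", "U")
    }
    return CoverageResult(
        record_id=beats.record_id,
        n_es=n_es,
        coverage_all=coverage_fraction(times, config),
        coverage_v=per_type["V"],
        coverage_s=per_type["S"],
        coverage_u=per_type["U"],
        analyzable=True,
    )
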