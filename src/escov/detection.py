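"""Rule-based detection of potentially eligible extrasystoles.

An extrasystole usable for fluid-responsiveness prediction must perturb
preload, which requires (a) a clearly premature beat and (b) a stable
sinus baseline against which the post-ectopic response can be read.
Both clauses are expressed purely on the RR tachogram:

1. **Prematurity** — the candidate RR interval is reduced by more than
   ``reduction_threshold`` (default 20%) relative to the immediately
   preceding interval.
2. **Sinus baseline** — none of the ``baseline_len`` (default 10) RR
   intervals preceding the candidate deviates from their median by more
   than ``baseline_tolerance`` (default 10%), which tolerates natural
   heart-rate variability while rejecting runs of ectopy, atrial
   fibrillation and artifacts.

Both thresholds are strict inequalities ("more than"): an exactly-20%
reduction does not trigger, an exactly-10% deviation does not disqualify.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from escov.annotations_io import RRSeries

CANDIDATE_COLUMNS = [
    "beat_index",
    "time_s",
    "ectopic_rr",
    "preceding_rr",
    "reduction",
    "baseline_median",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the two-clause detection rule.

    ``window_offset`` shifts the baseline window: 0 (default) uses the
    intervals ``rr[i - baseline_len .. i - 1]`` — i.e. the window ends
    with, and certifies, the reference interval of the prematurity
    clause; 1 excludes that interval (``rr[i-1-baseline_len .. i-2]``),
    for sensitivity analysis of the window anchoring.
    """

    reduction_threshold: float = 0.20
    baseline_len: int = 10
    baseline_tolerance: float = 0.10
    window_offset: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.reduction_threshold < 1:
            raise ValueError(f"reduction_threshold must be in (0,1), got {self.reduction_threshold}")
        if not 0 < self.baseline_tolerance < 1:
            raise ValueError(f"baseline_tolerance must be in (0,1), got {self.baseline_tolerance}")
        if self.baseline_len < 1:
            raise ValueError(f"baseline_len must be >= 1, got {self.baseline_len}")
        if self.window_offset not in (0, 1):
            raise ValueError(f"window_offset must be 0 or 1, got {self.window_offset}")


@dataclass(frozen=True)
class Candidate:
    """One potentially eligible extrasystole with its rule diagnostics.

    ``beat_index`` indexes the ectopic beat (the beat terminating the
    shortened interval) in the source BeatSeries; ``reduction`` is
    ``1 - ectopic_rr / preceding_rr``.
    """

    beat_index: int
    time_s: float
    ectopic_rr: float
    preceding_rr: float
    reduction: float
    baseline_median: float


def baseline_is_sinus(
    window: Sequence[float] | np.ndarray,
    tolerance: float = 0.10,
    *,
    baseline_len: int | None = None,
) -> bool:
    """Check the sinus-baseline clause on one window of RR intervals.

    True iff every interval lies within ``tolerance`` (fraction) of the
    window median; the median of an even-length window is the midpoint
    of the two central order statistics. If ``baseline_len`` is given,
    the window length is validated against it.
    """
    w = np.asarray(window, dtype=float)
    if baseline_len is not None and len(w) != baseline_len:
        raise ValueError(f"expected window of {baseline_len} intervals, got {len(w)}")
    if len(w) == 0:
        raise ValueError("empty baseline window")
    if np.any(w <= 0):
        raise ValueError("baseline window contains non-positive RR interval")
    med = float(np.median(w))
    return bool(np.all(np.abs(w - med) <= tolerance * med))


def detect_candidates(
    rr: RRSeries,
    config: DetectionConfig = DetectionConfig(),
    *,
    exclusion_mask: Sequence[tuple[float, float]] | None = None,
) -> list[Candidate]:
    """Scan an RR series for potentially eligible extrasystoles.

    An interval index ``i`` yields a candidate iff
    ``i >= baseline_len + 1 + window_offset`` (enough real history; no
    partial windows), the prematurity clause holds strictly, and the
    baseline clause holds on the preceding window. Candidates are
    returned in time order; the beat terminating the short interval is
    the ectopic beat.

    ``exclusion_mask`` optionally drops candidates whose time falls in
    any half-open ``[start, end)`` interval (e.g. unreadable ECG
    segments); the default is no exclusion.
    """
    x = rr.rr
    n = len(x)
    L = config.baseline_len
    start = L + 1 + config.window_offset
    out: list[Candidate] = []
    if n <= start:
        return out
    # prematurity clause, vectorized; baseline re-checked per hit
    prem = np.zeros(n, dtype=bool)
    prem[1:] = x[1:] < (1.0 - config.reduction_threshold) * x[:-1]
    for i in np.flatnonzero(prem):
        if i < start:
            continue
        lo = i - L - config.window_offset
        window = x[lo : lo + L]
        med = float(np.median(window))
        if not np.all(np.abs(window - med) <= config.baseline_tolerance * med):
            continue
        t = float(rr.end_times[i])
        if exclusion_mask and any(a <= t < b for a, b in exclusion_mask):
            continue
        out.append(
            Candidate(
                beat_index=int(i) + 1,
                time_s=t,
                ectopic_rr=float(x[i]),
                preceding_rr=float(x[i - 1]),
                reduction=float(1.0 - x[i] / x[i - 1]),
                baseline_median=med,
            )
        )
    return out


def candidates_to_frame(candidates: Sequence[Candidate]) -> pd.DataFrame:
    """Tabulate candidates with the standard output schema."""
    return pd.DataFrame(
        [[c.beat_index, c.time_s, c.ectopic_rr, c.preceding_rr, c.reduction, c.baseline_median] for c in candidates],
        columns=CANDIDATE_COLUMNS,
    )


def write_candidates(candidates: Sequence[Candidate], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, index=False)


def read_candidates(path: str | Path) -> list[Candidate]:
    df = pd.read_csv(path)
    return [
        Candidate(
            beat_index=int(r.beat_index),
            time_s=float(r.time_s),
            ectopic_rr=float(r.ectopic_rr),
            preceding_rr=float(r.preceding_rr),
            reduction=float(r.reduction),
            baseline_median=float(r.baseline_median),
        )
        for r in df.itertuples()
    ]
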