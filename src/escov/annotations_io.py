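"""Beat-annotation I/O and RR-interval derivation.

A record is a sequence of timestamped, labeled heartbeats covering (up
to) 24 hours. Labels use a five-letter vocabulary: ``N`` sinus beat,
``V`` ventricular extrasystole, ``S`` supraventricular extrasystole,
``U`` extrasystole of unknown origin, ``X`` erroneous detection /
artifact (not a beat). The on-disk format is a two-column CSV
(``time_s,label``) with an optional JSON metadata sidecar
(``record_id``, ``duration_s``, ``analyzable``).

An approximate mapping to WFDB annotation codes, for users converting
PhysioNet-style annotations upstream, is ``N<->N``, ``V<->V``,
``S<->A/S``, ``U<->Q``, ``X<->artifact``; no WFDB dependency is taken.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

VALID_LABELS = frozenset({"N", "V", "S", "U", "X"})

#: Ectopic (extrasystole) labels — everything that can count as an event.
ECTOPIC_LABELS = frozenset({"V", "S", "U"})

#: Floor below which an RR interval is treated as an annotation error
#: (no physiologic beat-to-beat interval this short in adults).
MIN_PLAUSIBLE_RR_S = 0.2


class AnnotationError(ValueError):
    """Raised for malformed or physiologically invalid beat annotations."""


@dataclass
class BeatSeries:
    """Timestamped, labeled heartbeats of one record.

    Parameters
    ----------
    record_id : str
        Identifier of the recording.
    times : ndarray of float
        Beat times in seconds from record start, strictly increasing,
        all within ``[0, duration_s)``.
    labels : ndarray of str
        One label per beat, drawn from ``{N, V, S, U, X}``.
    duration_s : float
        Nominal record duration in seconds (default 24 h).
    analyzable : bool
        Whether the record admits rule-based analysis. Records with
        atrial fibrillation, pacing or pervasive arrhythmia are flagged
        not analyzable by the analyst (never inferred here) and are
        assigned zero coverage downstream.
    """

    record_id: str
    times: np.ndarray
    labels: np.ndarray
    duration_s: float = 86400.0
    analyzable: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.duration_s <= 0:
            raise AnnotationError(f"duration_s must be positive, got {self.duration_s}")
        if self.times.ndim != 1 or self.labels.ndim != 1:
            raise AnnotationError("times and labels must be one-dimensional")
        if len(self.times) != len(self.labels):
            raise AnnotationError(
                f"times ({len(self.times)}) and labels ({len(self.labels)}) differ in length"
            )
        bad = set(np.unique(self.labels)) - VALID_LABELS if len(self.labels) else set()
        if bad:
            raise AnnotationError(f"unknown beat labels: {sorted(bad)}")
        if len(self.times):
            if self.times[0] < 0 or self.times[-1] >= self.duration_s:
                raise AnnotationError(
                    "beat times must satisfy 0 <= t < duration_s "
                    f"(got range [{self.times[0]}, {self.times[-1]}], duration {self.duration_s})"
                )
            if np.any(np.diff(self.times) <= 0):
                i = int(np.argmax(np.diff(self.times) <= 0))
                raise AnnotationError(
                    f"beat times must be strictly increasing (violation at beat {i + 1}, "
                    f"t={self.times[i + 1]})"
                )

    @property
    def n_beats(self) -> int:
        return len(self.times)


@dataclass
class RRSeries:
    """Consecutive inter-beat (RR) intervals of one record.

    ``rr[i]`` is the interval terminated by the source series' beat
    ``i + 1``; ``end_times[i]`` is that beat's time.
    """

    record_id: str
    rr: np.ndarray
    end_times: np.ndarray

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.end_times = np.asarray(self.end_times, dtype=float)
        if len(self.rr) != len(self.end_times):
            raise AnnotationError("rr and end_times must be parallel")
        if np.any(self.rr <= 0):
            raise AnnotationError("all RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.rr)


def read_beats(
    path: str | Path,
    duration_s: float | None = None,
    *,
    record_id: str | None = None,
    analyzable: bool | None = None,
) -> BeatSeries:
    """Read a beat-annotation CSV (header ``time_s,label``) into a BeatSeries.

    A JSON sidecar ``<stem>.meta.json`` next to the file, if present,
    supplies ``record_id``, ``duration_s`` and ``analyzable``; explicit
    arguments override it. Rows are sorted by time if needed; duplicate
    timestamps and times at or beyond the record duration are rejected.
    """
    path = Path(path)
    meta = _read_sidecar(path)
    if duration_s is None:
        duration_s = float(meta.get("duration_s", 86400.0))
    if record_id is None:
        record_id = str(meta.get("record_id", path.stem.removesuffix(".beats")))
    if analyzable is None:
        analyzable = bool(meta.get("analyzable", True))

    times: list[float] = []
    labels: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:2]] != ["time_s", "label"]:
            raise AnnotationError(f"{path}: expected header 'time_s,label', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise AnnotationError(f"{path}:{lineno}: malformed row {row!r}")
            try:
                t = float(row[0])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad time {row[0]!r}") from exc
            label = row[1].strip()
            if label not in VALID_LABELS:
                raise AnnotationError(
                    f"{path}:{lineno}: unknown beat label {label!r} "
                    f"(expected one of {sorted(VALID_LABELS)})"
                )
            if t >= duration_s or t < 0:
                raise AnnotationError(
                    f"{path}:{lineno}: time {t} outside [0, {duration_s})"
                )
            times.append(t)
            labels.append(label)

    t_arr = np.asarray(times, dtype=float)
    l_arr = np.asarray(labels, dtype="U1")
    order = np.argsort(t_arr, kind="stable")
    t_arr, l_arr = t_arr[order], l_arr[order]
    dup = np.flatnonzero(np.diff(t_arr) == 0)
    if len(dup):
        raise AnnotationError(f"{path}: duplicate beat time {t_arr[dup[0]]}")
    return BeatSeries(
        record_id=record_id,
        times=t_arr,
        labels=l_arr,
        duration_s=duration_s,
        analyzable=analyzable,
    )


def write_beats(beats: BeatSeries, path: str | Path, *, write_sidecar: bool = True) -> None:
    """Write a BeatSeries as CSV (times at 1 ms precision) plus metadata sidecar."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "label"])
        for t, lab in zip(beats.times, beats.labels):
            writer.writerow([f"{t:.3f}", lab])
    if write_sidecar:
        meta = {
            "record_id": beats.record_id,
            "duration_s": beats.duration_s,
            "analyzable": beats.analyzable,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def rr_from_beats(
    beats: BeatSeries, *, min_rr_s: float = MIN_PLAUSIBLE_RR_S, allow_fast: bool = False
) -> RRSeries:
    """Derive the RR-interval series from a BeatSeries.

    Intervals shorter than ``min_rr_s`` (default 0.2 s) are rejected as
    annotation errors unless ``allow_fast`` is set.
    """
    if beats.n_beats < 2:
        raise AnnotationError(
            f"insufficient beats: need >= 2, got {beats.n_beats}"
        )
    rr = np.diff(beats.times)
    if not allow_fast and np.any(rr < min_rr_s):
        i = int(np.argmax(rr < min_rr_s))
        raise AnnotationError(
            f"implausibly short RR interval {rr[i]:.4f} s at beat {i + 1} "
            f"(floor {min_rr_s} s; pass allow_fast=True to accept)"
        )
    return RRSeries(record_id=beats.record_id, rr=rr, end_times=beats.times[1:].copy())


def _sidecar_path(path: Path) -> Path:
    stem = path.name.removesuffix(".csv").removesuffix(".beats")
    return path.with_name(stem + ".meta.json")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        return json.loads(sidecar.read_text(encoding="utf-8"))
    return {}
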