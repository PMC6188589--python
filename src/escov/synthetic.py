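"""Arrhythmia-aware synthetic RR-tachogram generator.

Emits annotated 24 h beat series with the statistical structure the
analysis pipeline assumes, so every stage is testable without clinical
waveform data:

* **Sinus rhythm** — the instantaneous sinus RR interval is
  ``(60 / base_hr_bpm) * (1 + circadian_amplitude * sin(2*pi*t/86400 + phi))``
  modulated by multiplicative Gaussian beat-to-beat noise with
  coefficient of variation ``rr_noise_cv``, truncated at +/- 3 SD so
  intervals stay positive and the 10%-of-median baseline band has a
  controllable failure probability.
* **Ventricular extrasystoles** — a premature beat with coupling
  interval ``coupling_fraction * r`` (``r`` the local sinus RR)
  followed by a full compensatory pause ``(2 - coupling_fraction) * r``:
  the sinus lattice is preserved (coupling + pause = 2 r).
* **Supraventricular extrasystoles** — same coupling, but the sinus
  node is reset: the pause equals one local sinus RR, shifting all
  later beats earlier by ``(1 - coupling_fraction) * r``.
* **Atrial fibrillation segments** — optional intervals where RR is
  drawn iid Uniform(0.35 s, 1.20 s) and ectopic insertion is
  suppressed, emulating the irregularly irregular rhythm that defeats
  the sinus-baseline criterion.

Ectopic events arrive as independent Poisson processes and are thinned
to honor a minimum separation in beats, which makes every inserted
event eligible by construction (clean sinus baseline) and gives
sensitivity analyses an exact denominator. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from escov.annotations_io import BeatSeries
from escov.coverage import CoverageConfig, coverage_fraction

_AF_RR_LOW, _AF_RR_HIGH = 0.35, 1.20


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated 24 h recording.

    ``coupling_fraction`` must stay below 0.8 for constructed ectopics
    to satisfy a 20% prematurity rule in the noiseless limit.
    ``min_ectopic_separation_beats`` spaces events far enough apart
    that each one's 10-interval baseline is pure sinus; setting
    ``enforce_separation=False`` disables the thinning (events may
    then land in each other's baselines, as in bigeminy).
    ``circadian_phase`` pins the phase ``phi``; None randomizes it per
    record.
    """

    duration_s: float = 86400.0
    base_hr_bpm: float = 80.0
    circadian_amplitude: float = 0.08
    rr_noise_cv: float = 0.03
    ves_rate_per_h: float = 0.7
    sves_rate_per_h: float = 1.3
    coupling_fraction: float = 0.60
    min_ectopic_separation_beats: int = 12
    af_segments: tuple[tuple[float, float], ...] = ()
    seed: int = 0
    circadian_phase: float | None = None
    enforce_separation: bool = True
    record_id: str = "sim"

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.base_hr_bpm <= 0:
            raise ValueError("duration_s and base_hr_bpm must be positive")
        if not 0 < self.coupling_fraction < 1:
            raise ValueError(f"coupling_fraction must be in (0,1), got {self.coupling_fraction}")
        if self.rr_noise_cv < 0 or self.ves_rate_per_h < 0 or self.sves_rate_per_h < 0:
            raise ValueError("rates and rr_noise_cv must be non-negative")
        segs = sorted(self.af_segments)
        for (a, b) in segs:
            if not (0 <= a < b <= self.duration_s):
                raise ValueError(f"AF segment ({a}, {b}) out of range")
        for (_, b1), (a2, _) in zip(segs, segs[1:]):
            if a2 < b1:
                raise ValueError("AF segments overlap")


@dataclass
class GroundTruth:
    """Inserted ectopic events of one simulated record.

    ``eligible`` marks events whose construction honored the minimum
    separation and landed outside AF segments (always true in the
    default thinned mode); ``true_coverage`` is the coverage fraction
    of the eligible events on the record's circular clock.
    """

    times: np.ndarray
    types: np.ndarray
    eligible: np.ndarray
    true_coverage: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.types = np.asarray(self.types, dtype="U1")
        self.eligible = np.asarray(self.eligible, dtype=bool)


def simulate_record(config: SimConfig) -> tuple[BeatSeries, GroundTruth]:
    """Generate one annotated beat series plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    phi = (
        float(rng.uniform(0.0, 2.0 * math.pi))
        if config.circadian_phase is None
        else float(config.circadian_phase)
    )
    base_rr = 60.0 / config.base_hr_bpm
    d = config.duration_s
    cv = config.rr_noise_cv
    segs = sorted(config.af_segments)

    def sinus_rr0(t: float) -> float:
        return base_rr * (1.0 + config.circadian_amplitude * math.sin(2.0 * math.pi * t / 86400.0 + phi))

    def in_af(t: float) -> bool:
        return any(a <= t < b for a, b in segs)

    # sinus/AF beat lattice; noise pre-drawn in blocks for speed
    times = [0.0]
    rr_noiseless: list[float] = []  # noiseless local sinus RR of each interval
    af_beat: list[bool] = [in_af(0.0)]
    block = rng.normal(0.0, 1.0, size=4096)
    bi = 0
    t = 0.0
    while True:
        r0 = sinus_rr0(t)
        if in_af(t):
            rr = float(rng.uniform(_AF_RR_LOW, _AF_RR_HIGH))
        elif cv > 0:
            if bi == len(block):
                block = rng.normal(0.0, 1.0, size=4096)
                bi = 0
            eps = float(np.clip(block[bi] * cv, -3.0 * cv, 3.0 * cv))
            bi += 1
            rr = r0 * (1.0 + eps)
        else:
            rr = r0
        t_next = t + rr
        if t_next >= d:
            break
        times.append(t_next)
        rr_noiseless.append(r0)
        af_beat.append(in_af(t_next))
        t = t_next

    times_arr = np.asarray(times)
    n = len(times_arr)
    labels = np.full(n, "N", dtype="U1")
    rr = np.diff(times_arr)
    r0_arr = np.asarray(rr_noiseless)  # r0_arr[i] is the noiseless RR of interval i
    af_arr = np.asarray(af_beat, dtype=bool)

    # Poisson event times, mapped to the beat they replace
    raw: list[tuple[float, str]] = []
    for rate, lab in ((config.ves_rate_per_h, "V"), (config.sves_rate_per_h, "S")):
        if rate > 0:
            k = rng.poisson(rate * d / 3600.0)
            for et in rng.uniform(0.0, d, size=k):
                raw.append((float(et), lab))
    raw.sort()

    min_sep = config.min_ectopic_separation_beats
    guard = max(min_sep, 12)  # enough history for a full 10-interval baseline
    chosen: list[tuple[int, str, bool]] = []  # (beat index, type, eligible)
    last_idx = -10**9
    for et, lab in raw:
        b = int(np.searchsorted(times_arr, et, side="left"))
        if b < guard or b > n - 2:
            continue
        # suppress insertion inside AF; eligibility also needs a clean lookback
        if af_arr[b]:
            continue
        clean = not af_arr[max(0, b - guard - 1) : b + 2].any()
        sep_ok = b - last_idx >= min_sep
        if config.enforce_separation:
            if not (sep_ok and clean):
                continue
            eligible = True
        else:
            if b - last_idx < 2:  # interval edits must not collide
                continue
            eligible = sep_ok and clean
        chosen.append((b, lab, eligible))
        last_idx = b

    c = config.coupling_fraction
    for b, lab, _ in chosen:
        r_loc = r0_arr[b - 1]
        rr[b - 1] = c * r_loc
        rr[b] = (2.0 - c) * r_loc if lab == "V" else r_loc
        labels[b] = lab

    new_times = np.empty(n)
    new_times[0] = times_arr[0]
    new_times[1:] = times_arr[0] + np.cumsum(rr)
    keep = new_times < d
    new_times, labels = new_times[keep], labels[keep]

    ev_times = np.asarray([new_times[b] for b, _, _ in chosen if b < len(new_times)])
    ev_types = np.asarray([lab for b, lab, _ in chosen if b < len(new_times)], dtype="U1")
    ev_elig = np.asarray([el for b, _, el in chosen if b < len(new_times)], dtype=bool)
    truth = GroundTruth(
        times=ev_times,
        types=ev_types,
        eligible=ev_elig,
        true_coverage=coverage_fraction(
            ev_times[ev_elig] if len(ev_times) else ev_times,
            CoverageConfig(duration_s=d),
        ),
    )
    beats = BeatSeries(
        record_id=config.record_id,
        times=new_times,
        labels=labels,
        duration_s=d,
        analyzable=not segs,
    )
    return beats, truth


def simulate_raters(
    truth: Sequence[str] | np.ndarray,
    confusion_a: np.ndarray,
    confusion_b: np.ndarray,
    seed: int | None = None,
    categories: Sequence[str] = ("V", "S", "U", "X"),
):
    """Draw two raters' labels from per-rater confusion matrices.

    ``confusion_a[i, j]`` is the probability that the rater assigns
    category ``categories[j]`` to an event whose true category is
    ``categories[i]``; rows must sum to 1. The two raters err
    independently given the truth. Returns a RatingPair.
    """
    from escov.cohort_stats import RatingPair

    cats = list(categories)
    truth_arr = np.asarray(truth)
    lookup = {c: i for i, c in enumerate(cats)}
    idx = np.asarray([lookup[c] for c in truth_arr])
    rng = np.random.default_rng(seed)
    out = []
    for cm in (np.asarray(confusion_a, dtype=float), np.asarray(confusion_b, dtype=float)):
        if cm.shape != (len(cats), len(cats)):
            raise ValueError(f"confusion matrix must be {len(cats)}x{len(cats)}, got {cm.shape}")
        if np.any(cm < 0) or not np.allclose(cm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion matrix rows must be non-negative and sum to 1")
        cum = np.cumsum(cm, axis=1)
        u = rng.random(len(idx))
        draws = (u[:, None] >= cum[idx]).sum(axis=1)
        out.append(np.asarray(cats)[draws])
    return RatingPair(a=out[0], b=out[1], categories=tuple(cats))
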