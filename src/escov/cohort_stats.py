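"""Cohort aggregation and interrater agreement statistics.

Per-record coverages are averaged across the cohort, either over all
records (non-analyzable ones at their assigned 0%) or over the
analyzable subgroup only, with percentile-bootstrap confidence
intervals across records. Interrater reliability of the candidate
ratings is summarized by simple percentage agreement and unweighted
Cohen's kappa, before and after collapsing categories (all extrasystole
types vs erroneous detection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from escov.coverage import CoverageResult

VARIANTS = ("all-records", "analyzable-only")
TYPE_FIELDS = {"all": "coverage_all", "V": "coverage_v", "S": "coverage_s", "U": "coverage_u"}


@dataclass
class CohortSummary:
    """Cohort-level coverage estimate with bootstrap CI, in percent."""

    n_total: int
    n_analyzable: int
    variant: str
    mean_coverage_pct: float
    ci_low_pct: float
    ci_high_pct: float
    by_type: dict[str, dict[str, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_analyzable": self.n_analyzable,
            "variant": self.variant,
            "mean_pct": self.mean_coverage_pct,
            "ci_pct": [self.ci_low_pct, self.ci_high_pct],
            "by_type": self.by_type,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


@dataclass
class RatingPair:
    """Two raters' parallel category assignments over the same events."""

    a: np.ndarray
    b: np.ndarray
    categories: tuple[str, ...] = ("V", "S", "U", "X")

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        self.b = np.asarray(self.b)
        if len(self.a) != len(self.b) or len(self.a) == 0:
            raise ValueError("rating vectors must be parallel and non-empty")
        cats = set(self.categories)
        extra = (set(np.unique(self.a)) | set(np.unique(self.b))) - cats
        if extra:
            raise ValueError(f"ratings outside declared categories: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.a)


@dataclass
class AgreementResult:
    """Interrater agreement summary; kappa is NaN when not computed."""

    n: int
    n_disagree: int
    percent_agreement: float
    kappa: float = float("nan")


def cohort_mean(
    results: Sequence[CoverageResult],
    variant: str = "all-records",
    type_filter: str = "all",
) -> float:
    """Arithmetic mean coverage across records, in percent.

    ``all-records`` includes non-analyzable records at their assigned
    0%; ``analyzable-only`` drops them first. ``type_filter`` selects
    the overall or a type-specific coverage field.
    """
    values = _select_coverages(results, variant, type_filter)
    return float(np.mean(values)) * 100.0


def bootstrap_percentile_ci(
    values: Sequence[float] | np.ndarray,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval of a statistic.

    Resamples ``values`` with replacement (same length) ``n_boot``
    times and returns the empirical ``alpha/2`` and ``1 - alpha/2``
    quantiles of the resampled statistic, using the linear-interpolation
    quantile convention. Deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError(f"need at least 2 values to bootstrap, got {len(x)}")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    samples = x[idx]
    if statistic is np.mean:
        stats = samples.mean(axis=1)
    else:
        stats = np.asarray([statistic(row) for row in samples], dtype=float)
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def cohort_summary(
    results: Sequence[CoverageResult],
    variant: str = "all-records",
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> CohortSummary:
    """Mean coverage with bootstrap CI, overall and per extrasystole type.

    The bootstrap resamples records (patients), not individual beats:
    the CI expresses between-record sampling variability of the cohort
    mean. Per-type seeds are derived from ``seed`` so the four CIs are
    independently resampled yet jointly reproducible.
    """
    by_type: dict[str, dict[str, float]] = {}
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(TYPE_FIELDS))
    summary_mean = ci = None
    for (tf, _), child in zip(TYPE_FIELDS.items(), children):
        values = _select_coverages(results, variant, tf) * 100.0
        mean = float(np.mean(values))
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        lo, hi = bootstrap_percentile_ci(values, np.mean, n_boot, alpha, seed=sub_seed)
        by_type[tf] = {"mean_pct": mean, "ci_low_pct": lo, "ci_high_pct": hi}
        if tf == "all":
            summary_mean, ci = mean, (lo, hi)
    return CohortSummary(
        n_total=len(results),
        n_analyzable=sum(r.analyzable for r in results),
        variant=variant,
        mean_coverage_pct=summary_mean,
        ci_low_pct=ci[0],
        ci_high_pct=ci[1],
        by_type=by_type,
        n_boot=n_boot,
        seed=seed,
    )


def percent_agreement(pair: RatingPair) -> AgreementResult:
    """Simple percentage agreement between two raters."""
    n = len(pair)
    n_disagree = int(np.sum(pair.a != pair.b))
    return AgreementResult(
        n=n, n_disagree=n_disagree, percent_agreement=100.0 * (n - n_disagree) / n
    )


def cohen_kappa(pair: RatingPair) -> float:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement fraction; ``p_e`` the chance
    agreement implied by the product of the two raters' marginal
    category frequencies. If both raters are constant and identical
    (p_e == 1 with perfect agreement) the conventional value 1 is
    returned with a warning.
    """
    cats = list(pair.categories)
    n = len(pair)
    p_a = np.array([np.mean(pair.a == c) for c in cats])
    p_b = np.array([np.mean(pair.b == c) for c in cats])
    p_o = float(np.mean(pair.a == pair.b))
    p_e = float(np.dot(p_a, p_b))
    if p_e >= 1.0:
        warnings.warn(
            "both raters constant and identical: kappa undefined, returning 1 by convention",
            stacklevel=2,
        )
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def rate_agreement(pair: RatingPair) -> AgreementResult:
    """Percentage agreement and Cohen's kappa in one result."""
    res = percent_agreement(pair)
    res.kappa = cohen_kappa(pair)
    return res


def collapse_pair(pair: RatingPair, mapping: Mapping[str, str]) -> RatingPair:
    """Map both rating vectors through a category-collapse table."""
    missing = set(pair.categories) - set(mapping)
    if missing:
        raise ValueError(f"mapping does not cover categories: {sorted(missing)}")
    lut = dict(mapping)
    a = np.asarray([lut[v] for v in pair.a])
    b = np.asarray([lut[v] for v in pair.b])
    new_cats = tuple(dict.fromkeys(lut[c] for c in pair.categories))
    return RatingPair(a=a, b=b, categories=new_cats)


def prevalence_pct(flags: Sequence[bool] | np.ndarray) -> float:
    """Percentage of records satisfying a condition (e.g. has >= 1 event)."""
    f = np.asarray(flags, dtype=bool)
    if len(f) == 0:
        raise ValueError("empty selection")
    return 100.0 * float(np.mean(f))


def _select_coverages(
    results: Sequence[CoverageResult], variant: str, type_filter: str
) -> np.ndarray:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r} (expected one of {VARIANTS})")
    if type_filter not in TYPE_FIELDS:
        raise ValueError(f"unknown type filter {type_filter!r}")
    selected = [r for r in results if variant == "all-records" or r.analyzable]
    if not selected:
        raise ValueError("empty selection after variant filtering")
    fieldname = TYPE_FIELDS[type_filter]
    return np.asarray([getattr(r, fieldname) for r in selected], dtype=float)
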