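"""Deterministic extrasystole typing and rater adjudication.

Raters assign each detected candidate one of four categories:
``V`` ventricular extrasystole, ``S`` supraventricular extrasystole,
``U`` extrasystole of unknown origin, ``X`` erroneous detection.

The ventricular criteria are morphological: wide QRS complex
(> 120 ms), absent P-wave, altered T-wave morphology. A candidate
satisfying all three is ventricular; one satisfying none is
supraventricular; partial matches are forced to "unknown origin" — a
deterministic stand-in for a human rater's judgment call that errs
toward under-counting the specific types.

Disagreements between two raters are resolved conservatively by
default: a type disagreement among eligible categories becomes ``U``,
and any disagreement about eligibility itself (one rater says ``X``)
becomes ``X``. An ``eligible-wins`` policy is available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

RATER_CATEGORIES = ("V", "S", "U", "X")
ELIGIBLE_CATEGORIES = frozenset({"V", "S", "U"})

ADJUDICATION_POLICIES = ("conservative", "eligible-wins")

#: Category collapse used for the eligible-vs-erroneous super-category analysis.
ELIGIBILITY_MAPPING = {"V": "eligible", "S": "eligible", "U": "eligible", "X": "erroneous"}


@dataclass(frozen=True)
class MorphologyFeatures:
    """Visually assessed ECG morphology of one candidate extrasystole."""

    qrs_duration_ms: float
    p_wave_present: bool
    t_wave_altered: bool

    def __post_init__(self) -> None:
        if self.qrs_duration_ms <= 0:
            raise ValueError(f"qrs_duration_ms must be positive, got {self.qrs_duration_ms}")


def classify_morphology(features: MorphologyFeatures, qrs_threshold_ms: float = 120.0) -> str:
    """Map morphology features to a category in {V, S, U}.

    Counts the satisfied ventricular criteria (wide QRS, absent P,
    altered T): all three -> V, none -> S, otherwise -> U. Never
    returns X — eligibility is decided upstream of typing.
    """
    n_met = sum(
        (
            features.qrs_duration_ms > qrs_threshold_ms,
            not features.p_wave_present,
            features.t_wave_altered,
        )
    )
    if n_met == 3:
        return "V"
    if n_met == 0:
        return "S"
    return "U"


def adjudicate(a: str, b: str, policy: str = "conservative") -> str:
    """Resolve two raters' category labels into one consensus label.

    Agreement returns the shared label. Under ``conservative``, a type
    disagreement within {V, S, U} yields U and any eligibility
    disagreement (one label X) yields X; under ``eligible-wins`` the
    non-X label survives an eligibility disagreement.
    """
    for lab in (a, b):
        if lab not in RATER_CATEGORIES:
            raise ValueError(f"unknown rater category {lab!r}")
    if policy not in ADJUDICATION_POLICIES:
        raise ValueError(f"unknown adjudication policy {policy!r}")
    if a == b:
        return a
    if "X" in (a, b):
        if policy == "conservative":
            return "X"
        return a if b == "X" else b
    return "U"


def collapse_to_eligibility(label: str) -> str:
    """Collapse a four-way category into eligible vs erroneous."""
    try:
        return ELIGIBILITY_MAPPING[label]
    except KeyError:
        raise ValueError(f"unknown rater category {label!r}") from None
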