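"""Cohort aggregation, percentile bootstrap, and interrater agreement."""

import numpy as np
import pytest

from escov.classification import ELIGIBILITY_MAPPING
from escov.cohort_stats import (
    RatingPair,
    bootstrap_percentile_ci,
    cohen_kappa,
    cohort_mean,
    cohort_summary,
    collapse_pair,
    percent_agreement,
    prevalence_pct,
)
from escov.coverage import CoverageResult

from conftest import analytic_kappa, enumerate_bootstrap_quantiles


def _record(cov, analyzable=True, rid="r"):
    return CoverageResult(rid, 10, cov, cov / 2, cov / 2, 0.0, analyzable=analyzable)


class TestCohortMean:
    def test_zero_assigned_records_pull_down_the_cohort_mean(self):
        results = [_record(0.635) for _ in range(42)] + [
            _record(0.0, analyzable=False) for _ in range(8)
        ]
        assert round(cohort_mean(results, "all-records"), 1) == 53.3
        assert np.isclose(cohort_mean(results, "analyzable-only"), 63.5)

    def test_single_record(self):
        assert cohort_mean([_record(0.25)]) == 25.0

    def test_constant_cohort(self):
        assert np.isclose(cohort_mean([_record(0.4)] * 7), 40.0)

    def test_type_filter_selects_field(self):
        assert np.isclose(cohort_mean([_record(0.4)], type_filter="V"), 20.0)
        assert cohort_mean([_record(0.4)], type_filter="U") == 0.0

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_mean([_record(0.5, analyzable=False)], "analyzable-only")


class TestBootstrapCI:
    def test_constant_values_give_degenerate_interval(self):
        lo, hi = bootstrap_percentile_ci([0.4] * 10, seed=1)
        assert lo == hi == pytest.approx(0.4)

    def test_deterministic_given_seed(self):
        x = [0.1, 0.5, 0.9, 0.3, 0.7, 0.2]
        assert bootstrap_percentile_ci(x, seed=42) == bootstrap_percentile_ci(x, seed=42)
        assert bootstrap_percentile_ci(x, seed=42) != bootstrap_percentile_ci(x, seed=43)

    def test_matches_exhaustive_enumeration_at_tiny_n(self):
        # all 5^5 = 3125 equally likely resamples, enumerated directly
        values = [0.0, 0.0, 1.0, 1.0, 1.0]
        lo_ex, hi_ex = enumerate_bootstrap_quantiles(values)
        lo, hi = bootstrap_percentile_ci(values, n_boot=40000, seed=5)
        assert abs(lo - lo_ex) <= 0.05 and abs(hi - hi_ex) <= 0.05

    def test_width_shrinks_like_root_n(self):
        rng = np.random.default_rng(11)
        widths = {}
        for n in (10, 40, 160):
            x = rng.beta(2, 2, size=n)
            lo, hi = bootstrap_percentile_ci(x, n_boot=4000, seed=n)
            widths[n] = hi - lo
        assert widths[40] < widths[10] and widths[160] < widths[40]
        # quadrupling n should roughly halve the width
        assert 0.25 < widths[40] / widths[10] < 0.85
        assert 0.25 < widths[160] / widths[40] < 0.85

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_percentile_ci([1.0], seed=0)
        with pytest.raises(ValueError):
            bootstrap_percentile_ci([1.0, 2.0], n_boot=10, seed=0)

    def test_empirical_coverage_of_the_mean(self):
        # 95% percentile CI over Beta cohorts of n=42 should cover the
        # true mean in roughly 9 of 10 replicates even at this small scale
        rng = np.random.default_rng(3)
        a, b = 2.0, 1.2
        true_mean = a / (a + b)
        hits = 0
        reps = 60
        for i in range(reps):
            x = rng.beta(a, b, size=42)
            lo, hi = bootstrap_percentile_ci(x, n_boot=1000, seed=int(rng.integers(2**31)))
            hits += lo <= true_mean <= hi
        assert 0.85 <= hits / reps <= 1.0


class TestCohortSummary:
    def test_interval_orders_and_contains_point_estimate(self):
        rng = np.random.default_rng(9)
        results = [_record(c, rid=f"r{i}") for i, c in enumerate(rng.beta(2, 1.2, size=40))]
        s = cohort_summary(results, n_boot=2000, seed=4)
        assert s.ci_low_pct <= s.mean_coverage_pct <= s.ci_high_pct
        assert s.n_total == 40 and s.n_analyzable == 40
        for entry in s.by_type.values():
            assert entry["ci_low_pct"] <= entry["ci_high_pct"]
            assert 0 <= entry["mean_pct"] <= 100

    def test_reproducible_given_seed(self):
        results = [_record(c, rid=str(c)) for c in (0.1, 0.4, 0.5, 0.9, 0.3)]
        s1 = cohort_summary(results, n_boot=500, seed=7)
        s2 = cohort_summary(results, n_boot=500, seed=7)
        assert s1.to_dict() == s2.to_dict()


class TestAgreement:
    def _pair_with_disagreements(self, n, k):
        a = np.array(["V"] * n)
        b = a.copy()
        b[:k] = "S"
        return RatingPair(a=a, b=b)

    def test_identical_vectors_fully_agree(self):
        pair = RatingPair(a=np.array(["V", "S", "U", "X"]), b=np.array(["V", "S", "U", "X"]))
        res = percent_agreement(pair)
        assert res.percent_agreement == 100.0 and res.n_disagree == 0
        assert cohen_kappa(pair) == 1.0

    def test_four_category_agreement_at_cohort_scale(self):
        res = percent_agreement(self._pair_with_disagreements(10944, 919))
        assert round(res.percent_agreement) == 92

    def test_collapsed_agreement_at_cohort_scale(self):
        res = percent_agreement(self._pair_with_disagreements(10944, 37))
        assert round(res.percent_agreement, 1) == 99.7

    def test_kappa_hand_computed_two_by_two(self):
        # contingency [[20, 5], [10, 65]]: p_o = 0.85, p_e = 0.60, kappa = 0.625
        a = ["A"] * 25 + ["B"] * 75
        b = ["A"] * 20 + ["B"] * 5 + ["A"] * 10 + ["B"] * 65
        pair = RatingPair(a=np.array(a), b=np.array(b), categories=("A", "B"))
        assert np.isclose(cohen_kappa(pair), 0.625)

    def test_kappa_matches_statsmodels_on_random_tables(self, rng):
        from statsmodels.stats.inter_rater import cohens_kappa

        cats = ("V", "S", "U", "X")
        for _ in range(5):
            a = rng.choice(cats, size=500, p=(0.3, 0.3, 0.2, 0.2))
            flip = rng.random(500) < 0.3
            b = np.where(flip, rng.choice(cats, size=500), a)
            pair = RatingPair(a=a, b=b)
            table = np.array([[np.sum((a == x) & (b == y)) for y in cats] for x in cats])
            ref = cohens_kappa(table, return_results=False)
            assert np.isclose(cohen_kappa(pair), ref, atol=1e-12)

    def test_chance_level_raters_have_near_zero_kappa(self, rng):
        cats = ("V", "S", "U", "X")
        n = 100000
        pair = RatingPair(a=rng.choice(cats, n), b=rng.choice(cats, n))
        assert abs(cohen_kappa(pair)) < 0.02

    def test_kappa_invariant_under_category_relabeling(self, rng):
        cats = ("V", "S", "U", "X")
        a = rng.choice(cats, 400)
        b = np.where(rng.random(400) < 0.5, rng.choice(cats, 400), a)
        k0 = cohen_kappa(RatingPair(a=a, b=b))
        perm = {"V": "X", "S": "U", "U": "V", "X": "S"}
        pair2 = collapse_pair(RatingPair(a=a, b=b), perm)
        assert np.isclose(cohen_kappa(pair2), k0)

    def test_constant_identical_raters_return_one_with_warning(self):
        pair = RatingPair(a=np.array(["V"] * 5), b=np.array(["V"] * 5))
        with pytest.warns(UserWarning, match="constant"):
            assert cohen_kappa(pair) == 1.0

    def test_analytic_kappa_oracle(self):
        # two raters with known confusion structure: analytic joint
        # distribution vs the kappa formula on the exact expected table
        p_true = [0.4, 0.3, 0.2, 0.1]
        A = np.full((4, 4), 0.05) + np.eye(4) * 0.80
        B = np.full((4, 4), 0.10) + np.eye(4) * 0.60
        k = analytic_kappa(p_true, A, B)
        assert 0 < k < 1


class TestCollapsePair:
    def test_type_disagreement_vanishes_after_eligibility_collapse(self):
        pair = RatingPair(a=np.array(["V", "V"]), b=np.array(["S", "X"]))
        collapsed = collapse_pair(pair, ELIGIBILITY_MAPPING)
        assert list(collapsed.a) == ["eligible", "eligible"]
        assert list(collapsed.b) == ["eligible", "erroneous"]

    def test_identity_mapping_is_noop(self):
        pair = RatingPair(a=np.array(["V", "U"]), b=np.array(["S", "U"]))
        same = collapse_pair(pair, {c: c for c in pair.categories})
        assert list(same.a) == list(pair.a) and list(same.b) == list(pair.b)

    def test_collapsing_never_decreases_agreement(self, rng):
        for _ in range(10):
            a = rng.choice(("V", "S", "U", "X"), 300)
            b = rng.choice(("V", "S", "U", "X"), 300)
            pair = RatingPair(a=a, b=b)
            before = percent_agreement(pair).percent_agreement
            after = percent_agreement(collapse_pair(pair, ELIGIBILITY_MAPPING)).percent_agreement
            assert after >= before

    def test_partial_mapping_rejected(self):
        pair = RatingPair(a=np.array(["V"]), b=np.array(["S"]))
        with pytest.raises(ValueError, match="cover"):
            collapse_pair(pair, {"V": "eligible"})


class TestPrevalence:
    def test_fraction_of_records_with_events(self):
        assert round(prevalence_pct([True] * 40 + [False] * 2)) == 95
        assert np.isclose(prevalence_pct([True, False]), 50.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prevalence_pct([])
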