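"""Comparison statistics: test-path selection, exact oracles, tabulation."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats

from pmjq.model import Technique
from pmjq.stats import compare_age, compare_groups, summarize_cohort
from pmjq.synthetic import GeneratorSpec, generate_cohort


def fisher_2x2_oracle(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def freeman_halton_oracle(table):
    """Exact r×c conditional p by rational-arithmetic enumeration."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    n = sum(rows)

    def tables(i, colrem):
        if i == len(rows) - 1:
            if all(v >= 0 for v in colrem):
                yield [list(colrem)]
            return
        for combo in itertools.product(*[range(min(rows[i], colrem[j]) + 1)
                                         for j in range(len(cols))]):
            if sum(combo) == rows[i]:
                rem = [colrem[j] - combo[j] for j in range(len(cols))]
                for rest in tables(i + 1, rem):
                    yield [list(combo)] + rest

    def prob(t):
        num = Fraction(1)
        for r in rows:
            num *= math.factorial(r)
        for c in cols:
            num *= math.factorial(c)
        den = Fraction(math.factorial(n))
        for row in t:
            for v in row:
                den *= math.factorial(v)
        return num / den

    p_obs = prob(table)
    return float(sum(prob(t) for t in tables(0, list(cols)) if prob(t) <= p_obs))


class TestCompareGroups:
    def test_homogeneous_table_p_one(self):
        res = compare_groups([[10, 10], [10, 10]])
        assert res.test_name == "chi_square"
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_small_expected_takes_exact_path(self):
        res = compare_groups([[5, 0], [0, 5]])
        assert res.test_name == "fisher_exact"
        assert res.p_value == pytest.approx(0.007936507936507936, rel=1e-9)
        assert res.p_value == pytest.approx(fisher_2x2_oracle([[5, 0], [0, 5]]), rel=1e-9)

    @pytest.mark.parametrize(
        "table",
        [[[3, 1], [1, 3]], [[7, 2], [1, 6]], [[2, 5], [4, 1]], [[1, 1], [9, 2]]],
    )
    def test_fisher_matches_enumeration_oracle(self, table):
        res = compare_groups(table)
        assert res.test_name == "fisher_exact"
        assert res.p_value == pytest.approx(fisher_2x2_oracle(table), rel=1e-9)

    def test_large_expected_takes_chisquare_path(self):
        res = compare_groups([[71, 28], [2, 24], [5, 75]])
        assert res.test_name == "chi_square"
        assert res.p_value < 0.001

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 2, 1], [1, 2, 4]],
            [[1, 0, 3], [2, 3, 0], [0, 2, 2]],
            [[5, 1], [2, 2], [0, 4]],
        ],
    )
    def test_rxc_exact_matches_rational_enumeration(self, table):
        """Own r×c exact test vs exact-arithmetic brute force over all tables."""
        res = compare_groups(table)
        assert res.test_name == "freeman_halton_exact"
        assert res.p_value == pytest.approx(freeman_halton_oracle(table), rel=1e-9)

    def test_rxc_exact_consistent_with_scipy(self):
        """scipy's randomized r×c Fisher lands near the exact value.

        scipy >= 1.15 approximates r×c Fisher p-values by Monte Carlo, so
        agreement is only expected within its resampling error.
        """
        table = np.array([[5, 1], [2, 2], [0, 4]])
        res = compare_groups(table)
        ref = scipy.stats.fisher_exact(table).pvalue
        se = math.sqrt(ref * (1 - ref) / 10_000)  # scipy's default resamples
        assert abs(res.p_value - ref) < 5 * se

    def test_monte_carlo_agrees_with_enumeration(self):
        table = [[4, 1, 2], [1, 3, 3]]
        exact = compare_groups(table)
        mc = compare_groups(table, max_enumeration=5, mc_replicates=40_000, mc_seed=3)
        assert mc.detail["method"] == "monte_carlo"
        # add-one MC estimator: 3 sigma binomial band around the exact value
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 40_000)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 1e-4

    def test_monte_carlo_is_seeded(self):
        kw = dict(max_enumeration=5, mc_replicates=2000)
        a = compare_groups([[4, 1, 2], [1, 3, 3]], mc_seed=7, **kw)
        b = compare_groups([[4, 1, 2], [1, 3, 3]], mc_seed=7, **kw)
        assert a.p_value == b.p_value

    def test_chisquare_agrees_with_permutation_estimate(self):
        """Asymptotic path sanity-checked against a Monte-Carlo null."""
        table = np.array([[20, 30], [35, 15]])
        res = compare_groups(table)
        assert res.test_name == "chi_square"
        rng = np.random.default_rng(11)
        rows = np.repeat([0, 1], table.sum(axis=1))
        cols = np.repeat([0, 1], table.sum(axis=0))
        stat_obs = scipy.stats.chi2_contingency(table, correction=False)[0]
        hits = 0
        reps = 5000
        for _ in range(reps):
            perm = rng.permutation(cols)
            sim = np.bincount(rows * 2 + perm, minlength=4).reshape(2, 2)
            if scipy.stats.chi2_contingency(sim, correction=False)[0] >= stat_obs - 1e-9:
                hits += 1
        mc_p = (hits + 1) / (reps + 1)
        se = math.sqrt(max(mc_p * (1 - mc_p), 1e-6) / reps)
        assert abs(res.p_value - mc_p) < 4 * se + 5e-3

    def test_degenerate_margin_error_names_margin(self):
        with pytest.raises(ValueError, match="row 1"):
            compare_groups([[3, 4], [0, 0]])
        with pytest.raises(ValueError, match="column 0"):
            compare_groups([[0, 4], [0, 3]])

    def test_yates_correction_flag(self):
        plain = compare_groups([[20, 30], [35, 15]])
        corrected = compare_groups([[20, 30], [35, 15]], yates=True)
        assert corrected.p_value > plain.p_value
        assert corrected.detail["yates_correction"]


class TestCompareAge:
    def test_identical_samples(self):
        res = compare_age([30, 40, 50], [30, 40, 50])
        assert res.p_value == 1.0

    def test_fully_separated_small_samples_exact(self):
        res = compare_age([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0
        assert res.detail["method"] == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6, 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_age([], [1.0])

    def test_null_rejection_rate_is_alpha(self):
        """Size of the two-sided test ≈ 5% under the null (simulation)."""
        rng = np.random.default_rng(202)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(40, 10, 12)
            b = rng.normal(40, 10, 12)
            rejections += compare_age(a, b).significant
        rate = rejections / reps
        # binomial 3-sigma band around 0.05 (exact test is mildly conservative)
        assert 0.05 - 3 * math.sqrt(0.05 * 0.95 / reps) - 0.01 < rate
        assert rate < 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)


class TestSummarize:
    def _pattern_cohort(self, seed=5, n=60):
        spec = GeneratorSpec(
            mode="pattern",
            n_patients=n,
            seed=seed,
            pattern_weights={
                "bilateral_excellent": 2,
                "very_good": 1,
                "good_mirror": 1,
                "fair": 1,
                "poor_tuberosity": 2,
                "poor_superior": 1,
                "mixed_poor": 1,
            },
        )
        return generate_cohort(spec)

    def test_patient_order_invariance(self):
        cohort = self._pattern_cohort()
        s1 = summarize_cohort(cohort)
        s2 = summarize_cohort(list(reversed(cohort)))
        for name, df in s1.tables().items():
            assert df.equals(s2.tables()[name]), name

    def test_percentages_recompute_from_counts(self, study_cohort):
        s = summarize_cohort(study_cohort)
        for df in (s.overall_quality, s.symmetry, s.alignment):
            for tech, sub in df.groupby("technique"):
                denom = sub["count"].sum()
                recomputed = 100 * sub["count"] / denom
                assert (abs(sub["percent"] - recomputed) <= 0.05).all()

    def test_counts_sum_to_group_size(self, study_cohort):
        s = summarize_cohort(study_cohort)
        for tech, n in s.group_sizes.items():
            sub = s.overall_quality[s.overall_quality.technique == tech]
            assert sub["count"].sum() + s.ungraded[tech] == n

    def test_prevalence_total_is_sum_of_groups(self, study_cohort):
        s = summarize_cohort(study_cohort)
        prev = s.prevalence
        for site in prev.site.unique():
            sub = prev[prev.site == site].set_index("technique")["count"]
            assert sub["total"] == sub["directed"] + sub["downfracture"]

    def test_strict_cleancut_equals_excellent_sides(self, study_cohort):
        s = summarize_cohort(study_cohort)
        cc = s.cleancut
        for tech in ("directed", "downfracture"):
            for side in ("right", "left"):
                strict = cc[
                    (cc.technique == tech)
                    & (cc.definition == "strict")
                    & (cc.side == side)
                ].iloc[0].numerator
                exc = s.side_quality[
                    (s.side_quality.technique == tech)
                    & (s.side_quality.side == side)
                    & (s.side_quality.category == "excellent")
                ].iloc[0]["count"]
                assert strict == exc

    def test_alignment_yes_is_group_minus_poor(self, study_cohort):
        s = summarize_cohort(study_cohort)
        for tech, n in s.group_sizes.items():
            poor = s.overall_quality[
                (s.overall_quality.technique == tech)
                & (s.overall_quality.category == "poor")
            ].iloc[0]["count"]
            yes = s.alignment[
                (s.alignment.technique == tech) & (s.alignment.category == "yes")
            ].iloc[0]["count"]
            assert yes == n - s.ungraded[tech] - poor

    def test_ungraded_patients_warned_and_tallied(self):
        from pmjq.model import CheckpointMap, PatientRecord

        blank = CheckpointMap()
        exc = CheckpointMap(medial_inferior=True, lateral_inferior=True)
        cohort = [
            PatientRecord("A", Technique.DIRECTED, right=exc, left=exc),
            PatientRecord("B", Technique.DIRECTED, right=blank, left=blank),
        ]
        with pytest.warns(UserWarning, match="no checkpoint involvement"):
            s = summarize_cohort(cohort)
        assert s.ungraded["directed"] == 1
        assert s.overall_quality["count"].sum() == 1
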