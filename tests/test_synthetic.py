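"""Generator and reconstructor: determinism, calibration, round-trips."""

import numpy as np
import pytest

from pmjq import reference
from pmjq.io import cohort_frame
from pmjq.model import SITE_KEYS, Technique, patient_flags
from pmjq.patient import OverallQuality, overall_quality
from pmjq.stats import summarize_cohort
from pmjq.synthetic import (
    ConstraintSet,
    GeneratorSpec,
    InfeasibleConstraints,
    PATTERN_CLASSES,
    constraints_from_cohort,
    generate_cohort,
    reconstruct_cohort,
)


def _marginal_spec(n=5000, seed=0, technique="downfracture"):
    return reference.marginal_generator_spec(technique, n, seed=seed)


class TestGenerator:
    def test_same_seed_same_cohort(self):
        a = generate_cohort(_marginal_spec(n=200, seed=42))
        b = generate_cohort(_marginal_spec(n=200, seed=42))
        assert cohort_frame(a).equals(cohort_frame(b))

    def test_different_seed_different_cohort(self):
        a = generate_cohort(_marginal_spec(n=200, seed=1))
        b = generate_cohort(_marginal_spec(n=200, seed=2))
        assert not cohort_frame(a).equals(cohort_frame(b))

    def test_marginal_prevalence_recovers_probability(self):
        """Right tuberosity at p=0.603: empirical prevalence within ±0.02."""
        spec = _marginal_spec(n=5000, seed=7)
        cohort = generate_cohort(spec)
        prev = np.mean([patient_flags(p)[0] for p in cohort])
        assert abs(prev - spec.marginal_probs["r_tub"]) < 0.02

    def test_marginal_all_sites_converge(self):
        """Law-of-large-numbers calibration of every site at n=10,000.

        All ten sites are checked simultaneously, so the band uses a
        familywise z (4 sigma per site keeps the joint false-alarm rate
        well below 1e-3; a per-site 3-sigma band would fire on ~5% of
        seeds by chance alone).
        """
        spec = _marginal_spec(n=10_000, seed=123)
        cohort = generate_cohort(spec)
        flags = np.array([patient_flags(p) for p in cohort], dtype=float)
        for i, site in enumerate(SITE_KEYS):
            p = spec.marginal_probs[site]
            se = max(np.sqrt(p * (1 - p) / len(cohort)), 1e-4)
            assert abs(flags[:, i].mean() - p) < 4 * se, site

    def test_pattern_degenerate_weights(self):
        spec = GeneratorSpec(
            mode="pattern",
            n_patients=10,
            seed=0,
            pattern_weights={"bilateral_excellent": 1.0},
        )
        cohort = generate_cohort(spec)
        assert len(cohort) == 10
        assert all(overall_quality(p) is OverallQuality.EXCELLENT for p in cohort)

    def test_pattern_classes_classify_as_named(self):
        """Each pattern class produces patients of its nominal grade."""
        grade = {
            "bilateral_excellent": OverallQuality.EXCELLENT,
            "very_good": OverallQuality.VERY_GOOD,
            "good_mirror": OverallQuality.GOOD,
            "fair": OverallQuality.FAIR,
            "poor_tuberosity": OverallQuality.POOR,
            "poor_superior": OverallQuality.POOR,
            "mixed_poor": OverallQuality.POOR,
        }
        for name in PATTERN_CLASSES:
            spec = GeneratorSpec(
                mode="pattern", n_patients=20, seed=3, pattern_weights={name: 1.0}
            )
            for p in generate_cohort(spec):
                assert overall_quality(p) is grade[name], name

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(mode="marginal", n_patients=5, marginal_probs={"r_tub": 0.5})
        with pytest.raises(ValueError):
            GeneratorSpec(mode="pattern", n_patients=5, pattern_weights={"nope": 1.0})
        with pytest.raises(ValueError):
            GeneratorSpec(
                mode="pattern", n_patients=5, pattern_weights={"fair": -1.0}
            )


class TestReconstructor:
    def test_reference_groups_reproduce_all_printed_counts(self, study_cohort):
        s = summarize_cohort(study_cohort)
        for tech in ("directed", "downfracture"):
            want_sq = reference.SIDE_QUALITY_COUNTS[tech]
            for side in ("right", "left"):
                sub = s.side_quality[
                    (s.side_quality.technique == tech) & (s.side_quality.side == side)
                ].set_index("category")["count"]
                assert dict(sub) == want_sq[side]
            sub = s.overall_quality[s.overall_quality.technique == tech]
            assert dict(sub.set_index("category")["count"]) == (
                reference.OVERALL_QUALITY_COUNTS[tech]
            )
            sub = s.symmetry[s.symmetry.technique == tech]
            assert dict(sub.set_index("category")["count"]) == (
                reference.SYMMETRY_COUNTS[tech]
            )
            prev = s.prevalence[s.prevalence.technique == tech]
            assert dict(prev.set_index("site")["count"]) == (
                reference.SITE_PREVALENCE_COUNTS[tech]
            )

    def test_reconstruction_is_bitwise_deterministic(self):
        a = cohort_frame(reference.reconstructed_study_cohort()).to_csv(index=False)
        b = cohort_frame(reference.reconstructed_study_cohort()).to_csv(index=False)
        assert a == b

    def test_single_excellent_patient(self):
        cs = ConstraintSet(n=1, overall_quality={"excellent": 1})
        (p,) = reconstruct_cohort(cs)
        assert patient_flags(p) == (
            False, False, True, False, True, False, False, True, False, True
        )

    def test_alignment_count_must_equal_poor(self):
        cs = ConstraintSet(
            n=2,
            overall_quality={"poor": 0, "good": 2},
            alignment={"no": 1, "yes": 1},
        )
        with pytest.raises(InfeasibleConstraints, match="alignment"):
            reconstruct_cohort(cs)

    def test_incompatible_side_and_overall_counts(self):
        cs = ConstraintSet(
            n=2,
            overall_quality={"excellent": 2},
            side_quality={
                "right": {"poor": 0, "good": 2, "excellent": 0},
                "left": {"poor": 0, "good": 0, "excellent": 2},
            },
        )
        with pytest.raises(InfeasibleConstraints):
            reconstruct_cohort(cs)

    def test_symmetry_identity_enforced(self):
        cs = ConstraintSet(
            n=3,
            overall_quality={"excellent": 2, "good": 1},
            symmetry={
                "no_symmetry_no_alignment": 0,
                "no_symmetry_with_alignment": 2,
                "perfect_symmetry": 1,
            },
        )
        with pytest.raises(InfeasibleConstraints, match="perfect"):
            reconstruct_cohort(cs)

    @pytest.mark.parametrize("seed", range(12))
    def test_round_trip_pattern_cohorts(self, seed):
        """generate → summarize → reconstruct reproduces the whole summary."""
        rng = np.random.default_rng(seed)
        weights = {k: float(rng.random()) for k in PATTERN_CLASSES}
        spec = GeneratorSpec(
            mode="pattern",
            n_patients=int(rng.integers(10, 60)),
            seed=seed + 1000,
            technique=Technique.DIRECTED,
            pattern_weights=weights,
        )
        original = generate_cohort(spec)
        cs = constraints_from_cohort(original)["directed"]
        rebuilt = reconstruct_cohort(cs, Technique.DIRECTED)
        s0 = summarize_cohort(original)
        s1 = summarize_cohort(rebuilt)
        for name in ("side_quality", "overall_quality", "symmetry", "alignment",
                     "prevalence", "cleancut"):
            df0 = s0.tables()[name].drop(columns="technique")
            df1 = s1.tables()[name].drop(columns="technique")
            assert df0.equals(df1), name
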