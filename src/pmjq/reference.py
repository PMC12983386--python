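"""Published summary counts of the reference audit cohort.

The framework was established on a single-center retrospective cohort of
205 consecutive Le Fort I osteotomies — 127 with directed pterygomaxillary
disjunction and 78 with direct downfracture — whose per-patient data are
not deposited; only the per-group summary tables are available.  This
module records those printed counts verbatim.  They serve two purposes:

* as **constraints** for :func:`pmjq.synthetic.reconstruct_cohort`, which
  rebuilds per-patient cohorts whose classified summaries match every
  printed count exactly (the cross-table identities of the framework make
  the headline numbers over-determined, so this is possible); and
* as **marginal probabilities** for the synthetic generator's marginal mode
  (each site's within-group prevalence).

Counts are integers per technique group; site keys follow
:data:`pmjq.model.SITE_KEYS` (``r_``/``l_`` prefix; ``tub``, ``med_sup``,
``med_inf``, ``lat_sup``, ``lat_inf``).
"""

from __future__ import annotations

from .model import SITE_KEYS, Technique
from .synthetic import ConstraintSet, GeneratorSpec

GROUP_SIZES = {"directed": 127, "downfracture": 78}

#: per-side ordinal quality counts (poor / good / excellent), by technique
SIDE_QUALITY_COUNTS = {
    "downfracture": {
        "right": {"poor": 71, "good": 2, "excellent": 5},
        "left": {"poor": 67, "good": 1, "excellent": 10},
    },
    "directed": {
        "right": {"poor": 28, "good": 24, "excellent": 75},
        "left": {"poor": 38, "good": 28, "excellent": 61},
    },
}

#: patient-level overall quality counts, by technique
OVERALL_QUALITY_COUNTS = {
    "downfracture": {"poor": 77, "fair": 0, "good": 0, "very_good": 0, "excellent": 1},
    "directed": {"poor": 49, "fair": 0, "good": 15, "very_good": 15, "excellent": 48},
}

#: symmetry category counts, by technique
SYMMETRY_COUNTS = {
    "downfracture": {
        "no_symmetry_no_alignment": 77,
        "no_symmetry_with_alignment": 0,
        "perfect_symmetry": 1,
    },
    "directed": {
        "no_symmetry_no_alignment": 49,
        "no_symmetry_with_alignment": 15,
        "perfect_symmetry": 63,
    },
}

#: binary alignment counts (no / yes), by technique
ALIGNMENT_COUNTS = {
    "downfracture": {"no": 77, "yes": 1},
    "directed": {"no": 49, "yes": 78},
}

#: clean-cut numerators; pooled denominators are 2×group size, by-side = group size
CLEANCUT_COUNTS = {
    "downfracture": {
        "inclusive_pooled": 58,
        "strict_pooled": 15,
        "strict_right": 5,
        "strict_left": 10,
    },
    "directed": {
        "inclusive_pooled": 176,
        "strict_pooled": 136,
        "strict_right": 75,
        "strict_left": 61,
    },
}

#: per-site fracture-involvement counts within each technique group
SITE_PREVALENCE_COUNTS = {
    "downfracture": {
        "r_tub": 47,
        "r_med_sup": 20,
        "r_med_inf": 34,
        "r_lat_sup": 23,
        "r_lat_inf": 35,
        "l_tub": 44,
        "l_med_sup": 23,
        "l_med_inf": 40,
        "l_lat_sup": 21,
        "l_lat_inf": 38,
    },
    "directed": {
        "r_tub": 3,
        "r_med_sup": 8,
        "r_med_inf": 121,
        "r_lat_sup": 21,
        "r_lat_inf": 99,
        "l_tub": 7,
        "l_med_sup": 14,
        "l_med_inf": 114,
        "l_lat_sup": 24,
        "l_lat_inf": 83,
    },
}


def marginal_probabilities(technique: str) -> dict[str, float]:
    """Within-group site prevalences as Bernoulli probabilities.

    E.g. right maxillary tuberosity under direct downfracture:
    47/78 ≈ 0.603.
    """
    n = GROUP_SIZES[technique]
    counts = SITE_PREVALENCE_COUNTS[technique]
    return {k: counts[k] / n for k in SITE_KEYS}


def total_site_counts() -> dict[str, int]:
    """Whole-cohort site counts: sum of the two technique groups per site."""
    return {
        k: sum(SITE_PREVALENCE_COUNTS[t][k] for t in GROUP_SIZES)
        for k in SITE_KEYS
    }


def constraints(technique: str, with_site_targets: bool = True) -> ConstraintSet:
    """The reference group's printed counts as a reconstruction constraint set."""
    if technique not in GROUP_SIZES:
        raise KeyError(f"unknown technique {technique!r}")
    return ConstraintSet(
        n=GROUP_SIZES[technique],
        side_quality=SIDE_QUALITY_COUNTS[technique],
        overall_quality=OVERALL_QUALITY_COUNTS[technique],
        symmetry=SYMMETRY_COUNTS[technique],
        alignment=ALIGNMENT_COUNTS[technique],
        cleancut=CLEANCUT_COUNTS[technique],
        site_targets=SITE_PREVALENCE_COUNTS[technique] if with_site_targets else None,
        mirror_good=True,
    )


def marginal_generator_spec(
    technique: str, n_patients: int, seed: int = 0
) -> GeneratorSpec:
    """Marginal-mode generator spec calibrated to a reference group's prevalences."""
    return GeneratorSpec(
        mode="marginal",
        n_patients=n_patients,
        technique=Technique(technique),
        seed=seed,
        marginal_probs=marginal_probabilities(technique),
    )


def reconstructed_study_cohort():
    """The full two-group reconstruction of the reference study (205 patients)."""
    from .synthetic import reconstruct_cohort

    cohort = []
    for tech in ("directed", "downfracture"):
        cohort.extend(reconstruct_cohort(constraints(tech), Technique(tech)))
    return cohort
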