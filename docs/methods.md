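# Methods

## The fracture-quality framework

During Le Fort I osteotomy the maxilla must be separated from the pterygoid
plates of the sphenoid at the pterygomaxillary junction (PMJ). Where that
fracture runs is a quality and safety question: desirable separations stay
*inferior* on both pterygoid plates; undesired trajectories propagate
*superiorly* along the plates or into the maxillary tuberosity. The
framework codes each side of the face against five binary checkpoints —
maxillary tuberosity, and the superior/inferior portions of the medial and
lateral pterygoid plates (the split is the axial plane through the
posterior nasal spine) — giving a ten-bit bilateral map per patient.

All downstream outcomes are pure functions of those ten bits:

* **Per-side quality** (ordinal): POOR if any superior portion or the
  tuberosity is involved; otherwise EXCELLENT if both plates are involved
  inferiorly, GOOD if exactly one is. A side with zero involvement is
  outside the scale and is classed UNGRADED (see below).
* **Overall quality** (ordinal, patient level): POOR if any superior or
  tuberosity extension exists on either side; otherwise the count k of
  involved inferior segments among the four (right/left × medial/lateral)
  maps k=1..4 to FAIR, GOOD, VERY_GOOD, EXCELLENT.
* **Alignment** (binary): yes iff no superior/tuberosity extension anywhere
  — i.e. overall quality is not POOR. This operationalisation is an
  inference, not a published formula: it is the unique binary rule
  consistent with the published cross-table identity that the alignment-No
  count equals the overall-POOR count in both technique groups.
* **Symmetry** (three categories): not aligned → "no symmetry and no
  alignment"; aligned and the two sides involve identical checkpoint sets
  → "perfect symmetry"; aligned otherwise → "no symmetry with alignment".
  The mirror-equality reading is the default (`symmetry_rule: mirror`)
  because it is the anatomically literal meaning of symmetry. The published
  counts are equally consistent with a grade-based rule (perfect ⟺ at
  least three inferior segments), which is available as
  `symmetry_rule: grade_based` for sensitivity analysis.
* **Clean-cut surrogates** (per side): *inclusive* = both plates involved
  inferiorly regardless of concurrent superior/tuberosity extension;
  *strict* = inclusive plus absence of any superior or tuberosity
  involvement on that side. By construction a strict clean-cut side is
  exactly an EXCELLENT side; rates are reported pooled by sides
  (denominator 2n) and per side (denominator n).

### UNGRADED handling

The three-category side scale and five-category patient scale assign no
category to zero involvement. Rather than silently coercing such inputs
into a clinical category, the package marks them UNGRADED, excludes them
from ordinal tabulations with a warning and a separate tally, and raises
on alignment/symmetry classification (undefined for them). Flags are
strictly 0/1 in files; anything else is a validation error naming the row
and column — the ten-bit map is the entire data substrate, so imputation
would corrupt every downstream count.

## Statistics

Between-group categorical comparisons follow the standard audit policy:
Pearson chi-square (no continuity correction for tables larger than 2×2;
Yates correction off by default for 2×2, available as a flag) when every
expected cell count is at least `expected_min` (default 5 — "any expected
cell below 5" being the usual reading of a small-expected-counts switch);
otherwise an exact conditional test. The 2×2 exact test is the
hypergeometric (Fisher) test via scipy. For r×c tables the package
implements the generalisation directly: the two-sided p is the total
conditional probability of every margin-preserving table no more probable
than the observed one, computed by exact recursive enumeration, or by a
seeded Monte-Carlo estimate (add-one estimator, default 10^5 replicates,
seed recorded in the result) when more than `max_enumeration` (default
10^7) tables share the margins. A note on oracles: scipy ≥ 1.15 also
offers r×c `fisher_exact`, but it is itself a randomized approximation;
the test suite therefore validates the enumeration against an
exact-rational brute force and uses scipy only as a consistency check.

Categories empty in both groups are dropped before testing (a zero margin
is degenerate and is reported as an error naming the margin). Age uses the
two-sided Mann-Whitney U test: exact null distribution when both samples
are ≤ 20 and untied, otherwise the mid-rank normal approximation with tie
correction and no continuity correction (so identical samples give p = 1).
All tests are two-sided at α = 0.05.

## Synthetic cohorts

### Marginal mode

Each of the ten checkpoints is drawn independently as Bernoulli(p_site),
with per-technique site probabilities defaulting to the reference cohort's
within-group prevalences (e.g. right tuberosity 47/78 ≈ 0.603 under direct
downfracture). This mode deliberately ignores within-side and between-side
correlation: real fracture patterns are strongly structured (a strict
clean-cut side is a *joint* event), so marginal draws exercise the
statistical machinery and calibration, not the joint distribution. Passing
marginal-mode tests therefore says nothing about joint-count realism;
pattern mode and reconstruction exist for that.

### Pattern mode

Each patient is drawn from weighted bilateral pattern classes —
`bilateral_excellent` (all four inferior segments), `very_good` (three),
`good_mirror` (one mirror-paired segment per side), `fair` (one segment),
`poor_tuberosity` (tuberosity extension over an otherwise inclusive cut),
`poor_superior` (isolated superior propagation, single inferior segment
contralaterally), `mixed_poor` (bilateral inclusive cuts with a superior
extension on one side). Residual choices (which side, which segment, which
superior flag) are drawn from the seeded stream; output is reproducible
given the seed.

### Constraint-based reconstruction

`reconstruct_cohort` rebuilds a per-patient cohort whose classified
summary matches a supplied set of printed counts exactly. The category
counts over-determine most of the allocation through the framework's
identities (strict clean-cut ⟺ per-side EXCELLENT; alignment-No ⟺ overall
POOR; the symmetry partition), so the algorithm solves the integer
consistency system directly rather than searching: the one coupling
unknown is how many VERY_GOOD patients carry their double-inferior side on
the right, whose feasible interval follows from the side-quality counts
(infeasibility raises an error naming the violated identity). Patient-level
GOOD patients are built as mirror pairs by default — required for the
mirror symmetry rule to reproduce the published perfect-symmetry counts —
with `mirror_good=False` available for sensitivity analysis.

The residual freedom — which inferior segment each single-segment side
uses, which undesired flag each POOR side carries, and how
inclusive-but-not-strict sides split between right and left — does not
affect any category count. It is resolved against optional per-site
prevalence targets (soft constraints) by a small exact search over the
mirror-segment split and the inclusive split, minimising total absolute
deviation; with no targets, fixed documented priorities apply (medial
before lateral, right before left, tuberosity as the default undesired
flag). On the reference cohort this search attains zero deviation: all ten
site prevalences in both groups are reproduced exactly alongside every
category count. The function uses no randomness; repeated runs are
bitwise identical. The search is O(G × extras) and intended for
desk-scale cohorts (hundreds of patients).

## Numerical and formatting choices

* Percentages print to one decimal using round-half-up (clinical-table
  convention; Python's built-in rounding is half-even), always accompanied
  by numerator and denominator.
* Exact-test tie handling: tables with conditional probability equal to
  the observed one (within a 1e-9 log tolerance) are included in the tail,
  the standard two-sided convention.
* Monte-Carlo p-values use the add-one estimator, so a reported exact-path
  p is never zero.
* Reconstruction patient ids are deterministic (`DIR-001`, `DOW-001`, …);
  generator ids are `S00001`, ….

## Problem sizes used in the shipped checks

Classifier checks enumerate all 32 per-side and 1024 bilateral flag
combinations. Reconstruction checks run at the reference group sizes
(127 + 78). Generator calibration uses n = 10,000 patients (binomial SE
≈ 0.5 percentage points at p ≈ 0.5); round-trip checks run 100 random
pattern cohorts of 5–50 patients. These sizes make the full suite run in
well under a minute on one CPU.

## Known limitations

* The reconstructed cohort is *a* cohort consistent with every printed
  count, not the study's actual patient-level data; quantities the printed
  tables do not constrain (e.g. the joint distribution of undesired flags
  within POOR sides) are fixed by the documented priorities.
* The alignment rule and the perfect-symmetry rule are inferred from count
  identities, not from a published operational definition; both are
  flagged as inferences and the symmetry rule is switchable.
* Marginal-mode cohorts are not realistic joint patterns (see above).
* The exact r×c enumeration is practical for the small tables that arise
  here (≤ 5×2); very large sparse tables fall back to Monte Carlo.
* Demographics are carried but minimally modelled: age is an optional
  truncated-normal draw, sex is pass-through.
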