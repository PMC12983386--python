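"""Patient-level ordinal quality index and bilateral symmetry/alignment.

The overall quality status integrates both sides: provided no superior or
tuberosity extension is present anywhere, it tallies how many of the four
inferior plate portions (right/left × medial/lateral) are involved.  Any
superior or tuberosity extension on either side makes the patient POOR
outright; otherwise 1–4 involved inferior portions map to FAIR, GOOD,
VERY_GOOD and EXCELLENT.  Zero involvement anywhere is outside the scale
(UNGRADED).

Alignment is the binary directional-concordance outcome: a patient is
"aligned" when the fracture stayed inferiorly contained on both sides, i.e.
no superior or tuberosity extension anywhere (equivalently, overall quality
is not POOR).  Symmetry refines alignment into three categories: perfect
symmetry (aligned and the two checkpoint sets are mirror images), no
symmetry with alignment, and no symmetry and no alignment.  An alternative
grade-based symmetry rule (perfect ⟺ overall VERY_GOOD or EXCELLENT) is
available as a configuration switch; see docs/methods.md for why the mirror
rule is the default.
"""

from __future__ import annotations

import enum

from .model import PatientRecord, mirror_equal


class UngradedError(ValueError):
    """Raised when an ordinal-only operation receives an ungraded patient."""


class OverallQuality(enum.Enum):
    """Patient-level ordinal quality: POOR < FAIR < GOOD < VERY_GOOD < EXCELLENT."""

    POOR = 0
    FAIR = 1
    GOOD = 2
    VERY_GOOD = 3
    EXCELLENT = 4
    UNGRADED = -1

    def _check_comparable(self, other: "OverallQuality") -> None:
        if OverallQuality.UNGRADED in (self, other):
            raise TypeError("UNGRADED is outside the ordinal scale")

    def __lt__(self, other: "OverallQuality") -> bool:
        self._check_comparable(other)
        return self.value < other.value

    def __le__(self, other: "OverallQuality") -> bool:
        self._check_comparable(other)
        return self.value <= other.value

    def __gt__(self, other: "OverallQuality") -> bool:
        return other < self

    def __ge__(self, other: "OverallQuality") -> bool:
        return other <= self


class SymmetryCategory(str, enum.Enum):
    PERFECT_SYMMETRY = "perfect_symmetry"
    ALIGNED_NOT_SYMMETRIC = "no_symmetry_with_alignment"
    NO_SYMMETRY_NO_ALIGNMENT = "no_symmetry_no_alignment"


#: accepted values for the symmetry-rule configuration switch
SYMMETRY_RULES = ("mirror", "grade_based")

_INFERIOR_BY_QUALITY = {
    1: OverallQuality.FAIR,
    2: OverallQuality.GOOD,
    3: OverallQuality.VERY_GOOD,
    4: OverallQuality.EXCELLENT,
}


def overall_quality(patient: PatientRecord) -> OverallQuality:
    """Patient-level five-category ordinal quality status.

    POOR if any superior or tuberosity extension exists on either side;
    otherwise the count of involved inferior portions across the four
    inferior segments decides the grade (1→FAIR … 4→EXCELLENT); zero
    involvement → UNGRADED.
    """
    if patient.right.superior_or_tuberosity or patient.left.superior_or_tuberosity:
        return OverallQuality.POOR
    k = patient.right.inferior_count + patient.left.inferior_count
    return _INFERIOR_BY_QUALITY.get(k, OverallQuality.UNGRADED)


def classify_alignment(patient: PatientRecord) -> bool:
    """Binary bilateral alignment.

    True iff the fracture is inferiorly contained on both sides — no
    superior or tuberosity extension anywhere — i.e. overall quality is not
    POOR.  Raises :class:`UngradedError` for patients with zero involvement.
    """
    q = overall_quality(patient)
    if q is OverallQuality.UNGRADED:
        raise UngradedError(
            f"patient {patient.patient_id!r} has no checkpoint involvement; "
            "alignment is undefined"
        )
    return q is not OverallQuality.POOR


def classify_symmetry(
    patient: PatientRecord, rule: str = "mirror"
) -> SymmetryCategory:
    """Three-category bilateral symmetry outcome.

    Under the default ``mirror`` rule: not aligned → NO_SYMMETRY_NO_ALIGNMENT;
    aligned and the two sides involve identical checkpoint sets →
    PERFECT_SYMMETRY; aligned otherwise → ALIGNED_NOT_SYMMETRIC.

    Under the ``grade_based`` rule, perfect symmetry is instead granted to
    aligned patients whose overall grade is VERY_GOOD or EXCELLENT (at least
    three of four inferior segments involved).
    """
    if rule not in SYMMETRY_RULES:
        raise ValueError(f"unknown symmetry rule {rule!r}; expected {SYMMETRY_RULES}")
    if not classify_alignment(patient):
        return SymmetryCategory.NO_SYMMETRY_NO_ALIGNMENT
    if rule == "mirror":
        perfect = mirror_equal(patient.right, patient.left)
    else:
        perfect = overall_quality(patient) in (
            OverallQuality.VERY_GOOD,
            OverallQuality.EXCELLENT,
        )
    return (
        SymmetryCategory.PERFECT_SYMMETRY
        if perfect
        else SymmetryCategory.ALIGNED_NOT_SYMMETRIC
    )
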