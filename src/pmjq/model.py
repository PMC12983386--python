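"""Checkpoint data model and per-side fracture-quality classifier.

The pterygomaxillary junction (PMJ) fracture produced during Le Fort I
osteotomy is scored on each side of the face against five binary anatomical
checkpoints: the maxillary tuberosity and the superior and inferior portions
of the medial and lateral pterygoid plates (the inferior/superior split is
the axial plane through the posterior nasal spine; structures caudal to it
are "inferior").  A patient therefore carries a ten-point bilateral map.

Side-level quality is an ordinal three-category grade anchored in clinically
desirable containment of the fracture line:

* ``POOR`` — any superior plate portion or the tuberosity is involved,
  regardless of concurrent inferior involvement (an undesired trajectory);
* ``GOOD`` — exactly one plate is involved, confined to its inferior portion;
* ``EXCELLENT`` — both plates involved but confined to their inferior
  portions.

A side with no involvement at all falls outside this scale and is graded
``UNGRADED``; it is never coerced into one of the three clinical categories
and is excluded (with a warning) from ordinal tabulations downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import Iterable, Optional


class ValidationError(ValueError):
    """Raised when a checkpoint map or patient record is malformed."""


class Technique(str, enum.Enum):
    """Surgical technique used to separate the pterygomaxillary junction.

    ``DIRECTED`` is the osteotome-assisted intermediate release (directed
    disjunction); ``DOWNFRACTURE`` is direct downfracture without a dedicated
    pterygoid osteotome step.
    """

    DIRECTED = "directed"
    DOWNFRACTURE = "downfracture"


class SideQuality(enum.Enum):
    """Ordinal per-side fracture quality: POOR < GOOD < EXCELLENT.

    ``UNGRADED`` marks a side with zero checkpoint involvement; it does not
    participate in the total order and comparisons against it raise.
    """

    POOR = 0
    GOOD = 1
    EXCELLENT = 2
    UNGRADED = -1

    def _check_comparable(self, other: "SideQuality") -> None:
        if SideQuality.UNGRADED in (self, other):
            raise TypeError("UNGRADED is outside the ordinal scale")

    def __lt__(self, other: "SideQuality") -> bool:
        self._check_comparable(other)
        return self.value < other.value

    def __le__(self, other: "SideQuality") -> bool:
        self._check_comparable(other)
        return self.value <= other.value

    def __gt__(self, other: "SideQuality") -> bool:
        return other < self

    def __ge__(self, other: "SideQuality") -> bool:
        return other <= self


#: canonical checkpoint order used throughout file formats and tabulations
CHECKPOINT_FIELDS = (
    "tuberosity",
    "medial_superior",
    "medial_inferior",
    "lateral_superior",
    "lateral_inferior",
)


@dataclass(frozen=True)
class CheckpointMap:
    """Five binary fracture-involvement flags for one side.

    Semantics are side-local: the same class describes a right or a left
    side, and a map never mixes sides.  Flags must be strict booleans —
    blanks, NA or numeric codes other than 0/1 are validation errors at the
    I/O layer, never silently imputed, because the ten-bit map is the entire
    data substrate of the framework.
    """

    tuberosity: bool = False
    medial_superior: bool = False
    medial_inferior: bool = False
    lateral_superior: bool = False
    lateral_inferior: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, bool):
                raise ValidationError(
                    f"checkpoint flag {f.name!r} must be a bool, got {v!r}"
                )

    @classmethod
    def from_flags(cls, flags: Iterable[int]) -> "CheckpointMap":
        """Build a map from five 0/1 values in canonical checkpoint order."""
        vals = list(flags)
        if len(vals) != len(CHECKPOINT_FIELDS):
            raise ValidationError(
                f"expected {len(CHECKPOINT_FIELDS)} flags, got {len(vals)}"
            )
        kw = {}
        for name, v in zip(CHECKPOINT_FIELDS, vals):
            if v not in (0, 1, False, True):
                raise ValidationError(f"flag {name!r} must be 0 or 1, got {v!r}")
            kw[name] = bool(v)
        return cls(**kw)

    def flags(self) -> tuple[bool, ...]:
        """The five flags in canonical checkpoint order."""
        return tuple(getattr(self, name) for name in CHECKPOINT_FIELDS)

    @property
    def any_involvement(self) -> bool:
        return any(self.flags())

    @property
    def superior_or_tuberosity(self) -> bool:
        """True if the fracture escaped inferior containment on this side."""
        return self.tuberosity or self.medial_superior or self.lateral_superior

    @property
    def inferior_count(self) -> int:
        """Number of inferior plate portions involved (0–2)."""
        return int(self.medial_inferior) + int(self.lateral_inferior)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: technique label plus right and left checkpoint maps.

    ``right``/``left`` are in patient (anatomical) orientation; side is a
    recorded attribute of the data, never inferred from image geometry.
    """

    patient_id: str
    technique: Technique
    right: CheckpointMap
    left: CheckpointMap
    age: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.patient_id, str) or not self.patient_id:
            raise ValidationError("patient_id must be a non-empty string")
        if not isinstance(self.technique, Technique):
            raise ValidationError(f"unknown technique {self.technique!r}")
        for side in ("right", "left"):
            if not isinstance(getattr(self, side), CheckpointMap):
                raise ValidationError(f"{side} must be a CheckpointMap")
        if self.age is not None and self.age < 0:
            raise ValidationError("age must be non-negative")


#: short column codes for the five checkpoints, in canonical order
CHECKPOINT_SHORT = ("tub", "med_sup", "med_inf", "lat_sup", "lat_inf")

#: the ten bilateral site keys in canonical order (right block then left)
SITE_KEYS = tuple(
    f"{prefix}_{short}" for prefix in ("r", "l") for short in CHECKPOINT_SHORT
)


def patient_flags(patient: "PatientRecord") -> tuple[bool, ...]:
    """The ten bilateral flags in :data:`SITE_KEYS` order."""
    return patient.right.flags() + patient.left.flags()


def maps_from_flags(flags: Iterable[int]) -> tuple[CheckpointMap, CheckpointMap]:
    """Build (right, left) maps from ten 0/1 values in :data:`SITE_KEYS` order."""
    vals = list(flags)
    if len(vals) != 10:
        raise ValidationError(f"expected 10 flags, got {len(vals)}")
    return CheckpointMap.from_flags(vals[:5]), CheckpointMap.from_flags(vals[5:])


def classify_side(cmap: CheckpointMap) -> SideQuality:
    """Grade one side's fracture quality.

    Pure function over the five flags:

    * any superior portion or the tuberosity involved → ``POOR``
      (regardless of inferior involvement);
    * otherwise both inferior portions involved → ``EXCELLENT``;
    * otherwise exactly one inferior portion involved → ``GOOD``;
    * no involvement at all → ``UNGRADED``.
    """
    if cmap.superior_or_tuberosity:
        return SideQuality.POOR
    k = cmap.inferior_count
    if k == 2:
        return SideQuality.EXCELLENT
    if k == 1:
        return SideQuality.GOOD
    return SideQuality.UNGRADED


def mirror_equal(right: CheckpointMap, left: CheckpointMap) -> bool:
    """True iff the two sides involve exactly the same checkpoints.

    Mirror-image equality of the checkpoint sets; symmetric and reflexive.
    """
    return right.flags() == left.flags()
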