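"""Cohort CSV schema, validation, scoring and analysis configuration.

The cohort file is a flat CSV, one row per patient:

``patient_id, technique, r_tub, r_med_sup, r_med_inf, r_lat_sup, r_lat_inf,
l_tub, l_med_sup, l_med_inf, l_lat_sup, l_lat_inf[, age][, sex]``

Flags are strictly 0/1; ``technique`` is ``directed`` or ``downfracture``.
Column order is irrelevant but the header is otherwise exact: unknown
columns, missing columns, duplicate patient ids and non-binary flags are
hard errors that name the offending row/column — the ten-bit map is the
entire data substrate, so nothing is ever imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
import yaml

from .model import (
    PatientRecord,
    SITE_KEYS,
    Technique,
    ValidationError,
    maps_from_flags,
    patient_flags,
)

REQUIRED_COLUMNS = ("patient_id", "technique", *SITE_KEYS)
OPTIONAL_COLUMNS = ("age", "sex")


@dataclass
class AnalysisConfig:
    """Tunable analysis knobs with their audit-standard defaults."""

    symmetry_rule: str = "mirror"       # or "grade_based"
    expected_min: float = 5.0           # exact-test switch: any expected cell below
    yates: bool = False                 # 2x2 continuity correction
    alpha: float = 0.05
    mc_replicates: int = 100_000        # Monte-Carlo exact-test fallback
    mc_seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def read_cohort(path: Union[str, Path]) -> list[PatientRecord]:
    """Read and validate a cohort CSV into patient records."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = set(df.columns)
    missing = set(REQUIRED_COLUMNS) - cols
    if missing:
        raise ValidationError(f"missing column(s) {sorted(missing)} in {path}")
    unknown = cols - set(REQUIRED_COLUMNS) - set(OPTIONAL_COLUMNS)
    if unknown:
        raise ValidationError(f"unknown column(s) {sorted(unknown)} in {path}")
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        csv_row = int(idx) + 2  # header is row 1
        pid = row["patient_id"].strip()
        if not pid:
            raise ValidationError(f"row {csv_row}: empty patient_id")
        if pid in seen:
            raise ValidationError(f"row {csv_row}: duplicate patient_id {pid!r}")
        seen.add(pid)
        try:
            technique = Technique(row["technique"].strip())
        except ValueError:
            raise ValidationError(
                f"row {csv_row}: unknown technique {row['technique']!r} "
                f"(expected one of {[t.value for t in Technique]})"
            ) from None
        flags = []
        for col in SITE_KEYS:
            v = row[col].strip()
            if v not in ("0", "1"):
                raise ValidationError(
                    f"row {csv_row}, column {col!r}: flag must be 0 or 1, got {v!r}"
                )
            flags.append(int(v))
        right, left = maps_from_flags(flags)
        age = None
        if "age" in cols and row["age"].strip():
            try:
                age = float(row["age"])
            except ValueError:
                raise ValidationError(
                    f"row {csv_row}, column 'age': not a number: {row['age']!r}"
                ) from None
        sex = row["sex"].strip() or None if "sex" in cols else None
        try:
            records.append(
                PatientRecord(pid, technique, right=right, left=left, age=age, sex=sex)
            )
        except ValidationError as exc:
            raise ValidationError(f"row {csv_row}: {exc}") from None
    return records


def cohort_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical CSV column layout."""
    rows = []
    for p in cohort:
        row = {"patient_id": p.patient_id, "technique": p.technique.value}
        row.update({k: int(v) for k, v in zip(SITE_KEYS, patient_flags(p))})
        row["age"] = "" if p.age is None else p.age
        row["sex"] = "" if p.sex is None else p.sex
        rows.append(row)
    return pd.DataFrame(rows, columns=[*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS])


def write_cohort(cohort: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    """Write a cohort CSV (round-trips exactly through :func:`read_cohort`)."""
    cohort_frame(cohort).to_csv(path, index=False)


def score_cohort(
    cohort: Sequence[PatientRecord], symmetry_rule: str = "mirror"
) -> pd.DataFrame:
    """Per-patient classification table: one row per patient, all outcomes.

    UNGRADED patients get ``ungraded`` quality values and empty
    alignment/symmetry cells rather than being dropped.
    """
    from .cleancut import clean_cut
    from .patient import OverallQuality, classify_alignment, classify_symmetry, overall_quality
    from .model import classify_side

    rows = []
    for p in cohort:
        q = overall_quality(p)
        graded = q is not OverallQuality.UNGRADED
        cc_r, cc_l = clean_cut(p.right), clean_cut(p.left)
        rows.append(
            {
                "patient_id": p.patient_id,
                "technique": p.technique.value,
                "right_quality": classify_side(p.right).name.lower(),
                "left_quality": classify_side(p.left).name.lower(),
                "overall_quality": q.name.lower(),
                "alignment": (
                    ("yes" if classify_alignment(p) else "no") if graded else ""
                ),
                "symmetry": (
                    classify_symmetry(p, rule=symmetry_rule).value if graded else ""
                ),
                "right_inclusive_cleancut": int(cc_r.inclusive),
                "right_strict_cleancut": int(cc_r.strict),
                "left_inclusive_cleancut": int(cc_l.inclusive),
                "left_strict_cleancut": int(cc_l.strict),
            }
        )
    return pd.DataFrame(rows)
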