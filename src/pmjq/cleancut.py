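"""Inclusive and strict clean-cut surrogates, per side and pooled.

"Clean-cut" is the nomenclature used in the osteotomy literature for a
desirable pterygomaxillary separation.  Two pragmatic per-side surrogates
are operationalized on the checkpoint map:

* **inclusive** clean-cut — inferior involvement of both plates on a given
  side, regardless of concurrent superior or tuberosity extension;
* **strict** clean-cut — additionally requires the absence of any superior
  propagation and of tuberosity involvement on that side.

By construction strict ⟹ inclusive, and a strict clean-cut side is exactly
a side graded EXCELLENT.  Rates are reported both pooled by sides
(denominator = 2 × group size) and stratified by right and left
(denominator = group size) to avoid denominator ambiguity.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import pandas as pd

from .model import CheckpointMap, PatientRecord, Technique
from .util import percent


class CleanCutFlags(NamedTuple):
    """Per-side clean-cut status; ``strict`` implies ``inclusive``."""

    inclusive: bool
    strict: bool


def clean_cut(cmap: CheckpointMap) -> CleanCutFlags:
    """Evaluate both clean-cut surrogates on one side."""
    inclusive = cmap.medial_inferior and cmap.lateral_inferior
    strict = inclusive and not cmap.superior_or_tuberosity
    return CleanCutFlags(inclusive=inclusive, strict=strict)


def clean_cut_rates(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    """Clean-cut rate table per technique × definition × granularity.

    Returns a DataFrame with columns ``technique, definition, granularity,
    side, numerator, denominator, percent``; pooled rows use both sides of
    every patient in the technique group, by-side rows one side each.
    Percentages are to one decimal (round-half-up); numerator and
    denominator are always carried so rounding never hides information.
    """
    patients = list(cohort)
    if not patients:
        raise ValueError("empty cohort")
    rows = []
    present = [t for t in Technique if any(p.technique is t for p in patients)]
    for tech in present:
        group = [p for p in patients if p.technique is tech]
        flags = {
            "right": [clean_cut(p.right) for p in group],
            "left": [clean_cut(p.left) for p in group],
        }
        n = len(group)
        for definition in ("inclusive", "strict"):
            pooled_num = sum(
                getattr(f, definition) for side in ("right", "left") for f in flags[side]
            )
            rows.append(
                {
                    "technique": tech.value,
                    "definition": definition,
                    "granularity": "pooled_by_sides",
                    "side": "",
                    "numerator": pooled_num,
                    "denominator": 2 * n,
                    "percent": percent(pooled_num, 2 * n),
                }
            )
            for side in ("right", "left"):
                num = sum(getattr(f, definition) for f in flags[side])
                rows.append(
                    {
                        "technique": tech.value,
                        "definition": definition,
                        "granularity": "by_side",
                        "side": side,
                        "numerator": num,
                        "denominator": n,
                        "percent": percent(num, n),
                    }
                )
    return pd.DataFrame(rows)
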