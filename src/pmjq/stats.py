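"""Cohort tabulation and group-comparison statistics.

:func:`summarize_cohort` applies every classifier to a cohort and produces
the standard audit tables: per-side quality, patient-level overall quality,
symmetry, alignment, per-site fracture prevalence and clean-cut rates, each
as counts with within-group percentages.

:func:`compare_groups` implements the categorical test policy used in
surgical audit work: Pearson chi-square when all expected cell counts are
adequate, otherwise an exact conditional test — the hypergeometric test for
2×2 tables and its r×c generalisation (exact enumeration of all tables with
the observed margins, or a seeded Monte-Carlo approximation when the state
space is too large to enumerate).  :func:`compare_age` is the two-sided
Mann-Whitney U test (exact for small untied samples, mid-rank/normal
approximation with tie correction otherwise).  All tests are two-sided with
significance at p < alpha (default 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cleancut import clean_cut_rates
from .model import PatientRecord, SITE_KEYS, Technique, classify_side, patient_flags
from .patient import (
    OverallQuality,
    SymmetryCategory,
    classify_alignment,
    classify_symmetry,
    overall_quality,
)
from .util import percent

SIDE_CATEGORIES = ("poor", "good", "excellent")
OVERALL_CATEGORIES = ("poor", "fair", "good", "very_good", "excellent")
SYMMETRY_CATEGORIES = (
    "no_symmetry_no_alignment",
    "no_symmetry_with_alignment",
    "perfect_symmetry",
)

_SYM_KEY = {
    SymmetryCategory.NO_SYMMETRY_NO_ALIGNMENT: "no_symmetry_no_alignment",
    SymmetryCategory.ALIGNED_NOT_SYMMETRIC: "no_symmetry_with_alignment",
    SymmetryCategory.PERFECT_SYMMETRY: "perfect_symmetry",
}


@dataclass
class CohortSummary:
    """All audit tables for one cohort, one DataFrame per table family.

    Percentages are within-technique-group (denominator: graded patients
    for patient-level tables, graded sides for side-level tables) to one
    decimal; counts always accompany them.  ``ungraded`` reports patients
    with zero checkpoint involvement, which are excluded from the ordinal
    tables.
    """

    group_sizes: dict[str, int]
    side_quality: pd.DataFrame
    overall_quality: pd.DataFrame
    symmetry: pd.DataFrame
    alignment: pd.DataFrame
    prevalence: pd.DataFrame
    cleancut: pd.DataFrame
    ungraded: dict[str, int] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "side_quality": self.side_quality,
            "overall_quality": self.overall_quality,
            "symmetry": self.symmetry,
            "alignment": self.alignment,
            "prevalence": self.prevalence,
            "cleancut": self.cleancut,
        }

    def to_dict(self) -> dict:
        out: dict = {"group_sizes": self.group_sizes, "ungraded": self.ungraded}
        for name, df in self.tables().items():
            out[name] = df.to_dict(orient="records")
        return out


@dataclass
class ComparisonResult:
    """Outcome of one two-group hypothesis test.

    ``statistic`` is None for exact tests conventionally reported by their
    p-value alone.  ``table`` keeps the contingency counts actually tested
    (after dropping empty categories); ``detail`` records dof, the
    expected-count threshold and Monte-Carlo settings where relevant.
    """

    test_name: str
    p_value: float
    statistic: Optional[float] = None
    table: Optional[list[list[int]]] = None
    alpha: float = 0.05
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "table": self.table,
            "alpha": self.alpha,
            "significant": self.significant,
            **({"detail": self.detail} if self.detail else {}),
        }


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------


def _count_rows(counts: dict[str, int], denom: int, tech: str, extra: dict) -> list[dict]:
    rows = []
    for cat, cnt in counts.items():
        rows.append(
            {
                "technique": tech,
                **extra,
                "category": cat,
                "count": cnt,
                "percent": percent(cnt, denom) if denom else float("nan"),
            }
        )
    return rows


def summarize_cohort(
    cohort: Iterable[PatientRecord], symmetry_rule: str = "mirror"
) -> CohortSummary:
    """Classify every patient and tabulate all audit tables.

    Deterministic and invariant under patient order.  Patients with zero
    checkpoint involvement anywhere are UNGRADED: they are counted
    separately, excluded from the ordinal tables, and flagged by a warning.
    """
    patients = list(cohort)
    if not patients:
        raise ValueError("empty cohort")
    techs = [t.value for t in Technique if any(p.technique is t for p in patients)]
    group_sizes, ungraded = {}, {}
    sq_rows, ov_rows, sym_rows, al_rows, prev_rows = [], [], [], [], []
    total_sites = dict.fromkeys(SITE_KEYS, 0)
    total_n = 0
    for tech in techs:
        group = [p for p in patients if p.technique.value == tech]
        group_sizes[tech] = len(group)
        graded = [p for p in group if overall_quality(p) is not OverallQuality.UNGRADED]
        ungraded[tech] = len(group) - len(graded)
        if ungraded[tech]:
            warnings.warn(
                f"{ungraded[tech]} patient(s) in group {tech!r} have no checkpoint "
                "involvement; excluded from ordinal tabulations",
                stacklevel=2,
            )
        for side in ("right", "left"):
            maps = [getattr(p, side) for p in group]
            quals = [classify_side(m) for m in maps]
            counts = {c: sum(q.name.lower() == c for q in quals) for c in SIDE_CATEGORIES}
            denom = sum(counts.values())
            sq_rows += _count_rows(counts, denom, tech, {"side": side})
        ov = [overall_quality(p) for p in graded]
        counts = {c: sum(q.name.lower() == c for q in ov) for c in OVERALL_CATEGORIES}
        ov_rows += _count_rows(counts, len(graded), tech, {})
        sym = [classify_symmetry(p, rule=symmetry_rule) for p in graded]
        counts = {c: sum(_SYM_KEY[s] == c for s in sym) for c in SYMMETRY_CATEGORIES}
        sym_rows += _count_rows(counts, len(graded), tech, {})
        al = [classify_alignment(p) for p in graded]
        counts = {"no": sum(not x for x in al), "yes": sum(al)}
        al_rows += _count_rows(counts, len(graded), tech, {})
        site_counts = dict.fromkeys(SITE_KEYS, 0)
        for p in group:
            for k, v in zip(SITE_KEYS, patient_flags(p)):
                site_counts[k] += int(v)
        for k in SITE_KEYS:
            prev_rows.append(
                {
                    "technique": tech,
                    "site": k,
                    "count": site_counts[k],
                    "percent": percent(site_counts[k], len(group)),
                }
            )
            total_sites[k] += site_counts[k]
        total_n += len(group)
    for k in SITE_KEYS:
        prev_rows.append(
            {
                "technique": "total",
                "site": k,
                "count": total_sites[k],
                "percent": percent(total_sites[k], total_n),
            }
        )
    return CohortSummary(
        group_sizes=group_sizes,
        side_quality=pd.DataFrame(sq_rows),
        overall_quality=pd.DataFrame(ov_rows),
        symmetry=pd.DataFrame(sym_rows),
        alignment=pd.DataFrame(al_rows),
        prevalence=pd.DataFrame(prev_rows),
        cleancut=clean_cut_rates(patients),
        ungraded=ungraded,
    )


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray, lg_fact: np.ndarray, const: float) -> float:
    # conditional (multiple hypergeometric) probability of a table given margins
    return const - lg_fact[table].sum()


def _exact_rxc_enumerate(
    table: np.ndarray, max_tables: int
) -> Optional[float]:
    """Two-sided exact p over all tables with the observed margins.

    Generalises the 2×2 hypergeometric test: p = sum of the conditional
    probabilities of every margin-preserving table no more probable than
    the observed one.  Returns None if more than ``max_tables`` tables
    would need visiting.
    """
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    lg_fact = np.zeros(n + 1)
    lg_fact[1:] = np.cumsum(np.log(np.arange(1, n + 1)))
    const = lg_fact[rows].sum() + lg_fact[cols].sum() - lg_fact[n]
    logp_obs = _log_table_prob(table, lg_fact, const)
    cutoff = logp_obs + 1e-9
    r, c = table.shape
    p_total = 0.0
    visited = 0

    cur = np.zeros((r, c), dtype=int)

    def rec(i: int, j: int, col_rem: np.ndarray, row_rem: int) -> bool:
        nonlocal p_total, visited
        if visited > max_tables:
            return False
        if i == r:
            visited += 1
            lp = _log_table_prob(cur, lg_fact, const)
            if lp <= cutoff:
                p_total += math.exp(lp)
            return True
        if j == c - 1:
            if row_rem > col_rem[j]:
                return True
            cur[i, j] = row_rem
            col_rem[j] -= row_rem
            nxt = rows[i + 1] if i + 1 < r else 0
            ok = rec(i + 1, 0, col_rem, nxt)
            col_rem[j] += row_rem
            cur[i, j] = 0
            return ok
        lo = max(0, row_rem - int(col_rem[j + 1 :].sum()))
        hi = min(row_rem, int(col_rem[j]))
        for v in range(lo, hi + 1):
            cur[i, j] = v
            col_rem[j] -= v
            if not rec(i, j + 1, col_rem, row_rem - v):
                col_rem[j] += v
                cur[i, j] = 0
                return False
            col_rem[j] += v
            cur[i, j] = 0
        return True

    completed = rec(0, 0, cols.copy(), int(rows[0]))
    if not completed:
        return None
    return min(1.0, p_total)


def _exact_rxc_montecarlo(
    table: np.ndarray, replicates: int, seed: int
) -> float:
    """Seeded Monte-Carlo estimate of the exact conditional p-value.

    Samples margin-preserving tables by permuting the column labels of the
    pooled observations; uses the add-one estimator so p is never zero.
    """
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    r, c = table.shape
    lg_fact = np.zeros(n + 1)
    lg_fact[1:] = np.cumsum(np.log(np.arange(1, n + 1)))
    const = lg_fact[rows].sum() + lg_fact[cols].sum() - lg_fact[n]
    logp_obs = _log_table_prob(table, lg_fact, const)
    cutoff = logp_obs + 1e-9
    row_labels = np.repeat(np.arange(r), rows)
    col_labels = np.repeat(np.arange(c), cols)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(replicates):
        perm = rng.permutation(col_labels)
        sim = np.bincount(row_labels * c + perm, minlength=r * c).reshape(r, c)
        if _log_table_prob(sim, lg_fact, const) <= cutoff:
            hits += 1
    return (hits + 1) / (replicates + 1)


def compare_groups(
    table: Sequence[Sequence[int]],
    expected_min: float = 5.0,
    yates: bool = False,
    alpha: float = 0.05,
    mc_replicates: int = 100_000,
    mc_seed: int = 0,
    max_enumeration: int = 10_000_000,
) -> ComparisonResult:
    """Two-sided r×c homogeneity test with exact-test fallback.

    Pearson chi-square (Yates continuity correction optional, 2×2 only)
    when every expected cell count is at least ``expected_min``; otherwise
    an exact conditional test: hypergeometric for 2×2, exact enumeration of
    margin-preserving tables for larger tables, or a seeded Monte-Carlo
    approximation when more than ``max_enumeration`` tables share the
    margins.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("contingency table must hold integer counts")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    for axis, name in ((1, "row"), (0, "column")):
        margins = t.sum(axis=axis)
        bad = np.where(margins == 0)[0]
        if bad.size:
            raise ValueError(f"degenerate table: {name} {bad[0]} has a zero margin")

    expected = sps.contingency.expected_freq(t)
    detail: dict = {"expected_min_threshold": expected_min,
                    "min_expected": float(expected.min())}
    if expected.min() >= expected_min:
        correction = yates and t.shape == (2, 2)
        chi2, p, dof, _ = sps.chi2_contingency(t, correction=correction)
        detail["dof"] = int(dof)
        detail["yates_correction"] = bool(correction)
        return ComparisonResult(
            test_name="chi_square",
            statistic=float(chi2),
            p_value=float(p),
            table=t.tolist(),
            alpha=alpha,
            detail=detail,
        )
    if t.shape == (2, 2):
        _, p = sps.fisher_exact(t, alternative="two-sided")
        return ComparisonResult(
            test_name="fisher_exact",
            p_value=float(p),
            table=t.tolist(),
            alpha=alpha,
            detail=detail,
        )
    p_exact = _exact_rxc_enumerate(t, max_enumeration)
    if p_exact is not None:
        return ComparisonResult(
            test_name="freeman_halton_exact",
            p_value=float(p_exact),
            table=t.tolist(),
            alpha=alpha,
            detail={**detail, "method": "enumeration"},
        )
    p_mc = _exact_rxc_montecarlo(t, mc_replicates, mc_seed)
    return ComparisonResult(
        test_name="freeman_halton_exact",
        p_value=float(p_mc),
        table=t.tolist(),
        alpha=alpha,
        detail={**detail, "method": "monte_carlo",
                "replicates": mc_replicates, "seed": mc_seed},
    )


def compare_age(
    ages_a: Sequence[float], ages_b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two age samples.

    Exact null distribution when both samples are small (n <= 20) and
    untied; otherwise the normal approximation with mid-rank tie
    correction (no continuity correction, so identical samples give p = 1).
    """
    a = [float(x) for x in ages_a]
    b = [float(x) for x in ages_b]
    if not a or not b:
        raise ValueError("both age samples must be non-empty")
    pooled = a + b
    has_ties = len(set(pooled)) < len(pooled)
    small = max(len(a), len(b)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return ComparisonResult(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alpha=alpha,
        detail={"method": method, "n_a": len(a), "n_b": len(b)},
    )


# ---------------------------------------------------------------------------
# standard comparison battery
# ---------------------------------------------------------------------------


def _pivot_counts(df: pd.DataFrame, cats: Sequence[str], techs: Sequence[str],
                  **filters) -> np.ndarray:
    sub = df
    for k, v in filters.items():
        sub = sub[sub[k] == v]
    tab = []
    for cat in cats:
        row = [int(sub[(sub.technique == t) & (sub.category == cat)]["count"].iloc[0])
               for t in techs]
        tab.append(row)
    return np.array(tab)


def standard_comparisons(
    summary: CohortSummary,
    cohort: Optional[Sequence[PatientRecord]] = None,
    **test_kwargs,
) -> dict[str, ComparisonResult]:
    """The routine between-technique test battery on a two-group summary.

    Categories empty in both groups are dropped before testing (a zero
    margin is degenerate).  Clean-cut definitions are tested on pooled-side
    2×2 tables (clean vs not).  If ``cohort`` is given and both groups
    carry ages, an age comparison is included.
    """
    techs = sorted(summary.group_sizes)
    if len(techs) != 2:
        raise ValueError("standard comparisons need exactly two technique groups")
    out: dict[str, ComparisonResult] = {}
    specs = [
        ("right_side_quality", summary.side_quality, SIDE_CATEGORIES, {"side": "right"}),
        ("left_side_quality", summary.side_quality, SIDE_CATEGORIES, {"side": "left"}),
        ("overall_quality", summary.overall_quality, OVERALL_CATEGORIES, {}),
        ("symmetry", summary.symmetry, SYMMETRY_CATEGORIES, {}),
        ("alignment", summary.alignment, ("no", "yes"), {}),
    ]
    for name, df, cats, filters in specs:
        tab = _pivot_counts(df, cats, techs, **filters)
        keep = tab.sum(axis=1) > 0
        out[name] = compare_groups(tab[keep], **test_kwargs)
    cc = summary.cleancut
    for definition in ("inclusive", "strict"):
        sub = cc[(cc.definition == definition) & (cc.granularity == "pooled_by_sides")]
        tab = []
        for t in techs:
            row = sub[sub.technique == t]
            num = int(row["numerator"].iloc[0])
            den = int(row["denominator"].iloc[0])
            tab.append([num, den - num])
        out[f"{definition}_cleancut"] = compare_groups(np.array(tab).T, **test_kwargs)
    if cohort is not None:
        ages = {
            t: [p.age for p in cohort if p.technique.value == t and p.age is not None]
            for t in techs
        }
        if all(ages.values()):
            out["age"] = compare_age(ages[techs[0]], ages[techs[1]])
    return out
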