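"""Synthetic cohorts: random generation and exact constraint-based reconstruction.

Two complementary tools stand in for unavailable raw per-patient data:

* :func:`generate_cohort` draws random cohorts.  *Marginal* mode samples
  every checkpoint independently from per-site Bernoulli probabilities —
  deliberately ignoring within- and between-side correlation — and exists
  for statistical exercise of the pipeline.  *Pattern* mode draws each
  patient from named bilateral pattern classes (bilateral-excellent,
  very-good, good-mirror, fair, poor-tuberosity, poor-superior, mixed-poor)
  so the generated joint structure is the one the classifiers expect.

* :func:`reconstruct_cohort` deterministically builds a cohort whose
  classified summary reproduces a supplied set of printed counts *exactly*
  (group size, per-side quality, overall quality, symmetry, alignment,
  clean-cut numerators), with optional per-site prevalence counts treated
  as soft targets.  The category counts over-determine most of the
  allocation; the residual freedom (which inferior segment a single-segment
  side uses, which undesired flag a poor side carries, how inclusive
  clean-cut extras split between sides) is resolved by a small exact search
  that minimises deviation from the soft targets, with fixed documented
  priorities when no targets are given.  The function is pure: no
  randomness, bitwise-identical output across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .cleancut import clean_cut
from .model import (
    CheckpointMap,
    PatientRecord,
    SITE_KEYS,
    Technique,
    classify_side,
    maps_from_flags,
    patient_flags,
)
from .patient import OverallQuality, SymmetryCategory, classify_symmetry, overall_quality


class InfeasibleConstraints(ValueError):
    """Raised when no cohort can satisfy the supplied constraint set."""


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------

_SIDE_CATS = ("poor", "good", "excellent", "ungraded")
_OVERALL_CATS = ("poor", "fair", "good", "very_good", "excellent", "ungraded")


def _cls_bilateral_excellent(rng: np.random.Generator) -> list[int]:
    # all four inferior portions, nothing else
    return [0, 0, 1, 0, 1, 0, 0, 1, 0, 1]


def _cls_very_good(rng: np.random.Generator) -> list[int]:
    # one side both inferior, the other a single inferior segment
    flags = [0] * 10
    double = int(rng.integers(2))  # 0 = right, 1 = left
    single_seg = int(rng.integers(2))  # 0 = medial, 1 = lateral
    d, s = (0, 5) if double == 0 else (5, 0)
    flags[d + 2] = flags[d + 4] = 1
    flags[s + (2 if single_seg == 0 else 4)] = 1
    return flags


def _cls_good_mirror(rng: np.random.Generator) -> list[int]:
    # the same single inferior segment on both sides (mirror pair)
    seg = 2 if int(rng.integers(2)) == 0 else 4
    flags = [0] * 10
    flags[seg] = flags[5 + seg] = 1
    return flags


def _cls_fair(rng: np.random.Generator) -> list[int]:
    # exactly one inferior segment anywhere
    flags = [0] * 10
    side = 0 if int(rng.integers(2)) == 0 else 5
    seg = 2 if int(rng.integers(2)) == 0 else 4
    flags[side + seg] = 1
    return flags


def _cls_poor_tuberosity(rng: np.random.Generator) -> list[int]:
    # tuberosity extension over an otherwise inclusive cut on one side
    flags = list(_cls_bilateral_excellent(rng))
    side = 0 if int(rng.integers(2)) == 0 else 5
    flags[side + 0] = 1
    return flags


def _cls_poor_superior(rng: np.random.Generator) -> list[int]:
    # isolated superior propagation on one side, single inferior on the other
    flags = [0] * 10
    side = 0 if int(rng.integers(2)) == 0 else 5
    other = 5 - side
    sup = 1 if int(rng.integers(2)) == 0 else 3
    flags[side + sup] = 1
    flags[other + 2] = 1
    return flags


def _cls_mixed_poor(rng: np.random.Generator) -> list[int]:
    # inclusive cut on both sides with superior propagation on one
    flags = list(_cls_bilateral_excellent(rng))
    side = 0 if int(rng.integers(2)) == 0 else 5
    sup = 1 if int(rng.integers(2)) == 0 else 3
    flags[side + sup] = 1
    return flags


PATTERN_CLASSES = {
    "bilateral_excellent": _cls_bilateral_excellent,
    "very_good": _cls_very_good,
    "good_mirror": _cls_good_mirror,
    "fair": _cls_fair,
    "poor_tuberosity": _cls_poor_tuberosity,
    "poor_superior": _cls_poor_superior,
    "mixed_poor": _cls_mixed_poor,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic cohort draw.

    ``marginal`` mode requires ``marginal_probs`` with all ten site keys;
    ``pattern`` mode requires non-negative ``pattern_weights`` over
    :data:`PATTERN_CLASSES` (normalised before sampling).  ``seed`` fully
    determines the output.
    """

    mode: str
    n_patients: int
    technique: Technique = Technique.DIRECTED
    seed: int = 0
    marginal_probs: Optional[Mapping[str, float]] = None
    pattern_weights: Optional[Mapping[str, float]] = None
    age_mean: Optional[float] = None
    age_sd: float = 10.0
    id_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.mode not in ("marginal", "pattern"):
            raise ValueError(f"unknown generator mode {self.mode!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mode == "marginal":
            probs = self.marginal_probs
            if probs is None or set(probs) != set(SITE_KEYS):
                raise ValueError("marginal mode needs probabilities for all 10 sites")
            if any(not (0.0 <= probs[k] <= 1.0) for k in SITE_KEYS):
                raise ValueError("site probabilities must lie in [0, 1]")
        else:
            w = self.pattern_weights
            if not w or not set(w) <= set(PATTERN_CLASSES):
                raise ValueError(
                    f"pattern weights must be over {sorted(PATTERN_CLASSES)}"
                )
            if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise ValueError("pattern weights must be non-negative, not all zero")


def generate_cohort(spec: GeneratorSpec) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    if spec.mode == "marginal":
        p = np.array([spec.marginal_probs[k] for k in SITE_KEYS])
        draws = rng.random((spec.n_patients, 10)) < p
        flag_rows = draws.astype(int).tolist()
    else:
        names = sorted(spec.pattern_weights)
        w = np.array([spec.pattern_weights[k] for k in names], dtype=float)
        w = w / w.sum()
        picks = rng.choice(len(names), size=spec.n_patients, p=w)
        flag_rows = [PATTERN_CLASSES[names[i]](rng) for i in picks]
    ages: Sequence[Optional[float]]
    if spec.age_mean is not None:
        ages = np.maximum(rng.normal(spec.age_mean, spec.age_sd, spec.n_patients), 14.0)
        ages = np.round(ages, 1).tolist()
    else:
        ages = [None] * spec.n_patients
    for i, row in enumerate(flag_rows):
        right, left = maps_from_flags(row)
        records.append(
            PatientRecord(
                patient_id=f"{spec.id_prefix}{i + 1:05d}",
                technique=spec.technique,
                right=right,
                left=left,
                age=ages[i],
            )
        )
    return records


# ---------------------------------------------------------------------------
# constraint-based reconstruction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintSet:
    """Printed summary counts a reconstructed cohort must reproduce.

    ``side_quality`` maps side ("right"/"left") to category counts
    (poor/good/excellent, optionally ungraded); ``overall_quality`` the
    patient-level counts.  ``symmetry``, ``alignment`` and ``cleancut``
    (keys ``inclusive_pooled``/``inclusive_right``/``inclusive_left`` and
    the ``strict_*`` analogues) are optional hard constraints;
    ``site_targets`` (per-site involvement counts) are soft targets only.
    ``mirror_good`` makes patient-level GOOD patients mirror pairs, which
    is what lets them count as perfect symmetry under the mirror rule.
    """

    n: int
    overall_quality: Mapping[str, int]
    side_quality: Optional[Mapping[str, Mapping[str, int]]] = None
    symmetry: Optional[Mapping[str, int]] = None
    alignment: Optional[Mapping[str, int]] = None
    cleancut: Optional[Mapping[str, int]] = None
    site_targets: Optional[Mapping[str, int]] = None
    mirror_good: bool = True


def _norm_counts(raw: Mapping[str, int], cats: Sequence[str], n: int, what: str) -> dict:
    out = {}
    for c in cats:
        v = int(raw.get(c, 0))
        if v < 0 or v > n:
            raise InfeasibleConstraints(f"{what} count {c}={v} outside [0, n={n}]")
        out[c] = v
    unknown = set(raw) - set(cats)
    if unknown:
        raise InfeasibleConstraints(f"unknown {what} categories {sorted(unknown)}")
    return out


def _split_to_needs(total: int, need_a: int, need_b: int) -> tuple[int, int]:
    """Partition ``total`` into (a, b) minimising |a-need_a| + |b-need_b|."""
    na, nb = max(need_a, 0), max(need_b, 0)
    if total <= na + nb:
        a = min(na, total)
    else:
        a = max(na, total - nb)
    return a, total - a


class _Alloc:
    """One candidate inferior-segment allocation and its target deviation."""

    __slots__ = ("m", "x_r", "u", "e", "deviation")

    def __init__(self, m, x_r, u, e, deviation):
        self.m, self.x_r, self.u, self.e, self.deviation = m, x_r, u, e, deviation


def reconstruct_cohort(
    constraints: ConstraintSet,
    technique: Technique = Technique.DIRECTED,
    id_prefix: Optional[str] = None,
) -> list[PatientRecord]:
    """Deterministically build a cohort matching ``constraints`` exactly.

    Raises :class:`InfeasibleConstraints` naming the first violated
    cross-table identity when no cohort can satisfy the counts.
    """
    cs = constraints
    n = int(cs.n)
    if n < 1:
        raise InfeasibleConstraints("group size must be >= 1")
    ov = _norm_counts(cs.overall_quality, _OVERALL_CATS, n, "overall-quality")
    side_q = cs.side_quality
    if not side_q:
        # derive a consistent per-side distribution from the overall counts
        # (fixed priority: doubles and singles placed on the right first;
        # POOR patients poor on both sides)
        p_, f_, g_, v_, e_ = (ov[c] for c in _OVERALL_CATS[:-1])
        u_ = ov["ungraded"]
        side_q = {
            "right": {"poor": p_, "good": g_ + f_, "excellent": e_ + v_, "ungraded": u_},
            "left": {"poor": p_, "good": g_ + v_, "excellent": e_, "ungraded": u_ + f_},
        }
    elif "right" not in side_q or "left" not in side_q:
        raise InfeasibleConstraints("side_quality must give both sides or neither")
    sq_r = _norm_counts(side_q["right"], _SIDE_CATS, n, "right side-quality")
    sq_l = _norm_counts(side_q["left"], _SIDE_CATS, n, "left side-quality")

    # implicit ungraded sides: side categories must account for every patient
    for name, sq in (("right", sq_r), ("left", sq_l)):
        explicit = sq["poor"] + sq["good"] + sq["excellent"]
        if "ungraded" in side_q.get(name, {}):
            if explicit + sq["ungraded"] != n:
                raise InfeasibleConstraints(f"{name} side-quality counts do not sum to n={n}")
        else:
            if explicit > n:
                raise InfeasibleConstraints(f"{name} side-quality counts exceed n={n}")
            sq["ungraded"] = n - explicit
    explicit = sum(ov[c] for c in _OVERALL_CATS[:-1])
    if "ungraded" in cs.overall_quality:
        if explicit + ov["ungraded"] != n:
            raise InfeasibleConstraints(f"overall-quality counts do not sum to n={n}")
    else:
        if explicit > n:
            raise InfeasibleConstraints(f"overall-quality counts exceed n={n}")
        ov["ungraded"] = n - explicit

    P, F, G, V, E, U = (ov[c] for c in _OVERALL_CATS)
    rp, rg, re, r_un = (sq_r[c] for c in _SIDE_CATS)
    lp, lg, le, l_un = (sq_l[c] for c in _SIDE_CATS)

    # alignment identity: No == overall POOR; Yes == graded non-poor
    if cs.alignment is not None:
        al = _norm_counts(cs.alignment, ("no", "yes"), n, "alignment")
        if al["no"] != P:
            raise InfeasibleConstraints(
                f"alignment-No ({al['no']}) must equal overall POOR ({P})"
            )
        if al["yes"] != F + G + V + E:
            raise InfeasibleConstraints(
                f"alignment-Yes ({al['yes']}) must equal graded non-poor ({F + G + V + E})"
            )

    # symmetry identities under the mirror rule with the chosen GOOD pairing
    if cs.symmetry is not None:
        sym = _norm_counts(
            cs.symmetry,
            ("no_symmetry_no_alignment", "no_symmetry_with_alignment", "perfect_symmetry"),
            n,
            "symmetry",
        )
        if sym["no_symmetry_no_alignment"] != P:
            raise InfeasibleConstraints(
                f"no-symmetry-no-alignment ({sym['no_symmetry_no_alignment']}) "
                f"must equal overall POOR ({P})"
            )
        perfect = E + (G if cs.mirror_good else 0)
        if sym["perfect_symmetry"] != perfect:
            raise InfeasibleConstraints(
                f"perfect-symmetry ({sym['perfect_symmetry']}) must equal "
                f"EXCELLENT{' + GOOD (mirror pairing)' if cs.mirror_good else ''} ({perfect})"
            )
        if sym["no_symmetry_with_alignment"] != F + V + (0 if cs.mirror_good else G):
            raise InfeasibleConstraints(
                "no-symmetry-with-alignment count inconsistent with overall-quality counts"
            )

    # fair patients use one side; their other side is ungraded, as are both
    # sides of overall-ungraded patients
    f_r = l_un - U
    if not (0 <= f_r <= F) or r_un != U + F - f_r:
        raise InfeasibleConstraints(
            f"ungraded side counts (right {r_un}, left {l_un}) inconsistent with "
            f"overall FAIR={F} and UNGRADED={U}"
        )

    bp = rp + lp - P
    if bp < 0:
        raise InfeasibleConstraints(
            f"poor sides ({rp}+{lp}) cannot cover overall POOR patients ({P})"
        )
    if rp > P or lp > P:
        raise InfeasibleConstraints("a side has more POOR sides than POOR patients")

    # split of VERY_GOOD patients: a of them carry the double-inferior side
    # on the right.  pe/pg are the non-poor sides donated by POOR patients.
    a_min = max(0, G + V + f_r - rg, E + V - le)
    a_max = min(V, re - E, lg - G - (F - f_r))
    if a_min > a_max:
        raise InfeasibleConstraints(
            "side-quality counts incompatible with overall-quality counts "
            f"(no feasible VERY_GOOD left/right split: [{a_min}, {a_max}])"
        )
    a = a_min
    pe_r = re - E - a
    pg_r = rg - G - (V - a) - f_r
    pe_l = le - E - (V - a)
    pg_l = lg - G - a - (F - f_r)
    if pg_r + pe_r != P - rp or pg_l + pe_l != P - lp:
        raise InfeasibleConstraints(
            "non-poor side counts of POOR patients do not balance "
            f"(right {pg_r}+{pe_r} vs {P - rp}; left {pg_l}+{pe_l} vs {P - lp})"
        )

    # ---- inclusive clean-cut extras -------------------------------------
    x_r_range: Sequence[int]
    if cs.cleancut is not None:
        cc = dict(cs.cleancut)
        for key, want in (
            ("strict_pooled", re + le),
            ("strict_right", re),
            ("strict_left", le),
        ):
            if key in cc and int(cc[key]) != want:
                raise InfeasibleConstraints(
                    f"{key} ({cc[key]}) must equal the EXCELLENT side count ({want}); "
                    "strict clean-cut and per-side EXCELLENT are the same event"
                )
        if "inclusive_right" in cc or "inclusive_left" in cc:
            x_r_fix = int(cc.get("inclusive_right", re)) - re
            x_l_fix = int(cc.get("inclusive_left", le)) - le
            if not (0 <= x_r_fix <= rp) or not (0 <= x_l_fix <= lp):
                raise InfeasibleConstraints(
                    "by-side inclusive counts need more inclusive POOR sides than exist"
                )
            if "inclusive_pooled" in cc and int(cc["inclusive_pooled"]) != (
                re + x_r_fix + le + x_l_fix
            ):
                raise InfeasibleConstraints(
                    "pooled inclusive count inconsistent with by-side inclusive counts"
                )
            x_r_range = [x_r_fix]
            extra = x_r_fix + x_l_fix
        elif "inclusive_pooled" in cc:
            extra = int(cc["inclusive_pooled"]) - re - le
            if not (0 <= extra <= rp + lp):
                raise InfeasibleConstraints(
                    f"pooled inclusive count {cc['inclusive_pooled']} infeasible: "
                    f"strict sides {re + le}, POOR sides {rp + lp}"
                )
            x_r_range = range(max(0, extra - lp), min(rp, extra) + 1)
        else:
            extra = 0
            x_r_range = [0]
    else:
        extra = 0
        x_r_range = [0]
    free_pairs = cs.cleancut is None  # poor sides may take both inferior flags

    # ---- search the residual freedom against soft site targets ----------
    tg = dict(cs.site_targets) if cs.site_targets else None
    ur_r = rg - G  # uncoupled right singles (GOOD pairs use one per side)
    ur_l = lg - G
    if ur_r < 0 or ur_l < 0:
        raise InfeasibleConstraints("GOOD patients exceed per-side GOOD counts")

    def eval_alloc(m: int, x_r: int) -> _Alloc:
        x_l = extra - x_r
        u, e, dev = {}, {}, 0
        for s, (exc, ur, xs, ps) in (
            ("r", (re, ur_r, x_r, rp)),
            ("l", (le, ur_l, x_l, lp)),
        ):
            if tg is None:
                u[s] = (ur, 0)  # all singles medial by default priority
                e[s] = (0, 0)
                continue
            if cs.mirror_good:
                mir_med, mir_lat = m, G - m
            else:  # anti-paired GOOD: m × (right med, left lat)
                mir_med = m if s == "r" else G - m
                mir_lat = G - m if s == "r" else m
            n_med = tg.get(f"{s}_med_inf", 0) - exc - xs - mir_med
            n_lat = tg.get(f"{s}_lat_inf", 0) - exc - xs - mir_lat
            u_med, u_lat = _split_to_needs(ur, n_med, n_lat)
            rem_med, rem_lat = max(n_med - u_med, 0), max(n_lat - u_lat, 0)
            cap = (ps - xs) * (2 if free_pairs else 1)
            e_med = min(rem_med, ps - xs)
            e_lat = min(rem_lat, min(ps - xs, cap - e_med))
            dev += abs(n_med - u_med - e_med) + abs(n_lat - u_lat - e_lat)
            u[s] = (u_med, u_lat)
            e[s] = (e_med, e_lat)
        return _Alloc(m, x_r, u, e, dev)

    best: Optional[_Alloc] = None
    m_range = range(G + 1) if tg is not None else [G]
    for x_r in x_r_range:
        for m in m_range:
            cand = eval_alloc(m, x_r)
            if best is None or cand.deviation < best.deviation:
                best = cand
            if best.deviation == 0:
                break
        if best.deviation == 0:
            break
    assert best is not None
    x_r, x_l = best.x_r, extra - best.x_r

    # ---- materialise patients ------------------------------------------
    sides: dict[str, list[dict]] = {"r": [], "l": []}
    roster: list[tuple[dict, dict]] = []

    def new_side(kind: str, body: str) -> dict:
        d = {"kind": kind, "tub": 0, "med_sup": 0, "med_inf": 0, "lat_sup": 0, "lat_inf": 0}
        if kind == "exc":
            d["med_inf"] = d["lat_inf"] = 1
        sides[body].append(d)
        return d

    def add_patient(rk: str, lk: str) -> None:
        roster.append((new_side(rk, "r"), new_side(lk, "l")))

    for _ in range(E):
        add_patient("exc", "exc")
    # VERY_GOOD: a patients double on the right, V - a on the left
    for _ in range(a):
        add_patient("exc", "good")
    for _ in range(V - a):
        add_patient("good", "exc")
    # patient-level GOOD: mirror pairs (or anti-paired when mirror_good=False)
    good_pairs: list[tuple[dict, dict]] = []
    for _ in range(G):
        add_patient("good", "good")
        good_pairs.append(roster[-1])
    for _ in range(f_r):
        add_patient("good", "ung")
    for _ in range(F - f_r):
        add_patient("ung", "good")
    for _ in range(U):
        add_patient("ung", "ung")
    for _ in range(bp):
        add_patient("poor", "poor")
    for _ in range(pe_l):  # right-only-poor with an EXCELLENT left
        add_patient("poor", "exc")
    for _ in range(pg_l):
        add_patient("poor", "good")
    for _ in range(pe_r):
        add_patient("exc", "poor")
    for _ in range(pg_r):
        add_patient("good", "poor")

    # mirror/anti-paired GOOD segments: first m pairs medial(-lat), rest lateral(-med)
    for i, (rs, ls) in enumerate(good_pairs):
        if cs.mirror_good:
            seg = "med_inf" if i < best.m else "lat_inf"
            rs[seg] = ls[seg] = 1
        else:
            if i < best.m:
                rs["med_inf"] = ls["lat_inf"] = 1
            else:
                rs["lat_inf"] = ls["med_inf"] = 1
    # uncoupled single-inferior sides, in roster order
    for body in ("r", "l"):
        u_med, _u_lat = best.u[body]
        singles = [
            d for d in sides[body] if d["kind"] == "good" and d["med_inf"] + d["lat_inf"] == 0
        ]
        for i, d in enumerate(singles):
            d["med_inf" if i < u_med else "lat_inf"] = 1
    # POOR sides: inclusive marks, then extra single inferior flags
    for body, xs in (("r", x_r), ("l", x_l)):
        poor = [d for d in sides[body] if d["kind"] == "poor"]
        for d in poor[:xs]:
            d["med_inf"] = d["lat_inf"] = 1
        e_med, e_lat = best.e[body]
        pool = poor[xs:]
        if free_pairs:
            for i in range(e_med):
                pool[i]["med_inf"] = 1
            for i in range(e_lat):
                pool[i]["lat_inf"] = 1
        else:
            for i, d in enumerate(pool):
                if i < e_med:
                    d["med_inf"] = 1
                elif i < e_med + e_lat:
                    d["lat_inf"] = 1
        # undesired flags: every POOR side needs >= 1 of tuberosity/superior
        if tg is None:
            for d in poor:
                d["tub"] = 1
        else:
            remaining = {
                "tub": tg.get(f"{body}_tub", 0),
                "med_sup": tg.get(f"{body}_med_sup", 0),
                "lat_sup": tg.get(f"{body}_lat_sup", 0),
            }
            order = ("tub", "med_sup", "lat_sup")
            for d in poor:
                pick = max(order, key=lambda k: remaining[k])
                if remaining[pick] <= 0:
                    pick = "tub"
                d[pick] = 1
                remaining[pick] -= 1
            for k in order:
                for d in poor:
                    if remaining[k] <= 0:
                        break
                    if not d[k]:
                        d[k] = 1
                        remaining[k] -= 1

    prefix = id_prefix if id_prefix is not None else technique.value[:3].upper() + "-"
    records = []
    for i, (rs, ls) in enumerate(roster):
        right = CheckpointMap.from_flags(
            [rs["tub"], rs["med_sup"], rs["med_inf"], rs["lat_sup"], rs["lat_inf"]]
        )
        left = CheckpointMap.from_flags(
            [ls["tub"], ls["med_sup"], ls["med_inf"], ls["lat_sup"], ls["lat_inf"]]
        )
        records.append(
            PatientRecord(f"{prefix}{i + 1:03d}", technique, right=right, left=left)
        )

    _verify_reconstruction(records, cs, sq_r, sq_l, ov)
    return records


def _verify_reconstruction(records, cs, sq_r, sq_l, ov) -> None:
    """Recount the hard constraints on the built cohort; raise on mismatch."""
    got_sq = {"right": dict.fromkeys(_SIDE_CATS, 0), "left": dict.fromkeys(_SIDE_CATS, 0)}
    got_ov = dict.fromkeys(_OVERALL_CATS, 0)
    cc = {"inclusive_right": 0, "inclusive_left": 0, "strict_right": 0, "strict_left": 0}
    sym = dict.fromkeys(
        ("no_symmetry_no_alignment", "no_symmetry_with_alignment", "perfect_symmetry"), 0
    )
    for p in records:
        for side_name, cmap in (("right", p.right), ("left", p.left)):
            got_sq[side_name][classify_side(cmap).name.lower()] += 1
            f = clean_cut(cmap)
            cc[f"inclusive_{side_name}"] += f.inclusive
            cc[f"strict_{side_name}"] += f.strict
        q = overall_quality(p)
        got_ov[q.name.lower()] += 1
        if q is not OverallQuality.UNGRADED:
            s = classify_symmetry(p, rule="mirror")
            key = {
                SymmetryCategory.NO_SYMMETRY_NO_ALIGNMENT: "no_symmetry_no_alignment",
                SymmetryCategory.ALIGNED_NOT_SYMMETRIC: "no_symmetry_with_alignment",
                SymmetryCategory.PERFECT_SYMMETRY: "perfect_symmetry",
            }[s]
            sym[key] += 1
    for side_name, want in (("right", sq_r), ("left", sq_l)):
        if got_sq[side_name] != want:
            raise InfeasibleConstraints(
                f"reconstruction cannot realise {side_name} side-quality counts "
                f"(wanted {want}, achieved {got_sq[side_name]})"
            )
    if got_ov != ov:
        raise InfeasibleConstraints(
            f"reconstruction cannot realise overall-quality counts "
            f"(wanted {ov}, achieved {got_ov})"
        )
    if cs.cleancut is not None:
        ccs = dict(cs.cleancut)
        checks = {
            "inclusive_pooled": cc["inclusive_right"] + cc["inclusive_left"],
            "inclusive_right": cc["inclusive_right"],
            "inclusive_left": cc["inclusive_left"],
            "strict_pooled": cc["strict_right"] + cc["strict_left"],
            "strict_right": cc["strict_right"],
            "strict_left": cc["strict_left"],
        }
        for k, got in checks.items():
            if k in ccs and int(ccs[k]) != got:
                raise InfeasibleConstraints(
                    f"reconstruction cannot realise clean-cut count {k} "
                    f"(wanted {ccs[k]}, achieved {got})"
                )
    if cs.symmetry is not None:
        want_sym = {k: int(cs.symmetry.get(k, 0)) for k in sym}
        if sym != want_sym:
            raise InfeasibleConstraints(
                f"reconstruction cannot realise symmetry counts "
                f"(wanted {want_sym}, achieved {sym})"
            )


def constraints_from_cohort(
    cohort: Sequence[PatientRecord], include_sites: bool = True, mirror_good: bool = True
) -> dict[str, ConstraintSet]:
    """Summarise a cohort into per-technique :class:`ConstraintSet` objects.

    The inverse direction of :func:`reconstruct_cohort`: classify every
    patient, count, and package the counts as constraints (with the per-site
    counts as soft targets when ``include_sites``).
    """
    out = {}
    for tech in Technique:
        group = [p for p in cohort if p.technique is tech]
        if not group:
            continue
        sq = {"right": dict.fromkeys(_SIDE_CATS, 0), "left": dict.fromkeys(_SIDE_CATS, 0)}
        ov = dict.fromkeys(_OVERALL_CATS, 0)
        cc = {"inclusive_right": 0, "inclusive_left": 0}
        site = dict.fromkeys(SITE_KEYS, 0)
        for p in group:
            for side_name, cmap in (("right", p.right), ("left", p.left)):
                sq[side_name][classify_side(cmap).name.lower()] += 1
                cc[f"inclusive_{side_name}"] += clean_cut(cmap).inclusive
            ov[overall_quality(p).name.lower()] += 1
            for k, v in zip(SITE_KEYS, patient_flags(p)):
                site[k] += int(v)
        out[tech.value] = ConstraintSet(
            n=len(group),
            side_quality=sq,
            overall_quality=ov,
            cleancut={
                "inclusive_right": cc["inclusive_right"],
                "inclusive_left": cc["inclusive_left"],
                "strict_right": sq["right"]["excellent"],
                "strict_left": sq["left"]["excellent"],
            },
            site_targets=site if include_sites else None,
            mirror_good=mirror_good,
        )
    return out
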