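"""EHR-style cohort phenotyping for GLP1-RA and bariatric-surgery arms.

From longitudinal person/weight/drug/procedure tables this module finds
treatment initiation (T0), applies the inclusion and exclusion rules,
and derives the percentage-weight-change outcome:

* baseline weight W0: the measurement closest to T0 within the year
  before T0, falling back to the first 14 days after T0 only when no
  earlier measurement exists;
* follow-up weight mW1: the median (or, as a sensitivity definition, the
  minimum) of measurements 26-52 weeks after T0 for GLP1-RA, or
  180-1460 days after surgery;
* outcome: (mW1 − W0)/W0 × 100, negative = weight loss.

All window logic runs on integer day offsets from the per-person T0;
windows are closed intervals.  Every exclusion step is counted in an
attrition log whose counts sum to the number of input persons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GLP1_ATC_PREFIX",
    "GLP1_ATC_EXTRA",
    "ATC_TO_DRUG",
    "SEMA_LIRA_DRUGS",
    "CohortOptions",
    "TreatmentEpisode",
    "is_glp1_code",
    "find_glp1_initiation",
    "assess_persistence",
    "select_baseline_weight",
    "select_followup_weight",
    "percent_weight_change",
    "merge_same_day_weights",
    "build_cohort",
]

#: GLP1-RA identification: the dedicated ATC subgroup plus legacy codes.
GLP1_ATC_PREFIX = "A10BJ"
GLP1_ATC_EXTRA = frozenset({"A10BX04", "A10BX10", "A10BX13", "A10BX14"})

#: ATC code -> drug substance, for medication-type covariates and subgroups.
ATC_TO_DRUG: Mapping[str, str] = {
    "A10BJ01": "exenatide",
    "A10BJ02": "liraglutide",
    "A10BJ03": "lixisenatide",
    "A10BJ04": "albiglutide",
    "A10BJ05": "dulaglutide",
    "A10BJ06": "semaglutide",
    "A10BJ07": "beinaglutide",
    "A10BX04": "exenatide",
    "A10BX10": "lixisenatide",
    "A10BX13": "albiglutide",
    "A10BX14": "dulaglutide",
}

SEMA_LIRA_DRUGS = frozenset({"semaglutide", "liraglutide"})

DAYS_PER_YEAR = 365.25


def is_glp1_code(atc: str) -> bool:
    return atc.startswith(GLP1_ATC_PREFIX) or atc in GLP1_ATC_EXTRA


@dataclass(frozen=True)
class TreatmentEpisode:
    person_id: str
    arm: str
    t0: pd.Timestamp
    medication_type: str | None = None  # GLP1-RA only (ATC at initiation)
    procedure_type: str | None = None  # BS only
    persistent_12m: bool | None = None
    last_coverage_end: pd.Timestamp | None = None


@dataclass(frozen=True)
class CohortOptions:
    """Tunable phenotyping rules; defaults reproduce the primary analysis."""

    aggregate: str = "median"  # or "min" (sensitivity outcome)
    max_gap_days: int = 90  # largest tolerated uncovered refill gap
    baseline_lookback_days: int = 364  # "-52 weeks"
    baseline_post_days: int = 14  # "+2 weeks" fallback
    glp1_followup_window: tuple[int, int] = (182, 364)  # 26-52 weeks
    bs_followup_window: tuple[int, int] = (180, 1460)  # 180 days - 48 months
    min_days_pre_op: int = 0  # BS sensitivity: baseline >= this many days pre-op
    near_coverage_filter: bool = True  # GLP1: follow-up within drug coverage
    near_coverage_days: int = 30  # "within one month of the last purchase"
    min_age_years: float = 18.0


def find_glp1_initiation(drugs: pd.DataFrame, person_id: str | None = None) -> TreatmentEpisode | None:
    """First GLP1-RA record of one person's drug table; None if absent.

    Records on the same first day are tie-broken by lexicographic ATC code
    for the medication-type assignment.
    """
    d = drugs[drugs["atc_code"].map(is_glp1_code)]
    if d.empty:
        return None
    d = d.sort_values(["date", "atc_code"], kind="mergesort")
    first = d.iloc[0]
    pid = person_id if person_id is not None else str(first["person_id"])
    return TreatmentEpisode(pid, "glp1", pd.Timestamp(first["date"]), medication_type=str(first["atc_code"]))


def _coverage_ok(starts: np.ndarray, ends: np.ndarray, horizon: int, max_gap: int) -> bool:
    """True iff every maximal uncovered gap of [0, horizon] is <= max_gap."""
    order = np.argsort(starts, kind="mergesort")
    covered_to = 0.0
    for s, e in zip(starts[order], ends[order]):
        if s > covered_to + max_gap:
            return False
        covered_to = max(covered_to, e)
        if covered_to >= horizon:
            return True
    return horizon - covered_to <= max_gap


def assess_persistence(
    episode: TreatmentEpisode,
    drugs: pd.DataFrame,
    max_gap_days: int = 90,
    horizon_days: int = 364,
) -> TreatmentEpisode:
    """Judge 12-month persistence from the refill chain.

    The union of per-record coverage intervals [date, date + days_supply]
    must cover [T0, T0 + horizon] leaving no uncovered gap longer than
    ``max_gap_days``.  Returns the episode with ``persistent_12m`` and
    ``last_coverage_end`` filled in.
    """
    d = drugs[drugs["atc_code"].map(is_glp1_code)]
    offs = (pd.to_datetime(d["date"]) - episode.t0).dt.days.to_numpy(float)
    supply = d["days_supply"].to_numpy(float)
    keep = offs >= 0
    offs, supply = offs[keep], supply[keep]
    if offs.size == 0:
        return replace(episode, persistent_12m=False, last_coverage_end=None)
    ok = _coverage_ok(offs, offs + supply, horizon_days, max_gap_days)
    last_end = episode.t0 + pd.Timedelta(days=float(np.max(offs + supply)))
    return replace(episode, persistent_12m=bool(ok), last_coverage_end=last_end)


def merge_same_day_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Average multiple same-day measurements per person (symmetric rule)."""
    return (
        weights.groupby(["person_id", "date"], as_index=False, sort=True)["weight_kg"]
        .mean()
    )


def select_baseline_weight(
    days: np.ndarray,
    weights: np.ndarray,
    *,
    lookback_days: int = 364,
    post_days: int = 14,
    min_days_pre: int = 0,
) -> tuple[float, int] | None:
    """Baseline weight W0 from day offsets relative to T0.

    Measurements in [-lookback, 0] are preferred (closest to day 0 wins;
    for equal distance the earlier, pre-baseline one); only if that window
    is empty is the closest measurement in (0, post_days] used.
    ``min_days_pre`` > 0 restricts the pre-window to days <= -min_days_pre
    and disables the post-T0 fallback (pre-operative sensitivity rule).
    """
    days = np.asarray(days)
    weights = np.asarray(weights, dtype=float)
    hi = -min_days_pre if min_days_pre > 0 else 0
    pre = (days >= -lookback_days) & (days <= hi)
    if pre.any():
        i = np.flatnonzero(pre)[np.argmax(days[pre])]  # closest to T0 from below
        return float(weights[i]), int(days[i])
    if min_days_pre > 0:
        return None
    post = (days > 0) & (days <= post_days)
    if post.any():
        i = np.flatnonzero(post)[np.argmin(days[post])]
        return float(weights[i]), int(days[i])
    return None


def select_followup_weight(
    days: np.ndarray,
    weights: np.ndarray,
    arm: str,
    *,
    aggregate: str = "median",
    window: tuple[int, int] | None = None,
    max_day: int | None = None,
) -> tuple[float, int] | None:
    """Follow-up weight mW1 over the closed outcome window.

    ``window`` defaults per arm ([182, 364] GLP1-RA, [180, 1460] BS);
    ``max_day`` additionally caps eligible days (drug-coverage filter).
    Returns (aggregated weight, number of contributing measurements).
    """
    if window is None:
        window = (182, 364) if arm == "glp1" else (180, 1460)
    days = np.asarray(days)
    weights = np.asarray(weights, dtype=float)
    lo, hi = window
    mask = (days >= lo) & (days <= hi)
    if max_day is not None:
        mask &= days <= max_day
    if not mask.any():
        return None
    w = weights[mask]
    if aggregate == "median":
        val = float(np.median(w))
    elif aggregate == "min":
        val = float(np.min(w))
    else:
        raise ValueError(f"unknown aggregate: {aggregate!r}")
    return val, int(mask.sum())


def percent_weight_change(w0: float, mw1: float) -> float:
    """(mW1 − W0)/W0 × 100; negative values are weight loss."""
    if w0 <= 0:
        raise ValueError("baseline weight must be > 0")
    return (mw1 - w0) / w0 * 100.0


def _person_weight_arrays(weights: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pid, grp in weights.groupby("person_id", sort=False):
        out[pid] = (pd.to_datetime(grp["date"]).to_numpy(), grp["weight_kg"].to_numpy(float))
    return out


def build_cohort(
    tables: Mapping[str, pd.DataFrame],
    arm: str,
    options: CohortOptions | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the full inclusion/exclusion cascade and derive outcomes.

    ``tables`` must contain ``persons``, ``weights`` and, per arm,
    ``drugs`` (GLP1-RA) / ``procedures`` (BS).  Returns the cohort
    DataFrame (one row per surviving person) and an attrition log mapping
    each filter, in application order, to the number of persons it
    removed; counts plus survivors sum to the input person count.
    """
    if arm not in {"glp1", "bs"}:
        raise ValueError(f"unknown arm: {arm!r}")
    opt = options or CohortOptions()
    persons = tables["persons"]
    required = {"person_id", "study_id", "ancestry", "sex", "birth_date", "t2d"}
    missing = required - set(persons.columns)
    if missing:
        raise ValueError(f"persons table missing columns: {sorted(missing)}")
    for tab, cols in (("weights", {"person_id", "date", "weight_kg"}),):
        miss = cols - set(tables[tab].columns)
        if miss:
            raise ValueError(f"{tab} table missing columns: {sorted(miss)}")

    weights = merge_same_day_weights(tables["weights"])
    warr = _person_weight_arrays(weights)

    attrition: dict[str, int] = {}
    order = (
        ["no_arm_event", "under_18", "not_persistent", "no_baseline_weight",
         "no_followup_weight", "bs_during_first_year"]
        if arm == "glp1"
        else ["no_arm_event", "under_18", "no_baseline_weight", "no_followup_weight"]
    )
    for k in order:
        attrition[k] = 0

    # --- arm event detection -------------------------------------------------
    episodes: dict[str, TreatmentEpisode] = {}
    tie_count = 0
    if arm == "glp1":
        drugs = tables["drugs"]
        gl = drugs[drugs["atc_code"].map(is_glp1_code)].copy()
        gl["date"] = pd.to_datetime(gl["date"])
        by_person: dict[str, pd.DataFrame] = {p: g for p, g in gl.groupby("person_id", sort=False)}
        for pid, g in by_person.items():
            ep = find_glp1_initiation(g, person_id=pid)
            if ep is not None:
                same_day = (g["date"] == ep.t0).sum()
                if same_day > 1:
                    tie_count += 1
                episodes[pid] = ep
    else:
        procs = tables["procedures"].copy()
        procs["date"] = pd.to_datetime(procs["date"])
        procs = procs.sort_values(["date", "procedure_type"], kind="mergesort")
        for pid, g in procs.groupby("person_id", sort=False):
            first = g.iloc[0]
            episodes[pid] = TreatmentEpisode(
                pid, "bs", pd.Timestamp(first["date"]), procedure_type=str(first["procedure_type"])
            )

    # first-exposure dates for the GLP1 "no surgery in first year" exclusion
    first_bs: dict[str, pd.Timestamp] = {}
    if arm == "glp1" and "procedures" in tables and not tables["procedures"].empty:
        fb = tables["procedures"].copy()
        fb["date"] = pd.to_datetime(fb["date"])
        first_bs = fb.groupby("person_id")["date"].min().to_dict()

    persons = persons.set_index("person_id", drop=False)
    birth = pd.to_datetime(persons["birth_date"])

    rows = []
    for pid in persons.index:
        ep = episodes.get(pid)
        if ep is None:
            attrition["no_arm_event"] += 1
            continue
        age = (ep.t0 - birth.loc[pid]).days / DAYS_PER_YEAR
        if age < opt.min_age_years:
            attrition["under_18"] += 1
            continue
        max_day = None
        if arm == "glp1":
            ep = assess_persistence(ep, by_person[pid], opt.max_gap_days)
            if not ep.persistent_12m:
                attrition["not_persistent"] += 1
                continue
            if opt.near_coverage_filter and ep.last_coverage_end is not None:
                max_day = (ep.last_coverage_end - ep.t0).days + opt.near_coverage_days
        dates, wkg = warr.get(pid, (np.array([], dtype="datetime64[ns]"), np.array([])))
        days = ((dates - np.datetime64(ep.t0)) / np.timedelta64(1, "D")).astype(int) if dates.size else np.array([], int)
        base = select_baseline_weight(
            days, wkg,
            lookback_days=opt.baseline_lookback_days,
            post_days=opt.baseline_post_days,
            min_days_pre=opt.min_days_pre_op if arm == "bs" else 0,
        )
        if base is None:
            attrition["no_baseline_weight"] += 1
            continue
        w0, w0_day = base
        window = opt.glp1_followup_window if arm == "glp1" else opt.bs_followup_window
        fu = select_followup_weight(
            days, wkg, arm, aggregate=opt.aggregate, window=window, max_day=max_day
        )
        if fu is None:
            attrition["no_followup_weight"] += 1
            continue
        mw1, n_fu = fu
        if arm == "glp1":
            bs_date = first_bs.get(pid)
            if bs_date is not None and (bs_date - ep.t0).days <= 364:
                attrition["bs_during_first_year"] += 1
                continue
        prow = persons.loc[pid]
        rows.append(
            {
                "person_id": pid,
                "arm": arm,
                "study_id": prow["study_id"],
                "ancestry": prow["ancestry"],
                "stratum": f"{prow['study_id']}:{prow['ancestry']}",
                "sex": prow["sex"],
                "age": age,
                "t2d": int(prow["t2d"]),
                "t0_date": ep.t0,
                "w0_kg": w0,
                "w0_day": w0_day,
                "mw1_kg": mw1,
                "n_followup": n_fu,
                "pct_change": percent_weight_change(w0, mw1),
                "medication_type": (
                    ATC_TO_DRUG.get(ep.medication_type, ep.medication_type) if arm == "glp1" else None
                ),
                "procedure_type": ep.procedure_type if arm == "bs" else None,
            }
        )
    cohort = pd.DataFrame(
        rows,
        columns=[
            "person_id", "arm", "study_id", "ancestry", "stratum", "sex", "age",
            "t2d", "t0_date", "w0_kg", "w0_day", "mw1_kg", "n_followup",
            "pct_change", "medication_type", "procedure_type",
        ],
    )
    log = {
        "arm": arm,
        "n_input": int(len(persons)),
        "n_cohort": int(len(cohort)),
        "excluded": attrition,
        "filter_order": order,
        "medication_tie_count": tie_count,
    }
    return cohort, log
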