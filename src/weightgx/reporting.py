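"""Summary tables, weighted averages and forest-plot data.

Includes a loader for the transcribed published cohort-characteristics
table (per-stratum summary statistics only, no individual-level data),
used to regression-test the sample-size-weighted averages the analysis
reports.
"""

from __future__ import annotations

from importlib.resources import files
from typing import Sequence

import numpy as np
import pandas as pd

from .metapower import MetaResult, bonferroni_threshold

__all__ = [
    "make_table1",
    "weighted_summary",
    "load_published_table1",
    "forest_data",
]


def make_table1(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum baseline characteristics of an analysis cohort.

    One row per study × ancestry: n, proportion of women, mean (s.d.)
    baseline weight and age, T2D prevalence and — for GLP1-RA cohorts —
    the modal medication and the semaglutide share at initiation.
    Percentages are rounded to 1 decimal, kg/years to 2, matching the
    precision used for published cohort tables.
    """
    rows = []
    glp1 = (cohort["arm"] == "glp1").any()
    for (study, anc), grp in cohort.groupby(["study_id", "ancestry"], sort=True):
        row = {
            "study_id": study,
            "ancestry": anc,
            "n": int(len(grp)),
            "prop_women_pct": round(float((grp["sex"] == "F").mean() * 100), 1),
            "mean_weight_kg": round(float(grp["w0_kg"].mean()), 2),
            "sd_weight_kg": round(float(grp["w0_kg"].std(ddof=1)), 2) if len(grp) > 1 else float("nan"),
            "mean_age_years": round(float(grp["age"].mean()), 2),
            "sd_age_years": round(float(grp["age"].std(ddof=1)), 2) if len(grp) > 1 else float("nan"),
            "t2d_prev_pct": round(float(grp["t2d"].mean() * 100), 1),
        }
        if glp1:
            meds = grp["medication_type"].dropna()
            row["modal_medication"] = meds.mode().iloc[0] if not meds.empty else None
            row["prop_semaglutide_pct"] = round(float((meds == "semaglutide").mean() * 100), 1)
        rows.append(row)
    return pd.DataFrame(rows)


def weighted_summary(ns: Sequence[float], values: Sequence[float], name: str = "") -> dict:
    """Sample-size-weighted average Σ nᵢvᵢ / Σ nᵢ across strata."""
    n = np.asarray(ns, dtype=float)
    v = np.asarray(values, dtype=float)
    if n.size == 0:
        raise ValueError("weighted_summary requires at least one stratum")
    if np.any(n < 1):
        raise ValueError("all stratum sizes must be >= 1")
    return {
        "quantity": name,
        "weighted_value": float(np.sum(n * v) / np.sum(n)),
        "total_n": int(np.sum(n)),
    }


def load_published_table1() -> pd.DataFrame:
    """Transcribed published per-stratum summary statistics (both arms).

    These are aggregate statistics from a published cohort table — no
    individual-level biobank data — shipped so that the weighted-average
    computations can be checked against the printed values.
    """
    path = files("weightgx").joinpath("data/table1_published.tsv")
    with path.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def forest_data(
    meta_results: Sequence[MetaResult],
    fits: pd.DataFrame,
    *,
    alpha: float = 0.05,
    n_tests: int = 1,
) -> pd.DataFrame:
    """Per-stratum and pooled rows with 95% CIs and significance flags.

    ``fits`` is the tidy stratum-level table from the association stage;
    each meta result contributes one pooled row per exposure/scope.  The
    significance flag applies the Bonferroni threshold alpha/n_tests.
    """
    if not meta_results:
        raise ValueError("no meta-analysis results supplied")
    meta_keys = {m.exposure_id for m in meta_results}
    fit_keys = set(fits["exposure_id"].unique()) if len(fits) else set()
    if not fit_keys <= meta_keys:
        raise ValueError(f"fits contain exposures without meta results: {sorted(fit_keys - meta_keys)}")
    thr = bonferroni_threshold(alpha, n_tests)
    rows = []
    for _, r in fits.iterrows():
        rows.append({
            "exposure_id": r["exposure_id"], "row_type": "stratum", "label": r["stratum"],
            "beta": r["beta"], "ci_lo": r["beta"] - 1.96 * r["se"],
            "ci_hi": r["beta"] + 1.96 * r["se"], "p": r["p"], "n": r["n"],
            "significant": bool(r["p"] < thr),
        })
    for m in meta_results:
        rows.append({
            "exposure_id": m.exposure_id, "row_type": "pooled", "label": m.scope,
            "beta": m.beta, "ci_lo": m.beta - 1.96 * m.se, "ci_hi": m.beta + 1.96 * m.se,
            "p": m.p, "n": m.n, "significant": bool(m.p < thr),
        })
    return pd.DataFrame(rows)
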