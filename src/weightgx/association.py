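"""Stratified linear models of weight change on genetic exposures.

The primary model regresses percentage weight change on one genetic
exposure at a time, adjusting for baseline weight, sex, age at
initiation, the first 20 genetic principal components and (GLP1-RA only)
medication type, separately within each study-by-ancestry stratum.  The
secondary model uses the follow-up weight itself as the outcome and adds
a baseline-by-exposure interaction.  Fitting is ordinary least squares
via QR decomposition; standard errors come from sigma²(XᵀX)⁻¹ and
p-values from both tails of Student's t on the residual degrees of
freedom.

Also here: a simulation of baseline-adjustment (collider) bias — when a
variant shifts true baseline weight and baseline is measured with error,
adjusting the change score for measured baseline manufactures a spurious
exposure-outcome association that the unadjusted model does not show.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import genetics as gx
from .phenotyping import SEMA_LIRA_DRUGS, CohortOptions, build_cohort

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_ols",
    "build_design_matrix",
    "run_stratified",
    "run_covariate_model",
    "run_ancestry_contrast",
    "run_sensitivity_suite",
    "SENSITIVITY_VARIANTS",
    "collider_type1_error",
]

PC_COLS = [f"pc{i}" for i in range(1, 21)]


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what; flags mirror the analysis variants."""

    outcome: str = "pct_change"  # or "post_weight" (mW1 as outcome)
    exposure_id: str | None = None
    adjust_baseline: bool = True
    adjust_t2d: bool = False
    include_medication_type: bool = True  # honored for the GLP1-RA arm only
    interaction_baseline_x_exposure: bool = False
    subgroup: str | None = None  # semaglutide_liraglutide | rygb | sg
    extra_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.outcome not in {"pct_change", "post_weight"}:
            raise ValueError(f"unknown outcome: {self.outcome!r}")
        if self.interaction_baseline_x_exposure and self.outcome != "post_weight":
            raise ValueError("the baseline-by-exposure interaction is defined for the post_weight model only")


@dataclass(frozen=True)
class FitResult:
    """A full OLS fit: coefficient vector with SEs and t-test p-values."""

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    df_resid: int
    rss: float = field(default=float("nan"), compare=False)

    def term(self, name: str) -> tuple[float, float, float]:
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i]), float(self.p[i])


def fit_ols(y: np.ndarray, X: np.ndarray, names: Sequence[str] | None = None) -> FitResult:
    """Least squares through a QR decomposition.

    Requires n > p and full column rank; a rank-deficient design raises
    ``ValueError`` naming the offending columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if n <= p:
        raise ValueError(f"need more observations ({n}) than columns ({p})")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[j] for j in range(p) if diag[j] <= tol]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    Rinv = np.linalg.solve(R, np.eye(p))
    cov = sigma2 * (Rinv @ Rinv.T)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return FitResult(tuple(names), beta, se, pvals, n, df, rss)


def build_design_matrix(
    data: pd.DataFrame,
    spec: ModelSpec,
    arm: str,
    exposure: pd.Series | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Assemble (y, X, column names, n_dropped) for one stratum.

    ``data`` carries the cohort row plus merged PC columns; ``exposure``
    is the per-person exposure value (dosage or standardized PGS), aligned
    on ``data``'s index.  Categorical covariates are reference-coded
    against their lexicographically first level; covariate columns that
    are constant within the stratum (e.g. a single medication type) are
    dropped.  Rows with any missing value are dropped and counted.
    """
    df = data.copy()
    if exposure is not None:
        df["_exposure"] = np.asarray(exposure, dtype=float)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    if exposure is not None:
        cols[spec.exposure_id or "exposure"] = df["_exposure"].to_numpy(float)
    if spec.adjust_baseline:
        cols["w0_kg"] = df["w0_kg"].to_numpy(float)
    cols["sex_F"] = (df["sex"] == "F").to_numpy(float)
    cols["age"] = df["age"].to_numpy(float)
    for pc in PC_COLS:
        if pc in df.columns:
            cols[pc] = df[pc].to_numpy(float)
    if arm == "glp1" and spec.include_medication_type:
        levels = sorted(df["medication_type"].dropna().unique())
        for lev in levels[1:]:  # reference = first level
            cols[f"med_{lev}"] = (df["medication_type"] == lev).to_numpy(float)
    if spec.adjust_t2d:
        cols["t2d"] = df["t2d"].to_numpy(float)
    if spec.interaction_baseline_x_exposure:
        if exposure is None:
            raise ValueError("interaction model needs an exposure")
        cols["w0_x_exposure"] = cols["w0_kg"] * cols[spec.exposure_id or "exposure"]
    for extra in spec.extra_covariates:
        if extra not in df.columns:
            raise ValueError(f"extra covariate {extra!r} not in data")
        vals = df[extra]
        if vals.dtype == object or isinstance(vals.dtype, pd.CategoricalDtype):
            for lev in sorted(vals.dropna().unique())[1:]:
                cols[f"{extra}_{lev}"] = (vals == lev).to_numpy(float)
        else:
            cols[extra] = vals.to_numpy(float)

    yname = "pct_change" if spec.outcome == "pct_change" else "mw1_kg"
    y = df[yname].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    complete = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    n_dropped = int((~complete).sum())
    y, X = y[complete], X[complete]
    # prune within-stratum constant covariates (never intercept/exposure)
    protect = {"intercept", spec.exposure_id or "exposure"}
    keep = [
        j for j, nm in enumerate(names)
        if nm in protect or (X[:, j].size and X[:, j].std() > 0)
    ]
    X = X[:, keep]
    names = [names[j] for j in keep]
    return y, X, names, n_dropped


def _exposure_values(
    sub: pd.DataFrame, genetics_df: pd.DataFrame, exposure_id: str, standardize: bool
) -> pd.Series:
    vals = sub["person_id"].map(genetics_df.set_index("person_id")[exposure_id])
    if standardize:
        vals = gx.standardize_pgs(vals)
    return vals


def run_stratified(
    cohort: pd.DataFrame,
    persons: pd.DataFrame,
    genetics_df: pd.DataFrame,
    arm: str,
    spec: ModelSpec = ModelSpec(),
    exposures: Iterable[str] | None = None,
    *,
    min_stratum_n: int = 30,
    min_carriers: int = 5,
    mac_threshold: int = 10,
    rare_excluded: Iterable[str] = (),
) -> tuple[pd.DataFrame, list[dict]]:
    """Fit one model per eligible stratum × exposure.

    Returns a tidy fits table (exposure_id, stratum, study_id, ancestry,
    beta, se, p, n, df_resid — beta for the exposure term) and a skip log
    for strata or exposures failing the eligibility rules.
    """
    if exposures is None:
        exposures = gx.tested_exposures(arm, rare_excluded)
    registry = {e.exposure_id: e for e in gx.REGISTRY}
    gidx = genetics_df.set_index("person_id")
    pcs = persons.set_index("person_id")[[c for c in PC_COLS if c in persons.columns]]
    rows: list[dict] = []
    skips: list[dict] = []
    for stratum, sub in cohort.groupby("stratum", sort=True):
        if len(sub) < min_stratum_n:
            skips.append({"stratum": stratum, "exposure_id": None, "reason": f"stratum n={len(sub)} < {min_stratum_n}"})
            continue
        sub = sub.merge(pcs, left_on="person_id", right_index=True, how="left")
        for exp_id in exposures:
            entry = registry.get(exp_id)
            if entry is None:
                raise KeyError(f"exposure {exp_id!r} not in registry")
            vals = sub["person_id"].map(gidx[exp_id])
            if entry.kind == "snp":
                elig = gx.mac_filter({exp_id: vals.to_numpy()}, mac_threshold, stratum)[0]
                carriers = int((vals.to_numpy() >= 1).sum())
                if not elig.eligible or carriers < min_carriers:
                    skips.append({
                        "stratum": stratum, "exposure_id": exp_id,
                        "reason": f"MAC={elig.minor_allele_count} (threshold {mac_threshold}), carriers={carriers}",
                    })
                    continue
                evals = vals.astype(float)
            else:
                try:
                    evals = gx.standardize_pgs(vals)
                except ValueError as err:
                    skips.append({"stratum": stratum, "exposure_id": exp_id, "reason": str(err)})
                    continue
            espec = ModelSpec(**{**spec.__dict__, "exposure_id": exp_id})
            y, X, names, _ = build_design_matrix(sub, espec, arm, exposure=evals)
            try:
                fit = fit_ols(y, X, names)
            except ValueError as err:
                skips.append({"stratum": stratum, "exposure_id": exp_id, "reason": str(err)})
                continue
            beta, se, p = fit.term(exp_id)
            rows.append({
                "exposure_id": exp_id,
                "stratum": stratum,
                "study_id": sub["study_id"].iloc[0],
                "ancestry": sub["ancestry"].iloc[0],
                "beta": beta, "se": se, "p": p,
                "n": fit.n, "df_resid": fit.df_resid,
            })
    fits = pd.DataFrame(rows, columns=["exposure_id", "stratum", "study_id", "ancestry", "beta", "se", "p", "n", "df_resid"])
    return fits, skips


def run_ancestry_contrast(
    cohort: pd.DataFrame,
    arm: str,
    *,
    min_stratum_n: int = 30,
) -> tuple[pd.DataFrame, list[dict]]:
    """Ancestry-difference model within multiancestry studies.

    Per study containing at least two ancestry groups (EUR, the reference,
    among them), regresses percentage weight change on ancestry indicator
    variables adjusted for sex, age and baseline weight (plus medication
    type for GLP1-RA).  Genetic PCs are omitted here: within-study ancestry
    labels are themselves functions of the PCs.  Returns per-study
    indicator fits ready for meta-analysis, plus a skip log.
    """
    rows: list[dict] = []
    skips: list[dict] = []
    for study, sub in cohort.groupby("study_id", sort=True):
        ancestries = sorted(sub["ancestry"].unique())
        if len(ancestries) < 2:
            skips.append({"study_id": study, "reason": "single-ancestry study"})
            continue
        if "EUR" not in ancestries:
            skips.append({"study_id": study, "reason": "no EUR reference group"})
            continue
        counts = sub["ancestry"].value_counts()
        keep_anc = [a for a in ancestries if counts[a] >= min_stratum_n]
        if "EUR" not in keep_anc or len(keep_anc) < 2:
            skips.append({"study_id": study, "reason": "too few adequately sized ancestry groups"})
            continue
        sub = sub[sub["ancestry"].isin(keep_anc)]
        cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
        anc_terms = [a for a in keep_anc if a != "EUR"]
        for a in anc_terms:
            cols[f"anc_{a}"] = (sub["ancestry"] == a).to_numpy(float)
        cols["w0_kg"] = sub["w0_kg"].to_numpy(float)
        cols["sex_F"] = (sub["sex"] == "F").to_numpy(float)
        cols["age"] = sub["age"].to_numpy(float)
        if arm == "glp1":
            for lev in sorted(sub["medication_type"].dropna().unique())[1:]:
                cols[f"med_{lev}"] = (sub["medication_type"] == lev).to_numpy(float)
        X = np.column_stack(list(cols.values()))
        names = list(cols.keys())
        keep = [j for j, nm in enumerate(names) if nm == "intercept" or X[:, j].std() > 0]
        fit = fit_ols(sub["pct_change"].to_numpy(float), X[:, keep], [names[j] for j in keep])
        for a in anc_terms:
            nm = f"anc_{a}"
            if nm not in fit.names:
                continue
            beta, se, p = fit.term(nm)
            rows.append({"study_id": study, "ancestry": a, "beta": beta, "se": se, "p": p, "n": fit.n})
    return pd.DataFrame(rows, columns=["study_id", "ancestry", "beta", "se", "p", "n"]), skips


def run_covariate_model(
    cohort: pd.DataFrame,
    persons: pd.DataFrame,
    arm: str,
    *,
    min_stratum_n: int = 30,
) -> pd.DataFrame:
    """Demographic-effects model: no genetic exposure term.

    Fits, per stratum, percentage weight change on baseline weight, sex,
    age, 20 PCs (and medication type for GLP1-RA), and returns one row
    per stratum × term for the three reported demographic terms
    (``w0_kg``, ``sex_F``, ``age``), ready for meta-analysis.
    """
    pcs = persons.set_index("person_id")[[c for c in PC_COLS if c in persons.columns]]
    spec = ModelSpec()
    rows = []
    for stratum, sub in cohort.groupby("stratum", sort=True):
        if len(sub) < min_stratum_n:
            continue
        sub = sub.merge(pcs, left_on="person_id", right_index=True, how="left")
        y, X, names, _ = build_design_matrix(sub, spec, arm, exposure=None)
        try:
            fit = fit_ols(y, X, names)
        except ValueError:
            continue
        for term in ("w0_kg", "sex_F", "age"):
            if term not in fit.names:
                continue
            beta, se, p = fit.term(term)
            rows.append({
                "exposure_id": term, "stratum": stratum,
                "study_id": sub["study_id"].iloc[0], "ancestry": sub["ancestry"].iloc[0],
                "beta": beta, "se": se, "p": p, "n": fit.n, "df_resid": fit.df_resid,
            })
    return pd.DataFrame(rows, columns=["exposure_id", "stratum", "study_id", "ancestry", "beta", "se", "p", "n", "df_resid"])


#: Names of the supported sensitivity analyses.
SENSITIVITY_VARIANTS = (
    "min_weight_outcome",
    "bs_12m_followup",
    "bs_baseline_30d",
    "t2d_adjusted",
    "sema_lira_only",
    "rygb_strata",
    "sg_strata",
    "post_weight_interaction",
    "no_baseline",
)


def run_sensitivity_suite(
    tables: Mapping[str, pd.DataFrame],
    arm: str,
    variants: Iterable[str] | None = None,
    exposures: Iterable[str] | None = None,
    options: CohortOptions | None = None,
    **stratified_kw,
) -> dict[str, pd.DataFrame]:
    """Re-run phenotyping and/or association under each sensitivity variant."""
    base_opt = options or CohortOptions()
    if variants is None:
        variants = [
            v for v in SENSITIVITY_VARIANTS
            if not (arm == "glp1" and v.startswith(("bs_", "rygb", "sg")))
            and not (arm == "bs" and v == "sema_lira_only")
        ]
    persons, genetics_df = tables["persons"], tables["genetics"]
    out: dict[str, pd.DataFrame] = {}
    base_cohort, _ = build_cohort(tables, arm, base_opt)
    for variant in variants:
        if variant not in SENSITIVITY_VARIANTS:
            raise ValueError(f"unknown sensitivity variant: {variant!r}")
        cohort, spec = base_cohort, ModelSpec()
        if variant == "min_weight_outcome":
            opt = CohortOptions(**{**base_opt.__dict__, "aggregate": "min"})
            cohort, _ = build_cohort(tables, arm, opt)
        elif variant == "bs_12m_followup":
            opt = CohortOptions(**{**base_opt.__dict__, "bs_followup_window": (180, 364)})
            cohort, _ = build_cohort(tables, arm, opt)
        elif variant == "bs_baseline_30d":
            opt = CohortOptions(**{**base_opt.__dict__, "min_days_pre_op": 30})
            cohort, _ = build_cohort(tables, arm, opt)
        elif variant == "t2d_adjusted":
            spec = ModelSpec(adjust_t2d=True)
        elif variant == "sema_lira_only":
            cohort = base_cohort[base_cohort["medication_type"].isin(SEMA_LIRA_DRUGS)]
            spec = ModelSpec(subgroup="semaglutide_liraglutide")
        elif variant == "rygb_strata":
            cohort = base_cohort[base_cohort["procedure_type"] == "RYGB"]
            spec = ModelSpec(subgroup="rygb")
        elif variant == "sg_strata":
            cohort = base_cohort[base_cohort["procedure_type"] == "SG"]
            spec = ModelSpec(subgroup="sg")
        elif variant == "post_weight_interaction":
            spec = ModelSpec(outcome="post_weight", interaction_baseline_x_exposure=True)
        elif variant == "no_baseline":
            spec = ModelSpec(adjust_baseline=False)
        fits, _ = run_stratified(cohort, persons, genetics_df, arm, spec, exposures, **stratified_kw)
        out[variant] = fits
    return out


def collider_type1_error(
    n_per_rep: int = 2000,
    n_reps: int = 1000,
    *,
    snp_effect_kg: float = 3.0,
    error_sd_kg: float = 3.0,
    maf: float = 0.3,
    mean_weight_kg: float = 95.0,
    weight_sd_kg: float = 10.0,
    change_mean_pct: float = -4.0,
    change_sd_pct: float = 5.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical type-I error of baseline-adjusted vs unadjusted models.

    A variant shifts *true* baseline weight by ``snp_effect_kg`` per
    allele but has no effect on the true percentage weight change.  Both
    baseline and follow-up weights are observed with independent
    measurement error.  Each replicate regresses observed percentage
    change on the dosage with and without adjusting for the *measured*
    baseline; returned rates are the fractions of replicates with p < α
    for the dosage term.  Under the null the unadjusted rate should sit
    near α while the baseline-adjusted rate is inflated.
    """
    rng = np.random.default_rng(seed)
    hits_adj = 0
    hits_unadj = 0
    for _ in range(n_reps):
        g = rng.binomial(2, maf, n_per_rep).astype(float)
        w0_true = mean_weight_kg + snp_effect_kg * g + rng.normal(0, weight_sd_kg, n_per_rep)
        pct_true = rng.normal(change_mean_pct, change_sd_pct, n_per_rep)
        w1_true = w0_true * (1 + pct_true / 100.0)
        w0_obs = w0_true + rng.normal(0, error_sd_kg, n_per_rep)
        w1_obs = w1_true + rng.normal(0, error_sd_kg, n_per_rep)
        pct_obs = (w1_obs - w0_obs) / w0_obs * 100.0
        ones = np.ones(n_per_rep)
        fit_a = fit_ols(pct_obs, np.column_stack([ones, g, w0_obs]), ["intercept", "g", "w0"])
        fit_u = fit_ols(pct_obs, np.column_stack([ones, g]), ["intercept", "g"])
        hits_adj += fit_a.term("g")[2] < alpha
        hits_unadj += fit_u.term("g")[2] < alpha
    return {
        "adjusted_rate": hits_adj / n_reps,
        "unadjusted_rate": hits_unadj / n_reps,
        "n_reps": n_reps,
        "n_per_rep": n_per_rep,
        "alpha": alpha,
    }
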