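"""Fixed-effect meta-analysis, heterogeneity statistics and power.

Stratum-level regression estimates are pooled by inverse-variance
weighting under a common-effect assumption: with weights w_i = 1/se_i²,

    beta_meta = Σ w_i·beta_i / Σ w_i,    se_meta = 1/sqrt(Σ w_i).

Heterogeneity is summarized by Cochran's Q = Σ w_i (beta_i − beta_meta)²
on k−1 degrees of freedom and I² = max(0, (Q − df)/Q) × 100%.

Two power calculations are provided: the exact noncentral-t power of the
two-sided test of a single regression coefficient (for PGS effects on a
standardized exposure), and the noncentral chi-squared power for a
biallelic variant via the noncentrality parameter 2 f (1−f) n β².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MetaResult",
    "fixed_effect_meta",
    "meta_analyze_fits",
    "i_squared",
    "cochran_q_pvalue",
    "bonferroni_threshold",
    "power_pgs_ttest",
    "power_snp_ncp",
]


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effect estimate over k strata."""

    exposure_id: str
    scope: str
    beta: float
    se: float
    p: float
    k: int
    q: float
    df: int
    i2: float
    n: int = 0


def fixed_effect_meta(
    betas: Sequence[float],
    ses: Sequence[float],
    *,
    exposure_id: str = "",
    scope: str = "multiancestry",
    n_total: int = 0,
) -> MetaResult:
    """Pool estimates by fixed-effect inverse-variance weighting.

    The pooled p-value is two-sided from the normal approximation
    (standard for inverse-variance pooling).  Raises on empty input or a
    non-positive standard error.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("fixed_effect_meta requires at least one estimate")
    if b.shape != s.shape:
        raise ValueError("betas and ses must have equal length")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("all standard errors must be finite and > 0")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (b - beta) ** 2))
    k = int(b.size)
    df = k - 1
    return MetaResult(exposure_id, scope, beta, se, p, k, q, df, i_squared(q, df), n_total)


def meta_analyze_fits(fits, *, ancestry_specific: bool = True):
    """Pool a tidy stratum-level fits table per exposure.

    The multiancestry pool combines every stratum of an exposure in a
    single pass; ancestry-specific pools combine the strata sharing an
    ancestry label across studies.  Returns a list of
    :class:`MetaResult`.
    """
    results: list[MetaResult] = []
    for exp_id, grp in fits.groupby("exposure_id", sort=True):
        results.append(
            fixed_effect_meta(
                grp["beta"], grp["se"], exposure_id=exp_id, scope="multiancestry",
                n_total=int(grp["n"].sum()),
            )
        )
        if ancestry_specific:
            for anc, agrp in grp.groupby("ancestry", sort=True):
                results.append(
                    fixed_effect_meta(
                        agrp["beta"], agrp["se"], exposure_id=exp_id, scope=anc,
                        n_total=int(agrp["n"].sum()),
                    )
                )
    return results


def i_squared(q: float, df: float) -> float:
    """I² heterogeneity percentage: (Q − df)/Q × 100, clipped to [0, 100].

    Defined as 0 when Q = 0 (no dispersion) or Q ≤ df.
    """
    if q < 0 or df < 0:
        raise ValueError("q and df must be non-negative")
    if q == 0 or q <= df:
        return 0.0
    return (q - df) / q * 100.0


def cochran_q_pvalue(q: float, df: int) -> float:
    """Upper-tail chi-squared probability of Cochran's Q on df = k−1."""
    if df < 1:
        raise ValueError("Cochran's Q test requires df >= 1 (at least two strata)")
    if q < 0:
        raise ValueError("q must be non-negative")
    return float(stats.chi2.sf(q, df))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def power_pgs_ttest(
    effect_beta: float,
    sd_y: float,
    n: int,
    k_predictors: int,
    alpha: float = 0.05,
    r2: float | None = None,
) -> float:
    """Power of the two-sided t-test for one regression coefficient.

    The exposure is assumed standardized (s.d. 1), so the coefficient's
    noncentrality is (effect_beta / sd_y)·sqrt(n) with
    df = n − k_predictors − 1.  ``r2`` (an adjusted coefficient of
    determination some power packages accept) has no role in this
    noncentral-t formulation and is accepted for interface compatibility
    only.
    """
    del r2
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sd_y <= 0:
        raise ValueError("sd_y must be > 0")
    if n <= k_predictors + 1:
        raise ValueError("need n > k_predictors + 1")
    df = n - k_predictors - 1
    ncp = (effect_beta / sd_y) * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def power_snp_ncp(
    effect_beta: float,
    maf: float,
    n: int,
    alpha: float = 0.05,
    sd_y: float | None = None,
) -> tuple[float, float]:
    """Noncentrality parameter and power for a biallelic-variant test.

    NCP = 2·f·(1−f)·n·β² with β on a unit-variance outcome scale; pass
    ``sd_y`` to rescale a raw-unit β (β/sd_y is used instead).  Power is
    the upper-tail mass of a noncentral chi-squared(1, NCP) beyond the
    central level-α quantile.  Returns ``(ncp, power)``.
    """
    if not 0 <= maf <= 1:
        raise ValueError("maf must be in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    beta = effect_beta if sd_y is None else effect_beta / sd_y
    ncp = 2.0 * maf * (1.0 - maf) * n * beta**2
    crit = stats.chi2.ppf(1 - alpha, 1)
    power = float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(alpha)
    return float(ncp), power
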