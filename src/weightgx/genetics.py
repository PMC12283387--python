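"""Genetic-exposure registry, eligibility filtering and PGS handling.

The candidate-gene panel is fixed: 15 SNPs (10 in *GLP1R*, 2 in *PCSK1*,
1 in *APOE*, 2 bariatric-surgery replication variants) plus polygenic
scores for BMI and T2D.  SNPs enter an analysis stratum only if their
minor allele count in that stratum clears a threshold; polygenic scores
are always eligible and are analyzed in within-group standard-deviation
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticExposure",
    "StratumEligibility",
    "REGISTRY",
    "DEFAULT_BS_PANEL",
    "load_registry",
    "tested_exposures",
    "standardize_pgs",
    "mac_filter",
    "validate_pgs_association",
    "dosages_from_vcf",
    "registry_to_json",
]


@dataclass(frozen=True)
class GeneticExposure:
    """One entry of the candidate panel.

    ``kind`` is ``"snp"`` or ``"pgs"``; ``applicability`` names the
    treatment arms (``"glp1"``, ``"bs"``) the exposure is tested in.
    """

    exposure_id: str
    kind: str
    gene: str | None
    category: str
    applicability: frozenset[str] = field(default_factory=lambda: frozenset({"glp1", "bs"}))


def _snp(rsid: str, gene: str | None, category: str, arms: Iterable[str] = ("glp1", "bs")) -> GeneticExposure:
    return GeneticExposure(rsid, "snp", gene, category, frozenset(arms))


#: The immutable exposure registry: 15 SNPs + 2 polygenic scores.
REGISTRY: tuple[GeneticExposure, ...] = (
    # Functionally characterized GLP1R variants (gain/loss of function).
    _snp("rs10305492", "GLP1R", "GLP1R_functional"),
    _snp("rs146868158", "GLP1R", "GLP1R_functional"),
    _snp("rs6923761", "GLP1R", "GLP1R_functional"),
    # Common GLP1R missense variants (MAF > 1% in >=1 continental group).
    _snp("rs1042044", "GLP1R", "GLP1R_missense"),
    _snp("rs10305420", "GLP1R", "GLP1R_missense"),
    _snp("rs3765467", "GLP1R", "GLP1R_missense"),
    _snp("rs10305421", "GLP1R", "GLP1R_missense"),
    _snp("rs2295006", "GLP1R", "GLP1R_missense"),
    _snp("rs10305510", "GLP1R", "GLP1R_missense"),
    _snp("rs201672448", "GLP1R", "GLP1R_missense"),
    # PCSK1 missense variants associated with BMI variation.
    _snp("rs6232", "PCSK1", "PCSK1_missense"),
    _snp("rs6235", "PCSK1", "PCSK1_missense"),
    # APOE lead variant for BMI change over time.
    _snp("rs429358", "APOE", "APOE_bmi_change"),
    # Replication variants for excess-BMI-loss after bariatric surgery.
    _snp("rs728996", None, "BS_replication", arms=("bs",)),
    _snp("rs17702901", None, "BS_replication", arms=("bs",)),
    # Polygenic scores, always analyzed per within-group s.d.
    GeneticExposure("PGS_BMI", "pgs", None, "PGS_BMI"),
    GeneticExposure("PGS_T2D", "pgs", None, "PGS_T2D"),
)

_REGISTRY_IDS = frozenset(e.exposure_id for e in REGISTRY)

#: Default bariatric-surgery exposure panel (the two PGS, the APOE change
#: variant and the two surgery replication variants): five exposures.
DEFAULT_BS_PANEL: frozenset[str] = frozenset(
    {"PGS_BMI", "PGS_T2D", "rs429358", "rs728996", "rs17702901"}
)


def load_registry() -> list[GeneticExposure]:
    """Return the fixed exposure registry (15 SNPs + 2 PGS)."""
    return list(REGISTRY)


def registry_to_json() -> list[dict]:
    """Registry as JSON-serializable records."""
    return [
        {
            "exposure_id": e.exposure_id,
            "kind": e.kind,
            "gene": e.gene,
            "category": e.category,
            "applicability": sorted(e.applicability),
        }
        for e in REGISTRY
    ]


def tested_exposures(
    arm: str,
    rare_excluded: Iterable[str] = (),
    *,
    bs_full_panel: bool = False,
) -> list[str]:
    """Exposure ids actually tested in an arm after rarity exclusions.

    For the GLP1-RA arm this is every arm-applicable SNP not excluded as
    too rare, plus both PGS.  For the bariatric-surgery arm the default
    panel is restricted to :data:`DEFAULT_BS_PANEL` (five exposures);
    ``bs_full_panel=True`` keeps every bs-applicable registry entry.

    Raises ``KeyError`` for an exclusion id not present in the registry.
    """
    if arm not in {"glp1", "bs"}:
        raise ValueError(f"unknown arm: {arm!r}")
    rare = set(rare_excluded)
    unknown = rare - _REGISTRY_IDS
    if unknown:
        raise KeyError(f"rare_excluded ids not in registry: {sorted(unknown)}")
    out = []
    for e in REGISTRY:
        if arm not in e.applicability:
            continue
        if e.kind == "snp" and e.exposure_id in rare:
            continue
        if arm == "bs" and not bs_full_panel and e.exposure_id not in DEFAULT_BS_PANEL:
            continue
        out.append(e.exposure_id)
    return out


def standardize_pgs(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray | None = None,
) -> pd.Series:
    """Standardize PGS values to mean 0, s.d. 1 (ddof=1) within groups.

    ``groups=None`` standardizes globally.  A group with fewer than two
    distinct values has no scale and raises ``ValueError``.
    """
    s = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    if groups is None:
        grouper = pd.Series(0, index=s.index)
    else:
        grouper = pd.Series(np.asarray(groups), index=s.index)

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("cannot standardize a group with constant PGS values")
        return (x - x.mean()) / sd

    return s.groupby(grouper, sort=False).transform(_z)


@dataclass(frozen=True)
class StratumEligibility:
    stratum: str
    exposure_id: str
    minor_allele_count: int
    eligible: bool


def mac_filter(
    dosages: Mapping[str, Sequence[float]] | pd.DataFrame,
    threshold: int = 10,
    stratum: str = "",
) -> list[StratumEligibility]:
    """Minor-allele-count eligibility of SNPs within one stratum.

    ``dosages`` maps exposure id -> per-person dosages in {0, 1, 2}
    (a DataFrame column per SNP works).  MAC folds the allele label:
    ``min(sum(d), 2n - sum(d))``, so it is invariant to swapping which
    allele is counted.
    """
    if isinstance(dosages, pd.DataFrame):
        dosages = {c: dosages[c].to_numpy() for c in dosages.columns}
    out = []
    for rsid, dos in dosages.items():
        d = np.asarray(dos, dtype=float)
        d = d[~np.isnan(d)]
        total = float(d.sum())
        mac = int(round(min(total, 2 * len(d) - total)))
        out.append(StratumEligibility(stratum, rsid, mac, mac >= threshold))
    return out


def validate_pgs_association(
    persons: pd.DataFrame,
    pgs_col: str,
    trait_col: str,
    *,
    min_stratum_n: int = 50,
) -> pd.DataFrame:
    """Check that a PGS predicts its target trait within each ancestry.

    Fits, per ancestry, a linear model of the trait on the within-ancestry
    standardized PGS adjusted for sex, age and the 20 genetic PCs.  Binary
    traits (e.g. T2D status) go through the same linear engine as a linear
    probability model.  Ancestry groups below ``min_stratum_n`` are skipped.

    Returns a DataFrame with columns ancestry, beta, se, p, n.
    """
    from .association import fit_ols  # deferred: avoids an import cycle

    pc_cols = [f"pc{i}" for i in range(1, 21)]
    rows = []
    for anc, grp in persons.groupby("ancestry", sort=True):
        if len(grp) < min_stratum_n:
            continue
        z = standardize_pgs(grp[pgs_col])
        X = np.column_stack(
            [
                np.ones(len(grp)),
                z.to_numpy(),
                (grp["sex"] == "F").to_numpy(float),
                grp["age"].to_numpy(float),
                grp[pc_cols].to_numpy(float),
            ]
        )
        y = grp[trait_col].to_numpy(float)
        fit = fit_ols(y, X, ["intercept", pgs_col, "sex_F", "age", *pc_cols])
        i = 1  # the PGS column
        rows.append(
            {
                "ancestry": anc,
                "beta": fit.beta[i],
                "se": fit.se[i],
                "p": fit.p[i],
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows, columns=["ancestry", "beta", "se", "p", "n"])


def dosages_from_vcf(vcf_path: str, rsids: Iterable[str] | None = None) -> pd.DataFrame:
    """Read SNP dosages (0/1/2 alt-allele counts) for registry variants from a VCF.

    Matches records by ID against the registry rsIDs (or an explicit
    ``rsids`` subset).  Missing genotypes become NaN.  Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF  # optional dependency

    wanted = set(rsids) if rsids is not None else {e.exposure_id for e in REGISTRY if e.kind == "snp"}
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for rec in vcf:
        if rec.ID in wanted:
            gts = np.asarray(rec.gt_types, dtype=float)  # 0=hom-ref,1=het,2=unknown,3=hom-alt
            dos = np.where(gts == 3, 2.0, gts)
            dos[gts == 2] = np.nan
            cols[rec.ID] = dos
    return pd.DataFrame(cols, index=pd.Index(samples, name="person_id"))
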