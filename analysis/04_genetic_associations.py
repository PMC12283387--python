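#!/usr/bin/env python
"""Genetic exposures vs weight change: stratified fits and meta-analysis.

Fits the primary model for every tested exposure (13 for GLP1-RA after
rarity exclusion, the 5-exposure surgical panel for BS) in every
eligible study-by-ancestry stratum, pools by fixed-effect inverse-
variance meta-analysis (ancestry-specific and multiancestry), flags
Bonferroni significance and exports forest-plot data.
"""

from pathlib import Path

import pandas as pd

from weightgx import association, metapower, reporting

ROOT = Path(__file__).resolve().parents[1]
RARE_GLP1 = ["rs2295006", "rs201672448"]


def main() -> None:
    persons = pd.read_csv(ROOT / "results" / "data" / "persons.tsv", sep="\t")
    genetics = pd.read_csv(ROOT / "results" / "data" / "genetics.tsv", sep="\t")
    for arm in ("glp1", "bs"):
        cohort = pd.read_csv(ROOT / "results" / f"cohort_{arm}.tsv", sep="\t")
        rare = RARE_GLP1 if arm == "glp1" else []
        fits, skips = association.run_stratified(cohort, persons, genetics, arm, rare_excluded=rare)
        fits.to_csv(ROOT / "results" / f"fits_{arm}.tsv", sep="\t", index=False)
        m = fits["exposure_id"].nunique()
        thr = metapower.bonferroni_threshold(0.05, m)
        results = metapower.meta_analyze_fits(fits)
        meta_df = pd.DataFrame(
            [{"exposure_id": r.exposure_id, "scope": r.scope, "beta": r.beta, "se": r.se,
              "p": r.p, "k": r.k, "q": r.q, "df": r.df, "i2": r.i2, "n": r.n,
              "significant_bonferroni": r.p < thr} for r in results]
        )
        meta_df.to_csv(ROOT / "results" / f"meta_{arm}.tsv", sep="\t", index=False)
        pooled = metapower.meta_analyze_fits(fits, ancestry_specific=False)
        forest = reporting.forest_data(pooled, fits, n_tests=m)
        forest.to_csv(ROOT / "results" / f"forest_{arm}.tsv", sep="\t", index=False)
        hits = meta_df[(meta_df["scope"] == "multiancestry") & meta_df["significant_bonferroni"]]
        print(f"{arm}: {m} exposures tested, Bonferroni threshold {thr:.4g}, "
              f"{len(skips)} stratum-level skips, significant: "
              f"{', '.join(hits['exposure_id']) if len(hits) else 'none'}")
        for _, r in meta_df[meta_df["scope"] == "multiancestry"].iterrows():
            print(f"   {r['exposure_id']:12s} beta={r['beta']:+.3f} (SE {r['se']:.3f}) "
                  f"p={r['p']:.3g} I2={r['i2']:.0f}%")


if __name__ == "__main__":
    main()
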