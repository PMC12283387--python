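#!/usr/bin/env python
"""Demographic predictors of weight change (multivariable model).

Per stratum, regresses percentage weight change on baseline weight, sex,
age, 20 PCs (and medication type for GLP1-RA) with no genetic exposure
term, then pools the baseline-weight, sex and age coefficients by
fixed-effect meta-analysis.  Writes results/demographic_effects.tsv.
"""

from pathlib import Path

import pandas as pd

from weightgx import association, metapower

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    persons = pd.read_csv(ROOT / "results" / "data" / "persons.tsv", sep="\t")
    rows = []
    for arm in ("glp1", "bs"):
        cohort = pd.read_csv(ROOT / "results" / f"cohort_{arm}.tsv", sep="\t")
        fits = association.run_covariate_model(cohort, persons, arm)
        for r in metapower.meta_analyze_fits(fits, ancestry_specific=False):
            rows.append({"arm": arm, "term": r.exposure_id, "beta": r.beta, "se": r.se,
                         "p": r.p, "k": r.k, "i2": r.i2})
            print(f"{arm:4s} {r.exposure_id:7s} beta={r.beta:+.3f} (SE {r.se:.3f}) "
                  f"p={r.p:.2e} I2={r.i2:.0f}%")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "demographic_effects.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
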