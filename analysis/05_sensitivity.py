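#!/usr/bin/env python
"""Sensitivity analyses: outcome definitions, covariates, subgroups, models.

Re-runs phenotyping/association under each variant (minimum-weight
outcome, 12-month BS follow-up, 30-day pre-operative baseline, T2D
adjustment, semaglutide/liraglutide subgroup, RYGB/SG strata,
post-weight interaction model, no-baseline model) and pools the
BMI-PGS effect for each, the quantity most scrutinized in the primary
analysis.
"""

from pathlib import Path

import pandas as pd

from weightgx import association, metapower

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data"
    tables = {p.stem: pd.read_csv(p, sep="\t") for p in data.glob("*.tsv")}
    rows = []
    for arm in ("glp1", "bs"):
        out = association.run_sensitivity_suite(tables, arm, exposures=["PGS_BMI", "PGS_T2D"])
        for variant, fits in out.items():
            if fits.empty:
                print(f"{arm} {variant}: no eligible strata")
                continue
            for r in metapower.meta_analyze_fits(fits, ancestry_specific=False):
                rows.append({"arm": arm, "variant": variant, "exposure_id": r.exposure_id,
                             "beta": r.beta, "se": r.se, "p": r.p, "k": r.k})
                if r.exposure_id == "PGS_BMI":
                    print(f"{arm:4s} {variant:24s} PGS_BMI beta={r.beta:+.3f} "
                          f"(SE {r.se:.3f}) p={r.p:.3g}")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "sensitivity.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
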