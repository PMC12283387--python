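#!/usr/bin/env python
"""Weight-change differences across ancestry groups (EUR as reference).

Within each multiancestry study, regresses percentage weight change on
ancestry indicators adjusted for sex, age, baseline weight (and
medication type for GLP1-RA), then meta-analyzes each indicator across
studies.  Writes results/ancestry_contrasts.tsv.
"""

from pathlib import Path

import pandas as pd

from weightgx import association, metapower

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for arm in ("glp1", "bs"):
        cohort = pd.read_csv(ROOT / "results" / f"cohort_{arm}.tsv", sep="\t")
        fits, skips = association.run_ancestry_contrast(cohort, arm)
        for skip in skips:
            print(f"{arm}: skipped {skip['study_id']} ({skip['reason']})")
        for anc, grp in fits.groupby("ancestry"):
            r = metapower.fixed_effect_meta(grp["beta"], grp["se"], exposure_id=anc, scope=arm)
            rows.append({"arm": arm, "ancestry": anc, "beta": r.beta, "se": r.se,
                         "p": r.p, "k": r.k, "i2": r.i2})
            print(f"{arm:4s} {anc} vs EUR: beta={r.beta:+.3f} (SE {r.se:.3f}) p={r.p:.3g}")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "ancestry_contrasts.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
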