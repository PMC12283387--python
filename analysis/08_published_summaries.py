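#!/usr/bin/env python
"""Weighted summaries of the transcribed published cohort table.

Recomputes the sample-size-weighted averages (proportion of women, mean
age, mean baseline weight) for both treatment arms from the shipped
per-stratum summary table and writes results/published_summaries.tsv.
"""

from pathlib import Path

import pandas as pd

from weightgx import reporting

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    t1 = reporting.load_published_table1()
    rows = []
    for arm, grp in t1.groupby("arm"):
        for col in ("prop_women_pct", "mean_weight_kg", "mean_age_years", "t2d_prev_pct"):
            res = reporting.weighted_summary(grp["n"], grp[col], col)
            rows.append({"arm": arm, **res})
            print(f"{arm:4s} {col:18s} weighted mean {res['weighted_value']:.2f} "
                  f"over n={res['total_n']}")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "published_summaries.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
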