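#!/usr/bin/env python
"""Phenotype the GLP1-RA and bariatric-surgery cohorts.

Applies the inclusion/exclusion cascade (12-month persistence, baseline
and follow-up weight windows, surgery-during-treatment exclusion) and
derives the percentage-weight-change outcome; writes cohort tables,
attrition logs and per-stratum summary tables under results/.
"""

import json
from pathlib import Path

import pandas as pd

from weightgx import phenotyping, reporting

ROOT = Path(__file__).resolve().parents[1]


def load_tables() -> dict[str, pd.DataFrame]:
    data = ROOT / "results" / "data"
    return {p.stem: pd.read_csv(p, sep="\t") for p in data.glob("*.tsv")}


def main() -> None:
    tables = load_tables()
    out = ROOT / "results"
    attritions = {}
    for arm in ("glp1", "bs"):
        cohort, attrition = phenotyping.build_cohort(tables, arm)
        attritions[arm] = attrition
        cohort.to_csv(out / f"cohort_{arm}.tsv", sep="\t", index=False)
        reporting.make_table1(cohort).to_csv(out / f"table1_{arm}.tsv", sep="\t", index=False)
        print(f"{arm}: {attrition['n_cohort']} of {attrition['n_input']} persons retained; "
              f"mean weight change {cohort['pct_change'].mean():.2f}% "
              f"(exclusions: {attrition['excluded']})")
    (out / "attrition.json").write_text(json.dumps(attritions, indent=2) + "\n")


if __name__ == "__main__":
    main()
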