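#!/usr/bin/env python
"""Generate the flagship synthetic multi-study biobank dataset.

Reads analysis/config.yaml (six studies, three ancestries, n = 20,000)
and writes the five longitudinal tables plus metadata under
results/data/.
"""

from pathlib import Path

import yaml

from weightgx import simulate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = simulate.config_from_dict(yaml.safe_load((ROOT / "analysis" / "config.yaml").read_text()))
    tables = simulate.simulate_study(cfg)
    out = ROOT / "results" / "data"
    simulate.write_tables(tables, out, seed=cfg.seed)
    print(f"simulated {len(tables['persons'])} persons across {len(cfg.studies)} studies -> {out}")
    print(f"  weights: {len(tables['weights'])} rows, drug records: {len(tables['drugs'])}, "
          f"procedures: {len(tables['procedures'])}")


if __name__ == "__main__":
    main()
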