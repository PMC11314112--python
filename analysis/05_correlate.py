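#!/usr/bin/env python
"""Rank the meteorological drivers of planting area and yield.

Builds the 3 x 4 Pearson correlation grid — accumulated temperature T,
precipitation P and sunshine hours h against planting area, yield, and
their annual differences — with two-sided p-values and significance stars,
and ranks drivers per target by |r|.  Outputs: results/corr_table.csv,
results/corr_ranking.json.
"""

import json
from pathlib import Path

from wheatscape.correlate import build_corr_table
from wheatscape.met import aggregate_seasons
from wheatscape.synth import SynthConfig, make_area_yield, make_met_daily

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main():
    cfg = SynthConfig(seed=SEED)
    season_met = aggregate_seasons(make_met_daily(cfg), cfg.met_seasons)
    area, yld, _ = make_area_yield(cfg, season_met)
    tab = build_corr_table(season_met, area, yld)
    RESULTS.mkdir(exist_ok=True)
    tab.table.to_csv(RESULTS / "corr_table.csv")
    (RESULTS / "corr_ranking.json").write_text(json.dumps(tab.ranking, indent=2))

    d = tab.to_dict()["cells"]
    print("factor      area          yield         d_area        d_yield")
    for f in ("T", "P", "h"):
        cells = [f"{d[f][t]['r']:+.3f}{d[f][t]['stars']:<2}"
                 for t in ("area", "yield", "d_area", "d_yield")]
        print(f"{f:<10} " + "  ".join(f"{c:<12}" for c in cells))
    print(f"driver ranking by |r|: area {' > '.join(tab.ranking['area'])}, "
          f"yield {' > '.join(tab.ranking['yield'])}")
    print(f"generator anomaly weights were T > P > h with signs (+, +, -)")


if __name__ == "__main__":
    main()
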