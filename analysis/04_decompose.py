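#!/usr/bin/env python
"""HP-filter decomposition of the annual area and yield series.

Splits each series into a smooth trend and a high-frequency climatic
component (lambda = 100, the annual-data convention), computes annual
differences, and runs the MK mutation test on the raw series.  Outputs:
results/decomp_area.csv, results/decomp_yield.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wheatscape.decomp import hp_filter
from wheatscape.met import aggregate_seasons
from wheatscape.mktrend import mk_series
from wheatscape.synth import SynthConfig, make_area_yield, make_met_daily

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0
LAM = 100.0


def main():
    cfg = SynthConfig(seed=SEED)
    season_met = aggregate_seasons(make_met_daily(cfg), cfg.met_seasons)
    area, yld, truth = make_area_yield(cfg, season_met)
    years = area.index.to_numpy()
    RESULTS.mkdir(exist_ok=True)

    for name, series, comps in (("area", area, truth.area_components),
                                ("yield", yld, truth.yield_components)):
        res = hp_filter(series.to_numpy(), lam=LAM)
        pd.DataFrame({
            "year": years, "value": res.series, "trend": res.trend,
            "climatic": res.climatic,
            "annual_diff": np.concatenate([[np.nan], res.annual_diff]),
        }).to_csv(RESULTS / f"decomp_{name}.csv", index=False)
        r = np.corrcoef(res.climatic, comps["climatic"])[0, 1]
        mk = mk_series(years, series.to_numpy())
        unit = "k ha" if name == "area" else "1e4 t"
        print(f"{name}: {series.iloc[0]:.0f} -> {series.iloc[-1]:.0f} {unit}, "
              f"MK Z={mk.Z:.2f}, peak annual difference "
              f"{res.annual_diff.max():+.1f} {unit} in "
              f"{years[1:][np.argmax(res.annual_diff)]}")
        print(f"  recovered climatic component correlates {r:.3f} "
              f"with the injected one (lambda={LAM:g})")


if __name__ == "__main__":
    main()
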