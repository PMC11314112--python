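import numpy as np
import pandas as pd
import pytest

from wheatscape.met import aggregate_seasons
from wheatscape.synth import SynthConfig, make_area_yield, make_met_daily

N_REPLICATES = 200


@pytest.fixture(scope="session")
def met_replicates():
    """Monte-Carlo replicates of the default climate + area/yield generator.

    200 independent seeds of the default study conditions (40 seasons,
    warming regime, injected change points, default anomaly weights),
    shared across tests that measure recovery rates.
    """
    reps = []
    for seed in range(N_REPLICATES):
        cfg = SynthConfig(seed=seed)
        season_met = aggregate_seasons(make_met_daily(cfg), cfg.met_seasons)
        area, yld, truth = make_area_yield(cfg, season_met)
        reps.append({"met": season_met, "area": area, "yield": yld, "truth": truth})
    return reps


@pytest.fixture()
def small_met_table():
    """Tiny deterministic two-station daily table spanning one window."""
    dates = pd.date_range("2013-09-01", "2014-06-30", freq="D")
    rows = []
    for station, tshift in (("A", 0.0), ("B", 2.0)):
        rows.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "station": station,
                    "tmax_c": 20.0 + tshift,
                    "tmin_c": 10.0 + tshift,
                    "precip_mm": 1.0,
                    "sunshine_h": 6.0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
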