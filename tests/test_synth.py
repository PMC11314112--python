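"""Ground-truth generator: determinism, conservation, and calibration."""

import numpy as np
import pandas as pd
import pytest

from wheatscape.extract import PhenologyWindows, curve_features
from wheatscape.met import aggregate_seasons
from wheatscape.synth import (
    SynthConfig,
    make_area_yield,
    make_cropland_mask,
    make_lai_cube,
    make_met_daily,
    reference_area_series,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_rows=0), dict(n_composites=4), dict(wheat_fraction=1.2),
         dict(noise_sd=-0.1)],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)


class TestLaiCube:
    def test_bit_identical_under_same_seed(self):
        cfg = SynthConfig(n_rows=10, n_cols=10, seed=9)
        c1, t1 = make_lai_cube(cfg, 2005)
        c2, t2 = make_lai_cube(cfg, 2005)
        assert np.array_equal(c1.data, c2.data)
        assert np.array_equal(t1, t2)
        c3, _ = make_lai_cube(SynthConfig(n_rows=10, n_cols=10, seed=10), 2005)
        assert not np.array_equal(c1.data, c3.data)

    def test_wheat_count_is_exact_fraction_of_cropland(self):
        cfg = SynthConfig(n_rows=10, n_cols=10, cropland_fraction=1.0,
                          wheat_fraction=0.5, seed=2)
        _, truth = make_lai_cube(cfg, 2010)
        assert truth.sum() == 50

    def test_wheat_subset_of_cropland_every_season(self):
        cfg = SynthConfig(n_rows=15, n_cols=15, seed=4)
        cropland = make_cropland_mask(cfg)
        for season in (2000, 2007, 2019):
            _, truth = make_lai_cube(cfg, season)
            assert np.all(cropland[truth == 1] == 1)

    def test_noiseless_wheat_pixel_has_required_features(self):
        cfg = SynthConfig(n_rows=12, n_cols=12, noise_sd=0.0, seed=1)
        cube, truth = make_lai_cube(cfg, 2003)
        w = PhenologyWindows()
        r, c = np.argwhere(truth == 1)[0]
        curve = cube.data[:, r, c]
        feats = curve_features(curve)
        assert feats.peak_value >= w.lai_max_threshold
        assert w.spring_peak[0] <= feats.peak_index <= w.spring_peak[1]
        # non-cropland pixels stay below the wheat threshold
        cropland = make_cropland_mask(cfg)
        rn, cn = np.argwhere(cropland == 0)[0]
        assert cube.data[:, rn, cn].max() < w.lai_max_threshold

    def test_lai_nonnegative_with_noise(self):
        cfg = SynthConfig(n_rows=8, n_cols=8, noise_sd=1.0, seed=3)
        cube, _ = make_lai_cube(cfg, 2001)
        assert (cube.data >= 0).all()


class TestMetDaily:
    def test_columns_and_determinism(self):
        cfg = SynthConfig(seed=5, met_seasons=(2014, 2015))
        met = make_met_daily(cfg)
        assert list(met.columns) == ["date", "station", "tmax_c", "tmin_c",
                                     "precip_mm", "sunshine_h"]
        assert met["station"].nunique() == 7
        met2 = make_met_daily(SynthConfig(seed=5, met_seasons=(2014, 2015)))
        pd.testing.assert_frame_equal(met, met2)

    def test_zero_trend_zero_noise_gives_identical_seasons(self):
        # consecutive non-leap windows so both spans cover identical doy grids
        cfg = SynthConfig(seed=0, met_seasons=(2014, 2015), met_trend=0.0,
                          temp_noise_sd=0.0, temp_season_sd=0.0,
                          station_noise_sd=0.0, change_points={})
        sm = aggregate_seasons(make_met_daily(cfg), cfg.met_seasons)
        assert sm["T"].iloc[0] == pytest.approx(sm["T"].iloc[1], rel=1e-12)

    def test_precipitation_disabled(self):
        cfg = SynthConfig(seed=1, met_seasons=(2014, 2015), precip_scale=0.0)
        met = make_met_daily(cfg)
        assert (met["precip_mm"] == 0).all()

    def test_seasonal_sums_near_calibration_targets(self):
        cfg = SynthConfig(seed=11)
        sm = aggregate_seasons(make_met_daily(cfg), cfg.met_seasons)
        assert sm["T"].mean() == pytest.approx(3310.71, rel=0.03)
        assert sm["P"].mean() == pytest.approx(379.0, rel=0.10)
        assert sm["h"].mean() == pytest.approx(1447.8, rel=0.05)

    def test_linear_trend_recovered_within_ten_percent(self):
        # linear-drift mode (no change points), slope averaged over seeds
        slopes = []
        for seed in range(5):
            cfg = SynthConfig(seed=seed, change_points={}, met_trend=116.91)
            sm = aggregate_seasons(make_met_daily(cfg), cfg.met_seasons)
            slopes.append(np.polyfit(sm["season"], sm["T"], 1)[0] * 10)
        assert np.mean(slopes) == pytest.approx(116.91, rel=0.10)

    def test_wet_days_have_less_sunshine(self):
        cfg = SynthConfig(seed=2, met_seasons=(2014, 2015))
        met = make_met_daily(cfg)
        wet = met["precip_mm"] > 0
        assert met.loc[wet, "sunshine_h"].mean() < met.loc[~wet, "sunshine_h"].mean()


class TestAreaYield:
    def test_components_conserve_exactly(self, met_replicates):
        rep = met_replicates[0]
        for comp in (rep["truth"].area_components, rep["truth"].yield_components):
            resid = comp["value"] - comp["trend"] - comp["climatic"] - comp["noise"]
            assert np.max(np.abs(resid)) == 0.0

    def test_zero_weights_zero_noise_equals_trend(self):
        cfg = SynthConfig(seed=0, area_weights=(0, 0, 0), area_noise_sd=0.0,
                          yield_weights=(0, 0, 0), yield_noise_sd=0.0,
                          change_points={})
        sm = aggregate_seasons(make_met_daily(cfg), cfg.met_seasons)
        area, yld, truth = make_area_yield(cfg, sm)
        assert np.allclose(area.to_numpy(), truth.area_components["trend"])
        assert np.allclose(yld.to_numpy(), truth.yield_components["trend"])

    def test_pure_temperature_weight_gives_perfect_correlation(self):
        cfg = SynthConfig(seed=0, yield_weights=(50.0, 0.0, 0.0),
                          yield_trend=(1000.0,), yield_noise_sd=0.0,
                          change_points={})
        sm = aggregate_seasons(make_met_daily(cfg), cfg.met_seasons)
        _, yld, _ = make_area_yield(cfg, sm)
        r = np.corrcoef(yld.to_numpy(), sm["T"].to_numpy())[0, 1]
        assert r == pytest.approx(1.0)

    def test_injected_shift_recorded_in_truth(self, met_replicates):
        truth = met_replicates[0]["truth"]
        assert truth.mutation_years.get("T") == 1997
        assert truth.mutation_years.get("P") == 2004

    def test_season_coverage_mismatch_rejected(self):
        cfg = SynthConfig(seed=0)
        bad = pd.DataFrame({"season": [1980, 1981], "T": [1.0, 2.0],
                            "P": [0.0, 0.0], "h": [5.0, 6.0]})
        with pytest.raises(ValueError):
            make_area_yield(cfg, bad)


def test_reference_area_matches_truth_masks():
    cfg = SynthConfig(n_rows=10, n_cols=10, seed=6, seasons=(2000, 2001))
    masks = {s: make_lai_cube(cfg, s)[1] for s in cfg.seasons}
    ref = reference_area_series(masks, pixel_area_ha=6.25)
    for s in cfg.seasons:
        assert ref.loc[s] == pytest.approx(masks[s].sum() * 6.25 / 1000.0)
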