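"""Phenology feature extraction, wheat classification, and frequency maps."""

import numpy as np
import pytest

from wheatscape.extract import (
    NODATA_MASK,
    LaiCube,
    PhenologyWindows,
    apply_cropland_mask,
    classify_cube,
    classify_pixel,
    curve_features,
    frequency_map,
    make_intervals,
    planting_area,
)
from wheatscape.synth import SynthConfig, make_cropland_mask, make_lai_cube, wheat_curve


class TestCurveFeatures:
    def test_triangular_curve_peak(self):
        curve = np.concatenate([np.linspace(0, 4, 5), np.linspace(4, 0, 5)[1:]])
        feats = curve_features(curve)
        assert feats.peak_index == 4

    def test_constant_curve_no_inflections_first_index_peak(self):
        feats = curve_features(np.full(10, 1.3))
        assert feats.peak_index == 0
        assert feats.inflection_indices.size == 0

    def test_wheat_curve_inflections_bracket_peak(self):
        u = np.linspace(0, 15, 16)
        feats = curve_features(wheat_curve(u))
        assert feats.inflection_indices.size >= 2
        assert feats.inflection_indices.min() < feats.peak_index
        assert feats.inflection_indices.max() > feats.peak_index
        # an inflection (green-up onset) sits in the default autumn window
        a0, a1 = PhenologyWindows().autumn_rise
        assert np.any((feats.inflection_indices >= a0) & (feats.inflection_indices <= a1))

    def test_interior_nodata_interpolated(self):
        curve = wheat_curve(np.linspace(0, 15, 16))
        gappy = curve.copy()
        gappy[7] = np.nan
        feats = curve_features(gappy)
        assert feats is not None
        assert feats.peak_index == curve_features(curve).peak_index

    def test_unusable_pixels_return_skip_marker(self):
        assert curve_features(np.full(16, np.nan)) is None
        edge = np.ones(16)
        edge[0] = np.nan
        assert curve_features(edge) is None
        assert curve_features(np.ones(4)) is None  # too few composites


class TestClassification:
    def test_noiseless_wheat_pixel_is_wheat(self):
        feats = curve_features(wheat_curve(np.linspace(0, 15, 16)))
        assert classify_pixel(feats, PhenologyWindows())

    def test_low_constant_pixel_fails_threshold(self):
        feats = curve_features(np.full(16, 0.4))
        assert not classify_pixel(feats, PhenologyWindows())

    def test_noiseless_cube_recovers_truth_exactly(self):
        cfg = SynthConfig(n_rows=30, n_cols=30, noise_sd=0.0, seed=3)
        cube, truth = make_lai_cube(cfg, 2010)
        mask = classify_cube(cube, PhenologyWindows())
        mask = apply_cropland_mask(mask, make_cropland_mask(cfg))
        assert np.array_equal(mask, truth)

    def test_noisy_cube_accuracy(self):
        cfg = SynthConfig(n_rows=50, n_cols=50, wheat_fraction=0.4, noise_sd=0.15, seed=7)
        cube, truth = make_lai_cube(cfg, 2010)
        mask = apply_cropland_mask(classify_cube(cube, PhenologyWindows()),
                                   make_cropland_mask(cfg))
        acc = np.mean(mask == truth)
        assert acc >= 0.95

    def test_raising_threshold_never_adds_wheat(self):
        cfg = SynthConfig(n_rows=20, n_cols=20, noise_sd=0.3, seed=5)
        cube, _ = make_lai_cube(cfg, 2010)
        counts = []
        for thr in (1.0, 2.0, 3.0, 4.0):
            w = PhenologyWindows(lai_max_threshold=thr)
            counts.append(int((classify_cube(cube, w) == 1).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_misordered_windows_rejected(self):
        with pytest.raises(ValueError):
            PhenologyWindows(autumn_rise=(5, 2))
        with pytest.raises(ValueError):
            PhenologyWindows(autumn_rise=(1, 12), spring_peak=(9, 13))


class TestCroplandMask:
    def test_all_ones_is_identity_and_idempotent(self, rng):
        mask = rng.integers(0, 2, (10, 10)).astype(np.uint8)
        ones = np.ones((10, 10), dtype=np.uint8)
        out = apply_cropland_mask(mask, ones)
        assert np.array_equal(out, mask)
        zeros = np.zeros_like(ones)
        assert np.array_equal(apply_cropland_mask(mask, zeros) == 1,
                              np.zeros_like(mask, dtype=bool))

    def test_checkerboard_count_matches_pixel_loop(self, rng):
        mask = rng.integers(0, 2, (8, 8)).astype(np.uint8)
        crop = np.indices((8, 8)).sum(axis=0) % 2
        out = apply_cropland_mask(mask, crop.astype(np.uint8))
        expected = sum(
            1 for r in range(8) for c in range(8) if mask[r, c] == 1 and crop[r, c] == 1
        )
        assert int((out == 1).sum()) == expected
        # idempotence
        assert np.array_equal(apply_cropland_mask(out, crop.astype(np.uint8)), out)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            apply_cropland_mask(np.zeros((3, 3)), np.zeros((4, 4)))


class TestAreaAndFrequency:
    @pytest.mark.parametrize(
        "n_pixels, pixel_ha, expected_kha",
        [(0, 6.25, 0.0), (160, 6.25, 1.0), (100 * 100, 6.25, 62.5)],
    )
    def test_planting_area_arithmetic(self, n_pixels, pixel_ha, expected_kha):
        mask = np.zeros(10000, dtype=np.uint8)
        mask[:n_pixels] = 1
        assert planting_area(mask.reshape(100, 100), pixel_ha) == pytest.approx(expected_kha)

    def test_equal_interval_partition(self):
        ivs = make_intervals(range(2000, 2020), 4)
        assert ivs == [(2000, 2004), (2005, 2009), (2010, 2014), (2015, 2019)]
        with pytest.raises(ValueError):
            make_intervals(range(2000, 2019), 4)

    def test_frequency_counts_and_change(self, rng):
        seasons = list(range(2000, 2010))
        masks = {s: rng.integers(0, 2, (6, 6)).astype(np.uint8) for s in seasons}
        ivs = [(2000, 2004), (2005, 2009)]
        freq, change = frequency_map(masks, ivs)
        # brute-force recount
        for iv in ivs:
            for r in range(6):
                for c in range(6):
                    expected = sum(
                        int(masks[s][r, c] == 1) for s in seasons if iv[0] <= s <= iv[1]
                    )
                    assert freq[iv][r, c] == expected
        assert np.array_equal(change[(ivs[0], ivs[1])], freq[ivs[1]] - freq[ivs[0]])
        assert all((freq[iv] <= 5).all() for iv in ivs)

    def test_presence_all_seasons_gives_interval_length(self):
        masks = {s: np.ones((2, 2), dtype=np.uint8) for s in range(2000, 2005)}
        freq, _ = frequency_map(masks, [(2000, 2004)])
        assert (freq[(2000, 2004)] == 5).all()

    def test_season_outside_intervals_rejected(self):
        masks = {1999: np.zeros((2, 2), np.uint8)}
        with pytest.raises(ValueError):
            frequency_map(masks, [(2000, 2004)])


def test_classify_cube_marks_unusable_pixels():
    data = np.full((8, 2, 2), np.nan)
    data[:, 0, 0] = 1.0
    cube = LaiCube(data=data, dates=np.arange(8))
    mask = classify_cube(cube, PhenologyWindows(autumn_rise=(1, 3), spring_peak=(4, 6),
                                                senescence=(6, 7)))
    assert mask[0, 1] == NODATA_MASK
    assert mask[1, 0] == NODATA_MASK
    assert mask[0, 0] in (0, 1)
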