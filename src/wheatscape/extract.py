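"""Per-pixel winter-wheat classification from seasonal LAI curves.

Winter wheat has a distinctive double-feature seasonal LAI trajectory inside
its growing window (sowing in early autumn through harvest in late spring):
a rise after autumn emergence, a winter plateau, a strong spring green-up
peak, and senescence back to near zero before harvest.  A pixel is labelled
wheat when its (smoothed) curve shows

  1. the seasonal peak inside the spring green-up window,
  2. an inflection (second-difference sign change) inside the autumn-rise
     window,
  3. senescence: the final-composite LAI at most `lai_sow_max` times the
     peak value, and
  4. a seasonal maximum at least `lai_max_threshold` (threshold cleanup).

Curves are smoothed with a 3-composite moving average; the peak is the
argmax with first-index tie-break.  A cropland/dryland mask removes
non-cropland detections.  Multi-year presence masks are summarized into
planting-frequency maps over equal sub-intervals of the study span and
frequency-change maps between consecutive intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .rasters import check_aligned

__all__ = [
    "LaiCube",
    "PhenologyWindows",
    "CurveFeatures",
    "curve_features",
    "classify_pixel",
    "classify_cube",
    "apply_cropland_mask",
    "planting_area",
    "make_intervals",
    "frequency_map",
]

NODATA_MASK = 255  # byte-mask sentinel


@dataclass
class LaiCube:
    """One growing season of LAI composites: data[composite, row, col]."""

    data: np.ndarray
    dates: np.ndarray  # day-of-year label per composite, ordered within the window
    transform: tuple = (0.0, 250.0, 0.0, 0.0, 0.0, -250.0)
    nodata: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.dates = np.asarray(self.dates)
        if self.data.ndim != 3:
            raise ValueError("LAI cube must be 3-D (composite, row, col)")
        if self.data.shape[0] != self.dates.size:
            raise ValueError("one date label per composite required")

    @property
    def n_composites(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class PhenologyWindows:
    """Three climatic periods as inclusive composite-index windows.

    Defaults assume 16 composites spanning sowing (index 0) to harvest
    (last index); they are configuration, not constants of nature, and
    should be adapted to the composite schedule of the input product.
    """

    autumn_rise: tuple[int, int] = (1, 6)
    spring_peak: tuple[int, int] = (9, 13)
    senescence: tuple[int, int] = (13, 15)
    lai_max_threshold: float = 2.0  # minimum seasonal LAI maximum
    lai_sow_max: float = 0.5        # max final LAI as a fraction of the peak

    def __post_init__(self):
        for w in (self.autumn_rise, self.spring_peak, self.senescence):
            if w[0] > w[1]:
                raise ValueError(f"window {w} not ordered")
        if not (self.autumn_rise[1] <= self.spring_peak[0] <= self.spring_peak[1] <= self.senescence[1]):
            raise ValueError("windows must be ordered autumn <= spring <= senescence")
        if self.lai_max_threshold < 0 or self.lai_sow_max < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class CurveFeatures:
    peak_index: int
    peak_value: float
    inflection_indices: np.ndarray
    smoothed: np.ndarray = field(repr=False, default=None)


def curve_features(curve, dates=None, min_valid: int = 6):
    """Smooth one pixel's seasonal curve and locate its peak and inflections.

    Interior nodata (NaN) composites are linearly interpolated; pixels with
    leading/trailing NaN or fewer than `min_valid` valid composites return
    None (a skip marker, not an exception).  Inflections are indices i such
    that the second difference of the smoothed curve changes sign between
    curvature centers i and i+1; they are reported at curve index i+1.
    """
    y = np.asarray(curve, dtype=float).copy()
    valid = np.isfinite(y)
    if valid.sum() < min_valid:
        return None
    if not valid[0] or not valid[-1]:
        return None
    if not valid.all():
        idx = np.arange(y.size)
        y[~valid] = np.interp(idx[~valid], idx[valid], y[valid])
    smoothed = uniform_filter1d(y, size=3, mode="nearest")
    peak_index = int(np.argmax(smoothed))  # argmax takes the first index on ties
    d2 = np.diff(smoothed, 2)
    sign = np.sign(d2)
    flips = np.nonzero((sign[:-1] != sign[1:]) & (sign[:-1] != 0))[0]
    return CurveFeatures(
        peak_index=peak_index,
        peak_value=float(smoothed[peak_index]),
        inflection_indices=flips + 1,
        smoothed=smoothed,
    )


def classify_pixel(features: CurveFeatures, windows: PhenologyWindows) -> bool:
    """Apply the four wheat-phenology clauses to one pixel's features."""
    if features is None:
        return False
    a0, a1 = windows.autumn_rise
    s0, s1 = windows.spring_peak
    if not (s0 <= features.peak_index <= s1):
        return False
    infl = features.inflection_indices
    if not np.any((infl >= a0) & (infl <= a1)):
        return False
    if features.smoothed[-1] > windows.lai_sow_max * features.peak_value:
        return False
    if features.peak_value < windows.lai_max_threshold:
        return False
    return True


def classify_cube(cube: LaiCube, windows: PhenologyWindows) -> np.ndarray:
    """Classify every pixel of a seasonal cube; returns a byte mask.

    1 = wheat, 0 = not wheat, NODATA_MASK = skipped (unusable curve).
    """
    nrow, ncol = cube.shape
    mask = np.zeros((nrow, ncol), dtype=np.uint8)
    data = cube.data
    if cube.nodata is not None:
        data = np.where(data == cube.nodata, np.nan, data)
    for r in range(nrow):
        for c in range(ncol):
            feats = curve_features(data[:, r, c], cube.dates)
            if feats is None:
                mask[r, c] = NODATA_MASK
            elif classify_pixel(feats, windows):
                mask[r, c] = 1
    return mask


def apply_cropland_mask(mask, cropland, transform=None, cropland_transform=None):
    """Zero out wheat detections outside the cropland/dryland mask."""
    mask = np.asarray(mask)
    cropland = np.asarray(cropland)
    if transform is not None or cropland_transform is not None:
        check_aligned(mask.shape, transform, cropland.shape, cropland_transform)
    elif mask.shape != cropland.shape:
        raise ValueError(f"grid mismatch: {mask.shape} vs {cropland.shape}")
    out = mask.copy()
    out[(cropland == 0) & (out == 1)] = 0
    return out


def planting_area(mask, pixel_area_ha: float) -> float:
    """Planting area in k ha from a presence mask and per-pixel area (ha)."""
    if pixel_area_ha <= 0:
        raise ValueError("pixel area must be positive")
    return float(np.sum(np.asarray(mask) == 1)) * pixel_area_ha / 1000.0


def make_intervals(seasons, n_intervals: int = 4) -> list[tuple[int, int]]:
    """Split an ordered span of seasons into equal consecutive intervals."""
    seasons = sorted(int(s) for s in seasons)
    if len(seasons) % n_intervals:
        raise ValueError(
            f"{len(seasons)} seasons cannot be split into {n_intervals} equal intervals"
        )
    size = len(seasons) // n_intervals
    return [(seasons[k * size], seasons[(k + 1) * size - 1]) for k in range(n_intervals)]


def frequency_map(masks: dict, intervals) -> tuple[dict, dict]:
    """Per-interval planting-frequency maps and between-interval change maps.

    `masks` maps season -> presence mask; each season must fall in exactly
    one interval (inclusive bounds).  Frequency counts presence (mask == 1);
    change maps are later-interval frequency minus the previous interval's.
    """
    intervals = [tuple(iv) for iv in intervals]
    shapes = {m.shape for m in masks.values()}
    if len(shapes) > 1:
        raise ValueError(f"masks not aligned: shapes {shapes}")
    freq: dict = {}
    for season in masks:
        hits = [iv for iv in intervals if iv[0] <= int(season) <= iv[1]]
        if len(hits) != 1:
            raise ValueError(f"season {season} falls in {len(hits)} intervals")
    for iv in intervals:
        members = [m for s, m in masks.items() if iv[0] <= int(s) <= iv[1]]
        acc = np.zeros(next(iter(shapes)), dtype=np.int16)
        for m in members:
            acc += (np.asarray(m) == 1).astype(np.int16)
        freq[iv] = acc
    change = {
        (a, b): freq[b] - freq[a] for a, b in zip(intervals[:-1], intervals[1:])
    }
    return freq, change
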