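"""Synthetic inputs with known ground truth for the whole pipeline.

Everything downstream (phenology extraction, accuracy checks, trend and
mutation tests, decomposition, driver correlations) is exercised on data
from this module, so each generator stores the truth it embeds:

* seasonal LAI cubes whose wheat pixels follow a double-feature curve
  (autumn emergence rise, winter plateau, spring green-up peak, pre-harvest
  senescence) and whose non-wheat pixels follow a late single peak or a
  flat low curve, plus the true wheat mask;
* daily station meteorology with a sinusoidal annual temperature cycle,
  a configurable warming drift (default 116.91 degC/decade on the
  growing-season accumulated temperature, centered so the mean accumulated
  temperature sits near 3310.7 degC), seasonal precipitation occurrence and
  amounts (~379 mm per growing season), and sunshine hours that are reduced
  on wet days (which induces the physically expected negative
  precipitation-sunshine correlation) with an optional decline;
* annual planting-area and yield series built as smooth trend + weighted
  standardized met anomalies (positive on accumulated temperature, negative
  on sunshine) + white noise, with optional injected mean shifts.

All randomness derives from `SynthConfig.seed`; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .extract import LaiCube
from .met import HARVEST_DOY, SOWING_DOY, season_window
from .rasters import DEFAULT_TRANSFORM, write_raster

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "make_cropland_mask",
    "make_lai_cube",
    "make_met_daily",
    "make_area_yield",
    "make_shift_series",
    "reference_area_series",
    "emit_fixture_set",
]

WINDOW_DAYS = 238  # day 273 .. day 145 inclusive, non-leap pair (93 + 145)

# reference day-of-year grid of one (non-leap) growing window
_WINDOW_DOYS = np.concatenate([np.arange(SOWING_DOY, 366), np.arange(1, HARVEST_DOY + 1)])

# reference 16-composite parameterization of the wheat curve (index units on
# a 0..15 grid; other composite counts are mapped onto this grid)
_REF_GRID_MAX = 15.0


@dataclass
class SynthConfig:
    """Parameters of the synthetic study area and climate.

    Defaults emulate a warm-temperate winter-wheat province: 40 seasons of
    meteorology (1980-2019), 20 seasons of imagery (2000-2019), mean
    growing-season accumulated temperature ~3310.7 degC rising by
    ~116.91 degC/decade, ~379 mm seasonal precipitation, ~1448 h seasonal
    sunshine with a mild decline.
    """

    n_rows: int = 50
    n_cols: int = 50
    n_composites: int = 16
    cropland_fraction: float = 0.7
    wheat_fraction: float = 0.5
    seasons: tuple = tuple(range(2000, 2020))       # imaged (LAI) seasons
    met_seasons: tuple = tuple(range(1980, 2020))   # meteorology seasons
    noise_sd: float = 0.15       # additive LAI noise, LAI units
    seed: int = 0
    n_stations: int = 7
    mean_T: float = 3310.71      # target mean accumulated temperature, degC
    met_trend: float = 116.91    # accumulated-temperature drift, degC/decade
    mean_P: float = 379.0        # target mean seasonal precipitation, mm
    mean_h: float = 1447.8       # target mean seasonal sunshine, h
    sun_trend: float = -15.0     # sunshine drift, h/decade
    # "linear": uniform warming drift; "regime": flat before the injected T
    # change point, step + ramp after, with the ramp solved so the OLS slope
    # of accumulated temperature over the study still equals met_trend
    # (falls back to linear when no T change point is configured)
    met_trend_mode: str = "regime"
    temp_noise_sd: float = 1.5   # shared daily temperature noise, degC
    temp_season_sd: float = 65.0  # per-season accumulated-temperature anomaly, degC
    station_noise_sd: float = 0.5  # per-station daily temperature noise, degC
    precip_scale: float = 1.0    # 0 disables precipitation
    # area (k ha) and yield (1e4 t) series: trend polynomial coefficients in
    # normalized time tau in [0, 1], met-anomaly weights (T, P, h), noise sd
    area_trend: tuple = (3900.0, 1400.0, 400.0)
    area_weights: tuple = (80.0, 48.0, -24.0)
    area_noise_sd: float = 8.0
    yield_trend: tuple = (900.0, 2600.0, 250.0)
    yield_weights: tuple = (100.0, 60.0, -30.0)
    yield_noise_sd: float = 10.0
    # injected abrupt shifts: series name ("T", "P", "h", "area", "yield")
    # -> first season of the shifted regime
    change_points: dict = field(default_factory=lambda: {"T": 1997, "P": 2004})
    met_shift: dict = field(
        default_factory=lambda: {"T": 60.0, "P": 80.0, "h": -60.0}
    )  # seasonal-sum amplitude of injected met shifts
    series_shift_sd: float = 2.0  # area/yield shift amplitude, in sd of fluctuations

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("raster size must be positive")
        if self.n_composites < 6:
            raise ValueError("need at least 6 composites per season")
        if not 0 <= self.wheat_fraction <= 1:
            raise ValueError("wheat_fraction must be in [0, 1]")
        if not 0 <= self.cropland_fraction <= 1:
            raise ValueError("cropland_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["seasons"] = list(self.seasons)
        d["met_seasons"] = list(self.met_seasons)
        return d


@dataclass
class SynthTruth:
    """Ground truth stored alongside emitted synthetic data."""

    wheat_mask_per_season: dict = field(default_factory=dict)
    met_daily: pd.DataFrame | None = None
    area_components: pd.DataFrame | None = None
    yield_components: pd.DataFrame | None = None
    mutation_years: dict = field(default_factory=dict)


def _rng(cfg: SynthConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), *stream])


def _logistic(u, u0, k):
    return 1.0 / (1.0 + np.exp(-k * (u - u0)))


def composite_dates(cfg: SynthConfig) -> np.ndarray:
    """Day-of-year label per composite, sowing day 273 to harvest day 145."""
    offsets = np.round(np.linspace(0, WINDOW_DAYS - 1, cfg.n_composites)).astype(int)
    return (SOWING_DOY - 1 + offsets) % 365 + 1


def make_cropland_mask(cfg: SynthConfig) -> np.ndarray:
    """Byte cropland mask, constant across seasons (seeded by cfg.seed only)."""
    rng = _rng(cfg, 10)
    npix = cfg.n_rows * cfg.n_cols
    n_crop = int(round(cfg.cropland_fraction * npix))
    mask = np.zeros(npix, dtype=np.uint8)
    mask[rng.choice(npix, size=n_crop, replace=False)] = 1
    return mask.reshape(cfg.n_rows, cfg.n_cols)


def wheat_curve(u, ta=2.5, ts=10.0, te=13.5, amp_autumn=0.9, amp_spring=3.5, base=0.1):
    """Closed-form double-feature wheat LAI curve on the reference 0..15 grid.

    Autumn-emergence logistic (inflection near `ta`), spring green-up
    logistic (inflection near `ts`), multiplicative senescence decline
    centred at `te`, over a low background.
    """
    grow = amp_autumn * _logistic(u, ta, 2.0) + amp_spring * _logistic(u, ts, 1.5)
    return grow * (1.0 - _logistic(u, te, 2.5)) + base


def nonwheat_curve(u, t0=13.0, amp=2.5, base=0.15):
    """Late single-peak curve (e.g. a spring-sown crop still green at harvest)."""
    return base + amp * _logistic(u, t0, 1.2)


def make_lai_cube(cfg: SynthConfig, season) -> tuple[LaiCube, np.ndarray]:
    """One season's LAI cube plus the true wheat mask.

    Wheat pixels are drawn without replacement from the cropland pixels
    (count = round(wheat_fraction * n_cropland)); remaining cropland splits
    between the late-peak and flat-low non-wheat families; non-cropland is
    constant low.  Gaussian noise of sd cfg.noise_sd is added and the cube
    clipped at 0.
    """
    cropland = make_cropland_mask(cfg)
    rng = _rng(cfg, 20, int(season))
    n, m, T = cfg.n_rows, cfg.n_cols, cfg.n_composites
    u = np.linspace(0.0, _REF_GRID_MAX, T)

    crop_idx = np.flatnonzero(cropland.ravel() == 1)
    n_wheat = int(round(cfg.wheat_fraction * crop_idx.size))
    wheat_idx = rng.choice(crop_idx, size=n_wheat, replace=False) if n_wheat else np.array([], dtype=int)
    truth = np.zeros(n * m, dtype=np.uint8)
    truth[wheat_idx] = 1

    data = np.empty((T, n * m))
    data[:] = 0.15  # non-cropland background
    # wheat: per-pixel jitter on timing and spring amplitude
    if n_wheat:
        ta = rng.uniform(2.0, 3.0, n_wheat)
        ts = rng.uniform(9.5, 10.5, n_wheat)
        te = rng.uniform(13.2, 13.8, n_wheat)
        amp = 3.5 * rng.uniform(0.9, 1.1, n_wheat)
        for k, pix in enumerate(wheat_idx):
            data[:, pix] = wheat_curve(u, ta[k], ts[k], te[k], amp_spring=amp[k])
    # non-wheat cropland: late-peak or flat-low, chosen per pixel
    other_idx = np.setdiff1d(crop_idx, wheat_idx)
    if other_idx.size:
        late = rng.random(other_idx.size) < 0.5
        t0 = rng.uniform(12.5, 13.5, other_idx.size)
        amp_nw = rng.uniform(2.0, 3.0, other_idx.size)
        flat = rng.uniform(0.2, 0.6, other_idx.size)
        for k, pix in enumerate(other_idx):
            if late[k]:
                data[:, pix] = nonwheat_curve(u, t0[k], amp_nw[k])
            else:
                data[:, pix] = flat[k]

    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, data.shape)
    data = np.clip(data, 0.0, None)
    cube = LaiCube(
        data=data.reshape(T, n, m),
        dates=composite_dates(cfg),
        transform=DEFAULT_TRANSFORM,
    )
    return cube, truth.reshape(n, m)


def _season_of(dates: pd.DatetimeIndex) -> np.ndarray:
    """Harvest-year label of each date (dates outside any window get the
    upcoming harvest year; only in-window days matter downstream)."""
    doy = dates.dayofyear.to_numpy()
    year = dates.year.to_numpy()
    return np.where(doy >= SOWING_DOY, year + 1, year)


def make_met_daily(cfg: SynthConfig) -> pd.DataFrame:
    """Daily station meteorology covering every configured growing season.

    Weather is drawn once per day at the provincial scale — a temperature
    anomaly (daily noise plus a per-season anomaly of sd
    ``temp_season_sd`` on the accumulated scale), wet-day occurrence with a
    seasonal probability, exponential rain amounts, and a cloudiness factor
    that cuts sunshine far more on wet days — and stations add a fixed
    north-south offset plus small local noise.  Baselines are calibrated
    analytically so the default growing-season sums sit at ``mean_T``,
    ``mean_P`` and ``mean_h``; ``met_trend`` and ``sun_trend`` move the
    seasonal sums by the stated amount per decade, centered mid-study.

    Columns: date, station, tmax_c, tmin_c, precip_mm, sunshine_h.
    """
    rng = _rng(cfg, 30)
    first, last = min(cfg.met_seasons), max(cfg.met_seasons)
    start, _ = season_window(first)
    _, end = season_window(last)
    dates = pd.date_range(start, end, freq="D")
    ndays = dates.size
    doy = dates.dayofyear.to_numpy()
    frac_year = (dates - dates[0]).days.to_numpy() / 365.25
    mid = frac_year.mean()
    season_lbl = _season_of(dates)

    def wet_prob(d):
        return 0.10 + 0.25 * (1.0 + np.cos(2 * np.pi * (d - 197) / 365.25)) / 2.0

    # analytic calibration on the reference (non-leap) window grid
    phase = np.cos(2 * np.pi * (doy - 197) / 365.25)
    phase_w = np.cos(2 * np.pi * (_WINDOW_DOYS - 197) / 365.25)
    amp_T = 12.0
    t0 = cfg.mean_T / WINDOW_DAYS - amp_T * phase_w.mean()
    p_w = wet_prob(_WINDOW_DOYS)
    rain_mean = cfg.mean_P / p_w.sum()
    # E[reduction | wet] = 0.25, E[reduction | dry] = 0.85
    red_w = 0.85 - 0.6 * p_w
    clear_phase = np.cos(2 * np.pi * (doy - 172) / 365.25)
    clear_phase_w = np.cos(2 * np.pi * (_WINDOW_DOYS - 172) / 365.25)
    s_amp = 2.5
    s0 = (cfg.mean_h - s_amp * np.sum(clear_phase_w * red_w)) / red_w.sum()

    sun_daily_trend = cfg.sun_trend / (10.0 * WINDOW_DAYS)
    cp = cfg.change_points

    # warming drift on the daily scale.  Linear mode: uniform met_trend/decade.
    # Regime mode (with a T change point): flat before the change year, then a
    # sustained step — the abrupt-warming reading of a fitted "per decade"
    # slope — with the total step amplitude solved so the OLS slope of the
    # seasonal sums over the study period equals met_trend in expectation.
    # cfg.met_shift["T"] is part of that total (applied via t_step below).
    if cfg.met_trend_mode == "regime" and "T" in cp:
        yrs = np.asarray(sorted(cfg.met_seasons), dtype=float)
        cpy = float(cp["T"])
        step = (yrs >= cpy).astype(float)
        beta_step = np.mean((step - step.mean()) * (yrs - yrs.mean())) / np.var(yrs)
        total_step = cfg.met_trend / 10.0 / beta_step if beta_step > 0 else 0.0
        extra = total_step - cfg.met_shift.get("T", 0.0)
        season_step = (season_lbl >= cpy).astype(float)
        drift_arr = (extra / WINDOW_DAYS) * (season_step - step.mean())
    else:
        drift_arr = (cfg.met_trend / (10.0 * WINDOW_DAYS)) * (frac_year - mid)

    # injected abrupt shifts, expressed on the seasonal-sum scale and
    # centered so the long-run means stay at their calibrated targets
    yrs_all = np.asarray(sorted(cfg.met_seasons), dtype=float)

    def centered_step(name):
        if name not in cp:
            return np.zeros(ndays)
        frac_after = np.mean(yrs_all >= cp[name])
        ind = (season_lbl >= cp[name]).astype(float)
        return (cfg.met_shift.get(name, 0.0) / WINDOW_DAYS) * (ind - frac_after)

    t_step = centered_step("T")
    h_step = centered_step("h")
    if "P" in cp:
        rel = cfg.met_shift.get("P", 0.0) / cfg.mean_P
        frac_after = np.mean(yrs_all >= cp["P"])
        p_factor = np.where(season_lbl >= cp["P"], 1.0 + rel, 1.0) / (
            1.0 + rel * frac_after
        )
    else:
        p_factor = np.ones(ndays)

    # provincial weather, shared across stations
    seasons_all = np.unique(season_lbl)
    anom_by_season = dict(zip(
        seasons_all.tolist(),
        rng.normal(0.0, cfg.temp_season_sd / WINDOW_DAYS, seasons_all.size),
    ))
    t_anom = rng.normal(0.0, cfg.temp_noise_sd, ndays) + np.array(
        [anom_by_season[s] for s in season_lbl]
    )
    tmean_prov = t0 + amp_T * phase + drift_arr + t_step + t_anom
    wet = rng.random(ndays) < wet_prob(doy)
    amounts = rng.exponential(rain_mean, ndays) * cfg.precip_scale * p_factor
    precip_prov = np.where(wet, amounts, 0.0)
    reduction = np.where(wet, rng.uniform(0.0, 0.5, ndays), rng.uniform(0.7, 1.0, ndays))
    sun_prov = np.clip(
        (s0 + s_amp * clear_phase) * reduction
        + sun_daily_trend * (frac_year - mid)
        + h_step,
        0.0,
        None,
    )

    frames = []
    station_offsets = (
        np.linspace(-1.0, 1.0, cfg.n_stations) if cfg.n_stations > 1 else np.zeros(1)
    )
    for s in range(cfg.n_stations):
        half_range = np.abs(5.0 + rng.normal(0.0, 0.8, ndays))
        tmean = tmean_prov + station_offsets[s] + rng.normal(0.0, cfg.station_noise_sd, ndays)
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "station": f"S{s:02d}",
                    "tmax_c": tmean + half_range,
                    "tmin_c": tmean - half_range,
                    "precip_mm": precip_prov * rng.uniform(0.7, 1.3, ndays),
                    "sunshine_h": np.clip(
                        sun_prov + rng.normal(0.0, 0.3, ndays), 0.0, None
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _trend_poly(coefs, tau):
    out = np.zeros_like(tau)
    for k, c in enumerate(coefs):
        out += c * tau**k
    return out


def make_area_yield(
    cfg: SynthConfig, met: pd.DataFrame
) -> tuple[pd.Series, pd.Series, SynthTruth]:
    """Annual planting-area (k ha) and yield (1e4 t) series with stored truth.

    Each series = polynomial trend (+ any injected step, folded into the
    stored trend) + weighted standardized met anomalies + white noise; the
    stored components sum exactly to the emitted series.
    """
    needed = {"season", "T", "P", "h"}
    if not needed.issubset(met.columns):
        raise ValueError(f"met table needs columns {sorted(needed)}")
    seasons = met["season"].to_numpy()
    want = np.asarray(sorted(cfg.met_seasons))
    if not np.array_equal(np.sort(seasons), want):
        raise ValueError("met table does not cover the configured seasons")
    met = met.sort_values("season")
    seasons = met["season"].to_numpy()
    n = seasons.size
    tau = (seasons - seasons[0]) / max(n - 1, 1)
    z = {c: (met[c] - met[c].mean()).to_numpy() / met[c].std(ddof=0) for c in "TPh"}

    rng = _rng(cfg, 40)
    truth = SynthTruth()
    out = {}
    for name, coefs, weights, noise_sd in (
        ("area", cfg.area_trend, cfg.area_weights, cfg.area_noise_sd),
        ("yield", cfg.yield_trend, cfg.yield_weights, cfg.yield_noise_sd),
    ):
        trend = _trend_poly(np.asarray(coefs, dtype=float), tau)
        climatic = weights[0] * z["T"] + weights[1] * z["P"] + weights[2] * z["h"]
        noise = rng.normal(0.0, noise_sd, n)
        if name in cfg.change_points:
            amp = cfg.series_shift_sd * np.sqrt(np.var(climatic) + noise_sd**2)
            trend = trend + amp * (seasons >= cfg.change_points[name])
            truth.mutation_years[name] = int(cfg.change_points[name])
        values = trend + climatic + noise
        # store the noise column as the exact floating-point residual so
        # value - trend - climatic - noise is identically zero
        comp = pd.DataFrame(
            {"season": seasons, "value": values, "trend": trend,
             "climatic": climatic, "noise": values - trend - climatic}
        )
        out[name] = pd.Series(values, index=pd.Index(seasons, name="season"), name=name)
        if name == "area":
            truth.area_components = comp
        else:
            truth.yield_components = comp
    for key, yr in cfg.change_points.items():
        truth.mutation_years.setdefault(key, int(yr))
    return out["area"], out["yield"], truth


def make_shift_series(
    n: int, shift_index: int, amplitude_sd: float = 2.0, seed: int = 0
) -> np.ndarray:
    """Unit-variance white noise with a mean shift from `shift_index` on."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x[shift_index:] += amplitude_sd
    return x


def reference_area_series(truth_masks: dict, pixel_area_ha: float) -> pd.Series:
    """Yearbook-style reference areas (k ha) from the true wheat masks."""
    seasons = sorted(truth_masks)
    vals = [np.sum(truth_masks[s] == 1) * pixel_area_ha / 1000.0 for s in seasons]
    return pd.Series(vals, index=pd.Index(seasons, name="season"), name="reference_kha")


def emit_fixture_set(cfg: SynthConfig, outdir) -> dict:
    """Write the full synthetic input set (rasters, tables, config) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {"lai": {}, "truth_mask": {}}
    cropland = make_cropland_mask(cfg)
    paths["cropland"] = str(write_raster(outdir / "cropland.tif", cropland))
    truth_masks = {}
    for season in cfg.seasons:
        cube, truth = make_lai_cube(cfg, season)
        truth_masks[season] = truth
        paths["lai"][season] = str(
            write_raster(outdir / f"lai_{season}.tif", cube.data.astype(np.float32))
        )
        paths["truth_mask"][season] = str(
            write_raster(outdir / f"wheat_truth_{season}.tif", truth)
        )
    met = make_met_daily(cfg)
    met_path = outdir / "met_daily.csv"
    met.to_csv(met_path, index=False)
    paths["met_daily"] = str(met_path)
    from .met import aggregate_seasons  # local import to avoid cycle at module load

    season_met = aggregate_seasons(met, cfg.met_seasons)
    area, yld, truth = make_area_yield(cfg, season_met)
    for name, series in (("area", area), ("yield", yld)):
        p = outdir / f"{name}_series.csv"
        series.rename("value").reset_index().rename(
            columns={"season": "year"}
        ).to_csv(p, index=False)
        paths[name] = str(p)
    ref = reference_area_series(truth_masks, pixel_area_ha=6.25)
    ref_path = outdir / "reference_area.csv"
    ref.reset_index().rename(columns={"season": "year"}).to_csv(ref_path, index=False)
    paths["reference_area"] = str(ref_path)
    cfg_path = outdir / "synth_config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg.to_dict()))
    paths["config"] = str(cfg_path)
    return paths
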