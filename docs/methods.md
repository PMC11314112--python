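# Methods

This note documents the models, parameter choices and numerical decisions
behind `wheatscape`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Phenology-based wheat classification

A pixel's seasonal LAI curve (one value per composite, sowing → harvest) is
smoothed with a 3-composite moving average (`scipy.ndimage.uniform_filter1d`,
nearest-edge padding). Features:

* **peak** — argmax of the smoothed curve, first index on ties;
* **inflections** — indices where the second difference of the smoothed
  curve changes sign (reported at the center of the sign change).

A pixel is wheat iff all four clauses hold:

1. peak index inside the spring green-up window;
2. at least one inflection inside the autumn-rise window (emergence);
3. smoothed LAI at the final composite ≤ `lai_sow_max` × peak value
   (senescence observed before harvest);
4. peak value ≥ `lai_max_threshold` (threshold cleanup of low-LAI pixels).

Interior missing composites are linearly interpolated; pixels with missing
endpoints or fewer than 6 valid composites are skipped (mask value 255),
never guessed. Defaults (`PhenologyWindows`): autumn window composites 1–6,
spring window 9–13, senescence 13–15 on a 16-composite season,
`lai_max_threshold = 2.0`, `lai_sow_max = 0.5`. These are configuration,
not constants: they encode the crop calendar of the target region and the
composite schedule of the LAI product, and must be adapted to both. The
defaults describe a northern-hemisphere winter-wheat season sampled
16 times between sowing (day 273) and harvest (day 145).

Grids must share shape and transform exactly; the package performs no
resampling. Planting area is `count(mask == 1) × pixel_area / 1000` k ha.
Multi-year presence masks are summed per pixel inside equal consecutive
intervals of the study span (2000–2019 splits as 2000–2004, …, 2015–2019);
change maps difference consecutive intervals.

## Growing-season meteorology

The growing window of harvest year *y* runs from day-of-year 273 of
*y* − 1 through day-of-year 145 of *y*, inclusive — 238 days for a
non-leap pair (93 autumn days + 145 spring days). Day-of-year is taken in
each calendar year's own calendar, so the calendar dates of the window
bounds wobble by one day around leap years and a window containing a leap
February has 239 days.

Accumulated temperature is the plain sum of daily means `(tmax + tmin)/2`
with no base-temperature cutoff — at ~13.9 °C/day the 238-day window gives
the ~3145–3424 °C provincial range typical of warm-temperate winter-wheat
regions. Precipitation and sunshine are plain sums. The provincial value is
the unweighted mean over stations (7 by default). Gaps up to 5% of a
station's window days are filled (linear interpolation for temperature,
zero for precipitation, station-month mean for sunshine); larger gaps are a
hard error naming the station.

## Mann-Kendall trend and sequential mutation test

`S = Σ_{1≤j<i≤n} sign(x_i − x_j)`;
`Var(S) = [n(n−1)(2n+5) − Σ_p t_p(t_p−1)(2t_p+5)]/18` with tied-group sizes
`t_p`; `Z` uses the continuity correction (S−1 above zero, S+1 below) and
is 0 at S = 0. Two-sided critical value from the normal quantile
(1.96 at α = 0.05). Minimum length 3.

The sequential test follows the progressive/retrograde construction: UF_i
standardizes the cumulative count of earlier values exceeded by x_i, with
mean i(i−1)/4 and variance i(i−1)(2i+5)/72; ties contribute 1/2 to the
count (midrank), which makes UF ≡ 0 on constant series. No tie correction
is applied inside the sequential variance — ties are measure-zero in
continuous meteorological sums. UB is the progressive statistic of the
reversed series, negated and re-reversed; UF[0] = UB[n−1] = 0.

A mutation year is a strict sign change of UF − UB between consecutive
indices whose linearly interpolated crossing lies inside [−z_crit, +z_crit];
the crossing year is rounded half-up. A run of exact UF = UB equality
flanked by opposite signs reports the run's first year; identical curves
report nothing. Out-of-band crossings are ignored: when a series carries a
strong monotone trend the curves cross far outside the band and no mutation
is declared — detectability requires the shift to stand out against a
roughly trend-free background.

Calibration (measured by the acceptance script): empirical size ≈ 0.04–0.05
at n = 40 (slightly conservative, as expected from the continuity
correction); power ≈ 1 for a linear trend whose standard deviation across
the series equals the noise sd (that is the "1 sd trend" convention used
throughout — a trend whose *total rise* is 1 sd is a ~45% power alternative
for any correctly sized MK test); a 2-sd mean shift at index 20 of 40 is
localized to the true year (modal over 200 replicates, within ±3).

## HP decomposition

The trend minimizes `Σ(x_t − τ_t)² + λ Σ(τ_{t+1} − 2τ_t + τ_{t−1})²`,
solved exactly as the sparse pentadiagonal system `(I + λ DᵀD) τ = x`
(n ≤ 40 makes iteration pointless). λ defaults to 100, the classic
annual-data choice; 6.25 is the documented alternative. Limiting behaviour
is tested: linear input passes through, λ → ∞ reproduces the OLS line,
trend + residual reconstructs the series to machine precision, and the
result matches the statsmodels HP filter. The residual is interpreted as
the climate-driven component; note that when the climate anomalies
themselves carry a regime shift (as the default generator's temperature
does), part of that signal is low-frequency and lands in the trend — the
high-frequency recovery correlation > 0.9 holds for genuinely
high-frequency injected components.

## Driver correlations

Product-moment r with the two-sided p from
`t = r√((n−2)/(1−r²))` on n−2 df (via `scipy.stats.pearsonr`); stars
`*` p < 0.05, `**` p < 0.01; no multiple-testing correction (raw p-values
with star conventions are the field's reporting style). Annual-difference
targets are paired with the *level* of the factor in the later season by
default (`diff_met=True` pairs with the factor's own differences). Drivers
are ranked per target by |r|.

## The synthetic study area

`SynthConfig` defaults describe one coherent study: a 50 × 50 raster
(250 m pixels), 70% cropland, half of it wheat; 20 imaged seasons
(2000–2019), 16 composites each; 40 meteorology seasons (1980–2019),
7 stations.

* **LAI curves.** Wheat: product of an autumn-emergence logistic
  (inflection near composite 2.5), a spring green-up logistic (near 10) and
  a senescence decline (near 13.5) over a 0.1 background — peak ≈ 3.6–4.0
  at composite ~12, final value ≈ 0.1–0.15 of peak; per-pixel jitter on all
  timings and the spring amplitude. Non-wheat cropland: either a late
  single-peak curve still green at harvest or a flat low curve; bare land:
  constant 0.15. Gaussian noise (sd 0.15 by default) and clipping at 0.
  By construction wheat satisfies the four classification clauses and the
  non-wheat families each violate at least two, which is why recovery is
  exact without noise and ≥ 95% precision/recall at the default noise.
* **Meteorology.** Daily provincial weather shared across stations:
  sinusoidal temperature cycle calibrated so the mean seasonal sum is
  3310.7 °C; per-season anomalies of sd 65 °C; wet-day occurrence with a
  summer-peaked probability and exponential amounts calibrated to
  379 mm/season; sunshine as a clear-sky cycle times a cloudiness factor
  that is far smaller on wet days (mean 1447.8 h/season) — this induces the
  physically expected negative precipitation-sunshine correlation
  (ρ ≈ −0.6 between seasonal sums). Stations add a fixed N-S offset and
  small local noise. Warming: 116.91 °C/decade, realized by default as a
  sustained step at the injected 1997 change point whose amplitude is
  solved so the OLS slope over the study equals that figure
  (`met_trend_mode="regime"`); a uniform linear drift of the same size is
  available (`"linear"`) but pushes the UF/UB crossing far outside the
  significance band, i.e. a linear-warming world has no detectable
  "mutation" even though the change year is where the curves cross.
  Sunshine declines 15 h/decade. Injected met shifts are mean steps on the
  seasonal-sum scale (T +60 °C at 1997, P +80 mm at 2004 by default),
  centered so long-run means stay at their targets.
* **Area/yield.** Series = quadratic trend (area 3900 → 5700 k ha, yield
  900 → 3750 × 10⁴ t) + weighted standardized anomalies
  (area 80/48/−24, yield 100/60/−30 on T/P/h — positive temperature,
  weakly positive precipitation, negative sunshine, magnitudes ordered
  T > P > h) + white noise. The stored components sum to the emitted series
  exactly (the noise column is kept as the floating-point residual).

What the generator does **not** emulate: spatial autocorrelation of fields
or weather, mixed pixels, atmospheric/view-angle artefacts in LAI,
autocorrelated daily weather, station inhomogeneities, or policy/technology
shocks in the area series. Passing tests therefore demonstrate that the
*estimators* behave correctly under known truth, not that the default
thresholds transfer to any particular sensor or province.

## Recovery-rate limits

The Monte-Carlo driver-recovery experiment (200 replicates, n = 40)
separates two claims. The *sign* of each injected weight is recovered
essentially always (the yield-sunshine correlation is negative in ~100% of
replicates). The *joint* event — all three signs plus the strict
|r_T| > |r_P| > |r_h| ranking — succeeds in only ~20–25% of replicates
under the default conditions, and cannot exceed ~90% for any weight choice:
reliable strict ranking of three correlations at n = 40 needs pairwise |r|
gaps of ~0.3 against sampling noise of sd ≈ (1−r²)/√n, which together with
Σr² ≤ 1 is unsatisfiable; the natural precipitation-sunshine
anticorrelation further narrows the P-h gap. The acceptance script reports
the measured rate; treat the ranking of similarly sized correlations from
40 annual observations as descriptive, not inferential.

## Problem sizes

Tests and the acceptance script use 50 × 50 scenes (2 500 pixels), 40-season
series, 2 000 null replicates for test size, 500 for power, and 200-replicate
Monte-Carlos for change-point and correlation recovery; a full synthetic
pipeline run (20 seasons, all stages) completes in a few seconds and the
whole acceptance script in about three minutes on one CPU.

## Pipeline and reproducibility

One YAML config drives all stages; exactly one of a `synth` block or real
input paths must be given per data source (schema-checked before any
computation). All randomness derives from the single `seed` via
`numpy.random.default_rng([seed, stream...])` spawn keys; reports carry no
timestamps, so identical config + seed gives byte-identical reports.
Per-season wheat masks are cached on disk and reused unless `--force` is
given. Imagery-based areas cover the imaged seasons and are used for
accuracy scoring; the long statistical area/yield series drive the trend,
decomposition and correlation stages — mirroring how regional studies pair
a 20-year remote-sensing record with a 40-year yearbook record.
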