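# Methods

This note documents the models implemented in `pestrisk`, the choices made
where the published description leaves the design open, and what the
synthetic test world does and does not demonstrate.

## Mechanistic host model

### Weekly bridge

The canonical input is a monthly climatology (per cell: tmin, tmax, rain,
optionally RH at 09:00/15:00), matching the structure of the gridded
datasets used for this kind of analysis. The engine operates on a 52-week
year: temperatures are piecewise-linearly interpolated between month
midpoints (periodic, so the series cannot overshoot the monthly extremes),
and each month's rain is divided evenly over the weeks whose centres fall in
that month, conserving the annual total exactly. Weekly
tavg = (tmin + tmax)/2.

### Growth indices

Both growth responses are trapezoids: zero at or below the lower threshold
(DV0 / SM0), rising linearly to one at the lower optimum (DV1 / SM1), one
across the optimum plateau, falling to zero at the upper threshold
(DV3 / SM3). Boundary values at the outer thresholds score zero (closed at
the optimum, open at the limits). The annual growth index is
GIA = 100 · mean(TI_w · MI_w), reported on 0–100 so that EI lands on the
conventional 0–100 scale; TI and MI stay on 0–1.

Shipped defaults are the published sweetgum values (DV0–DV3 = 10, 16, 32,
38 °C; SM0–SM3 = 0.1, 0.5, 0.75, 1.5; stress pairs as in
`pestrisk/params.py`). Where the narrative description of the fitting
process disagrees with the final tabulated values (SM3, the dry- and
wet-stress rates, the hot-wet moisture threshold), the tabulated values are
the defaults and the narrative variants ship as a named override dict
(`SWEETGUM_TEXT_VARIANTS`); neither is assumed "correct".

### Water balance

The published description gives soil-moisture thresholds but no
water-balance form, so the package supplies a standard single-layer leaky
bucket. Moisture `m` is a fraction of capacity (default 100 mm):

```
m' = clamp(m + rain_w/C − et_coeff · max(tavg_w, 0) · min(m, 1)/C
            − drainage · max(m − 1, 0), 0, sm_max)
```

- evaporative demand (default et_coeff = 2 mm · week⁻¹ · °C⁻¹) is limited by
  available moisture, giving interior equilibria below field capacity
  (m\* = rain / (et_coeff · tavg) under constant forcing);
- storage above field capacity (m > 1) drains at 0.25 week⁻¹, so values in
  the 1–3 range — which the moisture thresholds SM3 = 1.5, SMWS = 1.8 and
  MTHW = 2.8 presuppose — are reachable in strongly over-saturated climates
  but transient elsewhere;
- hard clamp at sm_max = 3, initial value 0.5, one spin-up year (the second
  year of iterating the same annual forcing is used; under constant forcing
  the recurrence contracts geometrically, so the returned year is at the
  fixed point to well below 1e-6).

A plain clamp-only bucket (no supply limitation, no drainage) was rejected
because it admits no interior equilibrium: soil moisture then always pins at
a clamp, which either kills the moisture index in every wet climate (clamp
at or above SM3) or makes the wet and hot-wet stress thresholds unreachable
dead parameters (clamp below SMWS).

### Stress accumulation

Each stress has a weekly exceedance — cold: max(0, TTCS − tmin_w); heat:
max(0, tavg_w − TTHS); dry: max(0, SMDS − m_w); wet: max(0, m_w − SMWS);
hot-wet: max(0, tavg_w − TTHW) gated on m_w > MTHW — and a weekly rate. The
annual total is

```
stress = min(100, 100 · rate · Σ_w exc_w · n_w)
```

where n_w counts the stressful weeks so far in the year, so persistent
stress builds approximately quadratically. This is the simplest monotone
analogue of the exponentially compounding accumulation used by the original
mechanistic software; for a single stressful week it reduces to the plain
linear form 100 · rate · exc. The linear form (`accumulation="linear"`) is
kept as an option, but it cannot saturate bounded-exceedance stresses: dry
exceedance is at most SMDS = 0.1, so the linear total is bounded by
100 · 0.01 · 52 · 0.1 ≈ 5, and no desert could ever be excluded by dry
stress. Cold stress is driven by weekly tmin (survival is limited by
extremes); heat and hot-wet by tavg.

The stress-interaction term of the original EI formulation is fixed at 1;
hot-wet stress, which is parameterised separately, enters as a fifth
complement factor: EI = GIA · SI · (1 − HW/100).

### Habitat classes

EI 0 → unfavorable, (0, 15] → marginal, (15, 30] → favorable, > 30 → highly
favorable. The 15/30 cutoffs are the published class bounds for the host.

## Correlative pest model

- **Thinning**: greedy great-circle rarefaction in input order with a 10 km
  buffer; deterministic, idempotent, removes coordinate duplicates.
- **Background**: the published protocol generates 80 random
  "pseudo-presence" points; these are implemented as pseudo-*absences*
  (background contrasted with presences), since a two-class forest needs
  negatives. Default exclusion buffer around presences: 10 km, matching the
  thinning radius.
- **Features**: the 19 standard bioclimatic variables in the common
  dialect — quarters are the best wrapping 3-consecutive-month windows,
  bio4 is 100 × the (sample) standard deviation of monthly means, bio15 the
  CV of monthly totals with +1 mm on the mean.
- **Forest**: 500 trees, `sqrt` feature subsampling, probability = vote
  fraction, seed-deterministic (scikit-learn implementation behind the
  package's estimator surface).
- **Evaluation**: stratified 10-fold CV; inside each fold a random 70 % of
  the non-held-out points trains the model (the published hybrid design,
  reproduced literally). Metrics per fold and pooled over held-out
  predictions: AUC (rank-sum form, ties 0.5), kappa and TSS at the
  TSS-maximising threshold (the published description states no threshold
  rule; max-TSS is the standard choice). Degenerate folds are flagged,
  excluded from pooling, and warned about.
- **Importance**: permutation importance (mean AUC drop over 5 shuffles per
  feature), floored at zero and normalised to percentage contributions.
- **Classification**: exact Fisher–Jenks natural breaks (dynamic
  programming) into five classes (unsuitable / very low / low / medium /
  high), recomputed per scenario layer because the breaks depend on the
  layer's value distribution. The exact program is O(k·n²), so rasters with
  more than 2000 finite cells are broken on a deterministic
  quantile subsample; class assignment itself is exact, and ties at a break
  go to the lower class.

## Overlay and areas

The host mask is 1 where EI > 0. Masked cells become no-data and are
excluded from every total (counts logged). Change rasters are
future − current per cell, no-data where either scenario is. Cell areas use
the spherical band formula R² · Δλ · (sin φ_top − sin φ_bottom) with
R = 6371 km, which telescopes exactly to 4πR² over a global grid. Area
tables are (region × class × scenario) in 10⁴ km², with empty classes kept
as explicit zero rows. Because it is not stated whether published
suitable-area totals count the lowest suitable class, summaries report
totals both including and excluding it.

Region labels are synthetic (longitude sectors) — real continent boundaries
are out of scope; the accounting is exercised and tested on the synthetic
partition, whose conservation and additivity properties are
boundary-data-independent.

## Synthetic world

`default_global_scenario()` defines the study conditions: a global grid
(10′ for the headline runs; coarser in unit tests), annual-mean temperature
27 °C at the equator falling 0.6 °C per degree latitude, a sinusoidal
seasonal cycle growing to 24 °C amplitude at the poles (phase inverted
between hemispheres, so this world is colder at mid-latitudes and more
continental than Earth), diurnal range 8 °C, and five mirrored
precipitation bands: tropical-wet (|lat| < 8°, 2600 mm), arid (8–14°,
25 mm), humid-subtropical (14–24°, 850 mm, summer-wet), temperate (24–65°,
600 mm), polar (65–90°, 200 mm). Band totals were fixed once from the bucket
equilibria so that the three host archetypes exist by construction: the
humid-subtropical band sits inside both growth optima (EI > 30 everywhere),
the desert's soil moisture equilibrates below the wilting point (dry stress
saturates at 100), and polar winters cross the cold-stress threshold (cold
stress saturates at 100). The future scenario warms uniformly by 2 °C and
scales band rainfall ±10 % (wet wetter, dry drier).

Optional noise fields (per-cell temperature offset; independent per-cell,
per-month lognormal rain factors) default to zero. The
`parameter_recovery_scenario()` turns rain noise on (CV 0.8) over a single
moderate regime, so dry-month precipitation varies *within* latitude bands
and decorrelates from the temperature field; occurrences sampled from a
bio14-thresholded truth surface are then recoverable only through the
precipitation signal, which is what the recovery experiment measures
(pooled CV AUC and the driver's importance rank over 20 seeds, 200
presences + 200 background points each, on a 2° grid for tractability).

What the synthetic world does **not** emulate: longitudinal climate
structure (oceans, continentality, orography), interannual variability,
spatially autocorrelated sampling bias, and realistic collinearity among
bioclim variables. Passing tests therefore demonstrate correctness of the
algorithms and the recoverability of planted signal — not predictive skill
on real species data.

## Numerical notes

- All generators and model fits are pure functions of spec + seed; pipeline
  reruns with the same config are byte-identical.
- Trapezoids are evaluated exactly (no interpolation tables); degenerate
  zero-width ramps are handled as steps.
- The EI engine processes cells in chunks of 200k to bound memory on 10′
  global grids (2.3 M cells, ≈ 1 min on one CPU).
- Raster I/O is plain-text ESRI ASCII grid with `%.6g` values; round-trip
  accuracy is therefore ~6 significant digits, sufficient for all
  downstream thresholds.
- Percent area change is 100 · (current − future)/current, positive for
  reduction; it requires a positive current total.

## Known limitations

- The weekly stress compounding scheme is a simple monotone proxy for the
  original software's exponential accumulation; absolute stress values are
  not comparable to that software, only the saturation behaviour and
  ordering are.
- The water balance is a one-parameter-family bucket; no snow, runoff
  routing, or soil heterogeneity.
- The hybrid CV protocol (fold + 70 % subsample) is reproduced as described;
  its statistical properties are unusual, and pooled metrics should be read
  as descriptive, not as unbiased generalisation estimates.
- Jenks breaks on large rasters are computed on a quantile subsample; for
  pathological multimodal distributions the subsample optimum can differ
  slightly from the full-data optimum.
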