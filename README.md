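# pestrisk

Host-constrained risk mapping for an invasive bark beetle.

An oligophagous pest cannot establish where its host tree cannot grow. This
package couples two species distribution models to exploit that constraint:

1. a **mechanistic ecoclimatic-index model** of the host tree (American
   sweetgum, *Liquidambar styraciflua*), in the CLIMEX tradition, driven by
   monthly climate grids;
2. a **correlative random-forest model** of the bark beetle
   (*Acanthotomicus suncei*), trained on presence points against
   pseudo-absence background points over the 19 standard bioclimatic
   variables;
3. an **overlay stage** that masks the beetle's suitability map to the
   host's climatic range (EI > 0), differences current and future
   scenarios, and accounts suitable area per region and suitability class
   with true spherical cell areas.

Because the real climate grids and occurrence databases are large external
downloads, the package ships a first-class synthetic-data module that
generates climate scenario pairs and occurrence samples with the statistical
structure the analysis assumes, so the entire pipeline is testable and
reproducible offline.

## The models

**Host (mechanistic).** For each grid cell the monthly climate is
interpolated to 52 weeks. A trapezoidal temperature response `TI_w` (zero at
DV0 = 10 °C and DV3 = 38 °C, one between DV1 = 16 °C and DV2 = 32 °C) and a
trapezoidal soil-moisture response `MI_w` (over SM0..SM3, with soil moisture
from a weekly leaky-bucket water balance) combine into the annual growth
index, and accumulated weekly stresses (cold, heat, dry, wet, hot-wet)
discount it into the ecoclimatic index:

```
GIA = 100 · mean_w(TI_w · MI_w)
EI  = GIA · (1 − CS/100)(1 − HS/100)(1 − DS/100)(1 − WS/100) · (1 − HW/100)
```

EI is classified as unfavorable (0), marginal (0–15], favorable (15–30], or
highly favorable (> 30). The shipped parameter defaults are the published
values for sweetgum (`pestrisk.sweetgum_parameters()`).

**Pest (correlative).** Occurrences are spatially rarefied (10 km greedy
thinning), contrasted with 80 uniform background points, and modelled with a
500-tree random forest over bio1–bio19. Evaluation uses 10-fold
cross-validation with a 70 % training subsample inside each fold, reporting
AUC, Cohen's kappa and TSS (the latter two at the TSS-maximising threshold).
Probability maps are classified into five levels with exact Fisher–Jenks
natural breaks, recomputed per scenario layer.

## Worked example

Run the host model on the bundled synthetic globe (five latitude climate
bands, 4° resolution here for speed):

```python
from pestrisk import (EcoclimaticIndexEngine, sweetgum_parameters,
                      default_global_scenario, generate_climate_grid,
                      band_rows, percent_change)

spec = default_global_scenario(resolution_arcmin=240, seed=0)
grid = generate_climate_grid(spec)
result = EcoclimaticIndexEngine(sweetgum_parameters()).run_grid(grid)
for band in ("tropical_wet", "arid", "humid_subtropical", "temperate", "polar"):
    rows = band_rows(grid.geometry, band)
    print(f"{band:18s} EI {result.ei[rows].min():6.2f}..{result.ei[rows].max():6.2f}  "
          f"dry stress max {result.dry_stress[rows].max():5.1f}  "
          f"cold stress max {result.cold_stress[rows].max():5.1f}")
print("percent reduction from published totals:",
      round(percent_change(8764.93, 7914.02), 2))
```

prints

```
tropical_wet       EI  36.44.. 76.50  dry stress max   0.0  cold stress max   0.0
arid               EI   0.00..  0.00  dry stress max 100.0  cold stress max   0.0
humid_subtropical  EI  46.81.. 68.69  dry stress max   0.0  cold stress max   0.0
temperate          EI   0.00.. 31.51  dry stress max   0.0  cold stress max 100.0
polar              EI   0.00..  0.00  dry stress max   0.0  cold stress max 100.0
percent reduction from published totals: 9.71
```

The humid-subtropical band is highly favorable for the host; the desert band
is excluded by saturated dry stress and the polar band by saturated cold
stress. The last line is the headline change statistic applied to the
published current and future suitable-area totals (8764.93 and
7914.02 × 10⁴ km²): a 9.71 % reduction.

The full pipeline — synthetic scenario pair, host EI, pest SDM, overlay,
area report — runs from the shell:

```
pestrisk run-all --output-dir demo_run --seed 1 --resolution-arcmin 240
```

and writes EI/suitability/change rasters, the evaluation report, the
variable-importance table, the per-region area table
(`area_by_class.csv`), an area summary with percent change, and a run
manifest with hashes and seeds. Individual stages (`simulate-data`,
`host-ei`, `pest-sdm`, `overlay`, `report`) run separately on declared files.

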