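# Methods

This note records the model equations as implemented, the defaults and the
reasoning behind choices the published description of the method leaves
open. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Growth model

SAFY is a daily light-use-efficiency recurrence. Per day, with LAI the
leaf area index, DAM dry above-ground mass (g m⁻²) and SMT the air
temperature accumulated since emergence (°C day):

- biomass: `ΔDAM = Rg·εC·(1 − exp(−k·LAI))·ELUE·F_T(Ta)`, floored at 0;
- leaf growth: `ΔLAI⁺ = ΔDAM·P_l(SMT)·SLA` while the partition function
  `P_l = clip(1 − pl_a·exp(pl_b·SMT), 0, 1)` is positive;
- senescence: `ΔLAI⁻ = LAI·(SMT − S_TT)/R_s` once `SMT > S_TT`;
- grain filling: `ΔGY = DAM·P_y` from the day `P_l` first reaches 0
  (leaf production stopped) to the end of the season;
- thermal time: `SMT += max(Ta, 0)` (degree-day convention, base 0 °C).

The published description of the regional method names εI, F_T and P_l
but does not print their closed forms; the implementation uses the forms
of the original SAFY formulation: Beer–Lambert interception
`εI = 1 − exp(−k·LAI)`, a cardinal-temperature beta stress function
(0 at or below `t_min`, 1 at `t_opt`, 0 at or above `t_max`, exponent
`beta_t`), and the exponential leaf-partition function above. Each lives
behind one named function (`light_interception`, `temperature_stress`,
`leaf_partition`) so an alternative form can be swapped in.

Conventions the recurrence fixes explicitly:

- **Day indexing.** Season day 1 = 1 November; all calendar dates are
  converted at ingestion.
- **Emergence.** Days before `d0` hold the all-zero state. On day `d0`
  the crop initializes with `dam0` of biomass, the corresponding leaf
  area `dam0·P_l(0)·SLA`, and SMT starts accumulating that day.
- **Within-day ordering.** Partitioning, senescence and the
  grain-filling activation test use the start-of-day SMT; grain filling
  uses the end-of-day DAM; SMT is updated last.
- **Floors.** DAM, LAI and GY are clamped at ≥ 0 after every step, so
  degenerate parameter draws cannot produce negative biology.
- **SMT vs ΣTa.** The source description uses both symbols in the
  senescence term without distinguishing them; both are read as the same
  accumulated temperature.
- **εC.** Treated as the single Rg→APAR factor (no separate PAR unit
  conversion).

### Fixed parameter defaults

The eleven non-calibrated parameters default to a-priori values of the
kind used in prior SAFY work on cereals; they are package defaults, not
site measurements, and every one is overridable:

| parameter | default | unit | meaning |
|---|---|---|---|
| `k_ext` | 0.5 | – | light extinction |
| `eps_c` | 0.48 | – | climatic efficiency |
| `sla` | 0.022 | m² g⁻¹ | specific leaf area |
| `pl_a`, `pl_b` | 0.15, 0.002 | – | leaf partition |
| `rs` | 6000 | °C day | senescence rate scale |
| `py` | 0.005 | day⁻¹ | grain partition |
| `t_min`, `t_opt`, `t_max` | 0, 15, 37 | °C | cardinal temperatures |
| `beta_t` | 2 | – | stress shape |
| `dam0` | 4.2 | g m⁻² | biomass at emergence |

Yield unit conversion is 1 g m⁻² = 0.1 qx/ha; trajectories carry g m⁻²,
reports qx/ha.

### Implementation

The simulator advances many (d0, ELUE, S_TT) candidates in lock-step
through the season in one compiled kernel (`run_safy_batch`, numba);
`run_safy` is the single-candidate case. A deliberately naive scalar
day-loop re-implementation lives in the test suite and the two are
required to agree to 1e-9 relative on all state variables over random
admissible parameter draws.

## Calibration

Per plot, (d0, ELUE, S_TT) minimize the RMSE between simulated and
observed LAI, matched exactly on the daily grid (fractional observation
dates are rounded half-up at ingestion; no interpolation, no weighting —
a config hook is left for observation weights). The search box defaults
to the published ranges (d0 15–120 day, ELUE 0–10 g/MJ, S_TT
200–1800 °C day) and fitted values never leave it.

No optimization algorithm is published for this step. The objective is
cheap but non-smooth in d0 (a whole-day index) and multimodal: early
senescence with a larger ELUE can mimic a weak, late-senescing crop, and
these basins sit at different emergence days. The implemented search
therefore never discards a d0 before optimizing its inner problem:

1. a dense grid — every integer d0, 31 × 25 points in (ELUE, S_TT);
2. shrinking local grid refinement of (ELUE, S_TT) for **every** d0
   simultaneously (vectorized), with four inner starts per d0, one per
   block of the S_TT axis, 9 rounds of 7 × 7 offsets shrinking by 0.45;
3. Nelder–Mead polish at the three leading d0 values plus seeded
   Latin-hypercube restarts at the incumbent.

Exact ties prefer the smallest d0, then ELUE, then S_TT, which makes
results reproducible. Simulation stops at the last observation day
during the search (later days cannot affect the objective). All-zero
observation series are flagged non-identifiable (`converged=False`)
rather than raised; fewer than three observations triggers a warning
(three parameters are being fitted). The reported RMSE is re-evaluated
at the returned parameters on the full season.

## Yield statistic and regressions

`A_LAI` is the plain sum of daily LAI over season days 146–157 inclusive
(12 terms). A rectangle rule is used rather than a trapezoid because the
model is a daily recurrence: its LAI is piecewise constant per day.

Yield–A_LAI regressions are ordinary least squares via statsmodels,
per stratum (all / wheat / barley / irrigated / rainfed). Predictions
are floored at 0 qx/ha. Two uncertainty bands accompany a fit: the
confidence interval of the conditional mean and the prediction interval
for a new plot; both use the standard t-based closed forms and are
verified against statsmodels' `get_prediction` in the tests. The
confidence level defaults to 95% (none is published for the original
figures).

Validation follows repeated holdout: the cohort splits into three
disjoint folds (sizes differing by at most one), each fold in turn is
held out, and the whole split is repeated — 10 repeats by default (no
repeat count is published). The report keeps every run's holdout R² and
RMSE along with their averages; train-fit R² is available from the
regression object itself, since which of the two a published headline
figure refers to can be ambiguous.

## NDVI → LAI retrieval

NDVI is `(NIR − Red)/(NIR + Red)` with zero-denominator pixels set to
nodata. The semi-empirical NDVI→LAI relationship for the original site
is cited but not printed in the method's description, so the relation is
a required configuration input (form, coefficients, validity range,
monotone non-decreasing and non-negative on that range). A placeholder
default (`lai = 4.0·ndvi − 0.8`, valid NDVI 0.2–0.95) is shipped and
flagged `placeholder=True`; it anchors LAI 0 at the lower validity
bound and is not derived from any field campaign. NDVI below the
validity range maps to LAI 0; above it the relation saturates.

Rasters are single-band float grids, north-up, NaN nodata, stored as
TIFF with the geotransform and acquisition date as JSON in the image
description tag.

## Spatialization

The scene is tiled into `cell_px × cell_px` blocks (default 10, the
published cell size in pixels; the ground area follows from the pixel
size rather than being hard-coded, since "10 × 10 pixels ≈ 100 m²" and
10 m pixels cannot both hold). A cell joins the segment owning the
majority of its non-background pixels (ties to the smaller label) and is
dropped when non-background cover is below 50%; majority rule and the
50% threshold are package choices, exposed as config. Per date, the
cell's observation is the mean LAI over the owning segment's pixels in
the cell. Calibration runs per cell — the finer of the two granularities
the method describes — with `cell_px` configurable up to whole-segment;
one shared season forcing is used for all cells (single-site
assumption). Cells with identical observation series (noiseless
synthetic scenes) share one calibration via a cache.

The yield raster is computed by applying each cell's regression (the
segment regime's, falling back to the all-cereal line) to the A_LAI
raster pixelwise; the mapping stage adds no arithmetic of its own, and a
test asserts the yield map equals the regression of the A_LAI map
bit-for-bit.

## Synthetic data

The generators emulate the study conditions the pipeline assumes:

- **Climate** — seasonal sinusoids with daily Gaussian noise: Ta from a
  winter minimum near 8 °C (mid January) to an early-summer maximum near
  28 °C (sd 1.5 °C); Rg between about 8 and 28 MJ m⁻² day⁻¹ (sd 2,
  floored at 0); 270 days from 1 November.
- **Plots** — (d0, ELUE, S_TT) uniform on d0 15–100, ELUE 0.8–4.0 g/MJ,
  S_TT 400–1200 °C day. This support is deliberately narrower than the
  calibration search box: ELUE below 0.8 gives near-dead crops, and late
  emergence combined with a very high senescence threshold describes a
  crop that never senesces within the observed season — neither occurs
  on real cereal plots, whose LAI peaks and declines between February
  and May.
- **LAI observations** — five dates spread over season days 30–200 with
  at least 14 days between visits (a two-to-three-week campaign
  cadence), jittered per seed; values are simulated LAI plus Gaussian
  noise, floored at 0.
- **Yield cohorts** — A_LAI uniform on [0, 75] LAI·day; regime labels
  65% irrigated (the share of irrigated plots among the reference
  campaigns' classified fields); yields from the regime's generating
  line (the reference regression coefficients) plus Gaussian noise of
  sd 7.5 qx/ha, the scale of the published validation error; clipped to
  the observed 11–85 qx/ha range. Clipping biases the mean slightly
  upward, so the A_LAI upper bound was solved once (by simulation of the
  clipped mean) to put the default cohort mean at the observed
  32 qx/ha; 75 LAI·day is the result.
- **Scenes** — rectangular segments on a grid with a background margin;
  all pixels of a segment share the segment's simulated trajectory plus
  optional pixel noise; truth tables carry each segment's parameters,
  A_LAI and implied yield.

What the generators do **not** emulate: spatial climate gradients,
within-plot parameter heterogeneity, mixed pixels at field boundaries,
atmospheric or view-angle effects on reflectance, non-Gaussian or
temporally correlated observation errors, and crop-type-specific growth
differences (wheat/barley labels are attached but share one growth
model). Passing tests therefore demonstrate internal consistency of the
chain — recovery of known parameters and regression lines under the
stated noise — not accuracy on real imagery.

## Problem sizes and numerical choices

The simulator oracle uses 20 random draws over a 270-day season;
calibration recovery uses 50 noiseless plots with 5 observation dates;
the end-to-end mapping check uses a noiseless 200 × 200-px scene with 8
segments; regression recovery uses 50 replicate cohorts of 200 plots per
stratum. Optimizer tolerances: Nelder–Mead `xatol` 1e-7, `fatol` 1e-13,
at most 200 evaluations per start; grid ties broken lexicographically at
1e-12. Trajectory states are double precision; rasters are written as
float32.

## Known limitations

- Point estimates only: no posterior or standard errors on the fitted
  (d0, ELUE, S_TT).
- The grain-filling activation rule (start when P_l reaches 0) is one
  reading of "partition after leaf growth"; it is isolated in
  `grain_filling_start_smt` and easy to change.
- With all five observations before senescence onset, S_TT is not
  identifiable (the objective is flat above a threshold); the optimizer
  then returns the tie-break value. The plot generator avoids this
  regime by construction; real late-senescing plots would need a later
  acquisition.
- No water-balance or soil-moisture stress term, no multi-year
  carryover, no CO₂ response; segmentation and land-use classification
  are consumed, not produced.
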