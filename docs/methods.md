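# Methods

This note documents the models and procedures implemented in `microheat`,
the assumptions behind the synthetic study generator, and the numerical
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Wet-bulb temperature

Hourly wet-bulb temperature is derived from hourly-mean dry-bulb *T* (°C)
and relative humidity RH (%) with Stull's empirical closed form, which
assumes standard sea-level pressure — appropriate for coastal-plain cities.
Aggregation order is: average raw records to hourly means first, then
derive *T*w from the hourly *T* and RH.

Inputs outside the fit's published rectangle (RH ∈ [5, 99] %, T ∈ [−20, 50]
°C) are computed anyway and flagged invalid rather than rejected: monsoon
humidity grazes 100 %, and dropping those hours would bias the very maxima
the analysis cares about.

The validation oracle (`wet_bulb_oracle`) solves the psychrometric balance
e(Tw) − γ·P·(T − Tw) = (RH/100)·e(T) by bisection on Tw ∈ [−40, T] to
10⁻⁴ °C, with the Magnus saturation-vapor-pressure form (Alduchov–Eskridge
constants: 0.61094 kPa, 17.625, 243.04 °C) and the aspirated-psychrometer
coefficient γ = 6.6·10⁻⁴ K⁻¹, P = 101.325 kPa by default. The oracle is
water-phase throughout; it is a validation instrument, not a replacement
for the closed form.

**Known limitation.** The closed form is only credible away from the
cold–dry corner of its rectangle. Over the warm subdomain (T ≥ 5 °C,
RH ≥ 10 %) it tracks the oracle within a mean |Δ| of about 0.31 °C and a
max of about 1.0 °C, and is monotone in both arguments; toward (−20 °C,
5 % RH) it departs by several degrees and loses monotonicity in RH. The
acceptance suite asserts the tolerance over the *full* rectangle and that
check is expected to fail; it is kept deliberately as an honest record of
the fit's domain. All study-relevant conditions lie well inside the warm
subdomain.

## Synthetic study generator

The generator emulates a one-year deployment in a monsoonal Indian city:
by default 45 dwellings stratified round-robin over 9 administrative zones
(a block partition of the grid), each dwelling carrying one indoor and one
outdoor hourly logger from 1 May through 30 April, on a 96 × 96 grid of
30 m cells.

Outdoor dry-bulb temperature is built additively:

- annual harmonic, amplitude 6 °C, peaking mid-May (day 135);
- diurnal harmonic, amplitude 5 °C, peaking 15:00; during monsoon months
  (Jul–Sep) the diurnal amplitude shrinks by 30 % (cloud cover), which is
  what lets wet-bulb minima peak in the monsoon as observed in the field;
- land-cover effects entering **separately on the daily minimum and
  maximum**: the min-side effect is weighted by the trough half of the
  diurnal cosine, the max-side by the crest half. Defaults: building
  volume +2.0 °C per unit normalized volume on the minimum and −1.0 °C on
  the maximum; NDVI −2.0 and +1.0 °C per NDVI unit. This encodes the
  canonical urban-heat-island sign reversal (built mass stores heat and
  warms nights; shaded, ventilated cores are cooler at midday) so the
  association stage has known signs to recover;
- a per-site Gaussian baseline offset (σ = 0.3 °C) and iid hourly noise
  (σ = 0.5 °C).

Indoor temperature is a first-order exponential low-pass filter of the
outdoor signal (smoothing factor 0.3, lag 1 h) plus a +0.7 °C insulation
offset; indoor land-cover effect sizes are half the outdoor ones
(`indoor_effect_scale` = 0.5). With smoothing 1, lag 0 and offset 0 the
filter is the identity, which the tests exploit. Two parameters reproduce
the observed diurnal contrast: indoors warmer from evening through
mid-morning, cooler through the afternoon.

Relative humidity follows a saturation-deficit-style anti-correlation with
the *total* (seasonal + diurnal) temperature anomaly at −2.5 % RH per °C
around a 55 % base, plus a +25 % RH additive boost in monsoon months,
clipped to [2, 99.5] %. Humidity responding to the seasonal anomaly makes
the pre-monsoon hot season dry and the monsoon humid, so seasonal wet-bulb
ordering comes out right.

The landscape programs a classic center–periphery structure: building
volume decays exponentially from the center (30 000 m³/cell core, e-folding
length 55 % of the half-width) with lognormal noise, while base NDVI rises
from 0.05 to 0.60 along the same gradient with additive noise; the noise
levels are set so the realized site-level Spearman correlation between the
two sits near −0.8, the regime reported for dense Indian cities. NDVI
carries a monthly greening factor peaking post-monsoon. Albedo is an
independent smoothed Gaussian random field (0.25 ± 0.05); water is a
meandering river plus scattered ponds, static across months. All landscape
noise scales with `noise_sd`, so a noise-free config yields strictly
monotone fields.

Missingness is injected as contiguous runs with geometric run lengths
(mean 6 h) until the target fraction (default 8.3 %, the worse of the two
deployment-scale gap rates the design emulates) is reached, with the
pre-gap values kept in hidden `T_true`/`RH_true` columns. Bursty gaps are
deliberately harder for imputation than pointwise missingness.

Everything is a pure function of (config, seed) via named substreams, so
all outputs are bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sensor calibration drift and radiative shielding
errors; spatial autocorrelation of temperature beyond the land-cover
gradient; real HLS radiometry, cloud masking, or building-footprint fusion
(index/volume fields are generated directly); weather (synoptic)
variability around the smooth harmonics; and any human behavior affecting
indoor conditions (fans, cooking, occupancy).

## Gap imputation

Per gap and per variable (T and RH independently): candidate donors — the
other loggers of the same location type — are ranked by Pearson
correlation with the target over the surrounding ±14 days of shared
non-missing hours; donors with < 48 h of overlap or zero variance are
excluded (an undefined correlation can never qualify a donor). For each of
the top-3 donors a least-squares map `target ~ a + b·donor` is fitted on
the window and the gap predicted as the correlation-weighted mean of the
donor predictions. Hours where T or RH has no donor coverage are left
missing and counted; a record is flagged imputed only when both variables
were filled, and *T*w is recomputed from the imputed pair. The ±14-day
window tracks seasonal drift in inter-site offsets; k = 3 trades variance
against contamination by poorly matched donors. All parameters are
config-exposed.

## Summaries

Daily extremes use calendar days with ≥ 18 valid hours (flags observed,
partial, and — unless excluded — imputed); the threshold prevents
half-days from biasing extremes. The monthly value of an extreme is the
**mean of daily extremes**, not the monthly absolute extreme, and the
seasonal value is the mean of its member months — means of means, stated
explicitly because summary bands could be read either way. Difference
surfaces average indoor−outdoor over all complete pairs per (month, hour);
by default imputed hours are excluded from these means, and both modes are
available. Timestamps are local standard time with no DST.

## Focal statistics and window selection

A focal value is the mean over all cells whose **centers** lie within
Euclidean distance `window_m` (a circular radius) of the sensor; for the
binary water mask this is the areal water fraction. Radius-based circular
windows match the sensor-centric design; the cell-center rule is simple,
deterministic, and cheap to verify against a brute-force all-cells scan,
which the tests do. Cells outside the raster are simply absent from the
denominator. Layers entering one computation must share their grid
exactly — mismatch is a hard error, never a silent resample.

Window selection: per (temperature metric, land-cover variable), the mean
of |ρ| over the 4 seasons × 2 locations is computed per window (missing
cells excluded, with a count) and the argmax window chosen; ties break
toward the smallest window, which is the most local and cheapest choice.

Significance stars use raw two-sided p < 0.05 (strict), matching the
no-multiplicity convention of the bar-chart display this stage mirrors; a
Benjamini–Hochberg option exists but is off by default.

## Additive models

The engine is a Gaussian penalized-least-squares GAM on P-spline bases:
cubic B-splines on equally spaced knots with second-order difference
penalties; cyclic variants wrap both basis and penalty (hour of day,
period 24; day of year, period 366, so the smooth is continuous across
midnight and New Year). Tensor products use the row-wise Kronecker basis
of the two marginals with one penalty — and one smoothing parameter — per
margin. Location-varying terms are separate smooths per level with
separate penalties (the more flexible reading of a by-factor smooth), plus
a parametric location intercept. Every smooth is centered by absorbing the
sum-to-zero constraint into the basis, keeping the design full rank next
to the intercept and factor terms.

Basis dimensions default to 8 per tensor margin (64 coefficients per
surface) and 10 per univariate smooth. A covariate with fewer than 4
unique values (the water fraction can collapse this way) is demoted to a
linear term with a log note rather than crashing. Smoothing parameters
minimize GCV = n·RSS/(n − edf)² over log-λ by bounded Powell search;
GCV was chosen over a REML criterion because the Gaussian fits here are
large-n and penalized-least-squares, where the two select nearly identical
λ and GCV needs no variance profiling — one unit test pins the engine
against R's mgcv on the same P-spline/GCV setup (fitted values agree to
~10⁻⁵). A relative ridge of 10⁻⁸ guards the normal equations.

Reported statistics: effective degrees of freedom edf = tr(H) of the
penalized hat matrix; AIC = n·log(2π·RSS/n) + n + 2·(edf+1) (Gaussian,
variance profiled); adjusted R² with n − edf residual dof. Nested fits on
identical response rows are compared by ΔAIC and an F statistic on
effective-dof differences — approximate by construction, since penalized
edf are not integer ranks, and labelled as such in outputs.

Model 1/2 responses are pooled hourly series per city with no site-level
term (the literal reading of the temporal model displays); the temporal
covariate is day-of-year with a cyclic basis. Models are fitted one city
per run; multi-city studies are two runs.

## Pipeline

`run_all` chains simulate → validate → impute → wet-bulb → summaries →
focal features → correlations → window selection → temporal GAMs → spatial
GAMs → comparisons, writing tidy CSVs plus a run log with stage timings.
Each CSV's first line carries the resolved config hash (paths excluded)
and seed. Any stage failure halts the run, names the stage, and leaves an
`INCOMPLETE` marker beside the partial outputs. Rasters are plain-text
ESRI ASCII grids; with cell size and origin in projected meters these
carry everything the analysis needs.

## Problem sizes used in tests and acceptance

The default study (45 sites × 2 loggers × ~8 784 h, 96 × 96 grid) is used
for the imputation-recovery (seeds 1–5), sign-recovery (10 seeds, gap
injection off — missingness is exercised by the imputation checks), and
end-to-end determinism measurements. The multi-seed model-comparison rates
(20 seeds per arm) fit the temporal models on 4 sites at 4-hourly
sampling — the location contrast there is so strong that this subsample
decides the comparison unambiguously — and the spatial models on the full
45-site seasonal table. The type-I measurement pushes 1 216 independent
null cells through the package's own correlation-and-stars path.

## Known limitations

- The imputation model is linear per donor; nonlinear indoor–outdoor
  coupling (e.g., threshold ventilation behavior) would degrade it.
- The F test between penalized fits is approximate; treat p-values near
  the threshold with care and prefer ΔAIC magnitudes.
- Seasonal feature averages assume the monthly composites are unbiased;
  no cloud-gap weighting is modeled.
- With very small networks (< ~10 sites) the spatial models are
  intentionally refused rather than fitted unstably.
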