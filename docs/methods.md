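# Methods

`lakemwat` emulates, at desk scale, the workflow of training a statistical
surrogate on a designed set of lake thermal simulations and projecting
thermal-stress risk for a lake population. Everything here is synthetic and
self-contained: the "teacher" simulator, the weather generator and the lake
table stand in for a process-based water-column model, downscaled climate
forcing and a national lake survey. This note records the models, their
parameters, the numerical choices, and what the synthetic setting does and
does not demonstrate.

## Response variable

MWAT (maximum weekly average temperature, also 7DADMax) is the highest
annual mean of seven consecutive daily maximum temperatures, the standard
chronic thermal-stress index for fish. It is evaluated on the layer
immediately above the thermocline — operationally, the layer deeper than
1 m just above the interface of maximum vertical gradient |dT|/dz when that
gradient reaches 1 °C·m⁻¹ (the common stratification convention;
configurable), or the bottom layer when the column is mixed. Windows are
trailing 7-day means confined within calendar years; multi-year runs are
reduced to one value per run by the mean of annual MWATs (the stable
choice; a "max" mode is provided because the reduction used for 30-year
simulations is ambiguous, and the choice is recorded in output metadata).
The two-layer simulator emits one above-thermocline value per day, which is
treated as that day's maximum.

## Synthetic climate

Daily weather per location follows

  T(d) = T̄ − A·cos(2π(doy − d₀)/365) + ε(d) + Δ_m(doy),

with a 365-day no-leap calendar, trough at day-of-year d₀ = 15, AR(1)
anomaly ε (ρ = 0.7, stationary sd 1.5 °C by default), and the scenario's
additive monthly delta Δ_m. Daily max/min bracket the mean by half the
diurnal range. Shortwave is a seasonal cosine with white noise (scenario
factors multiply it); wind is white noise about the location mean.

Two construction choices matter:

* **Scenarios share weather noise.** The AR(1) stream depends only on
  (location, length, seed), so a scenario differs from its baseline exactly
  by the monthly change signal — the delta method of scenario construction.
  This keeps the teacher's response to warming smooth and learnable.
* **Humidity follows the baseline temperature.** Specific humidity is
  computed from the location's mean relative humidity at the *unperturbed*
  temperature, so warming scenarios hold absolute humidity near historical
  levels (falling relative humidity). This is the warm-dry regime under
  which lake thermal risk is largest; with constant relative humidity
  instead, rising vapour pressure cancels most of the evaporative-cooling
  feedback and the response surface loses its temperature gradient.

Nine location presets span humid sub-tropical (annual mean 22.3 °C) to
cold high-elevation (4.6 °C). The desk-scale trio (subtropical,
continental, alpine) shares most non-thermal climatology so baseline
temperature is the dominant axis of the design, as in a station transect
chosen for thermal contrast.

## Two-layer lake simulator

The teacher integrates a daily epilimnion/hypolimnion energy balance:

* Equilibrium temperature
  E = T_air + a·SW·(1 − e^(−η·z_mix)) − b·u·max(e_s(T_epi) − e_a, 0),
  with solar gain a = 0.24 °C/(MJ m⁻² d⁻¹), evaporative coefficient
  b = 1.2 °C/(m s⁻¹ kPa), extinction η, wind u, and water-surface vapour
  pressure deficit. The epilimnion relaxes toward E at rate
  min(k₀/z_mix, 0.9) d⁻¹, k₀ = 0.87 m d⁻¹.
* Mixed-layer depth
  z_mix = clip(c₁/η + c₂·fetch^0.25 − c₃·max(T_epi − T_hypo, 0), 1 m, H)
  with c₁ = 1.75 m², c₂ = 0.57, c₃ = 0.38 m/°C and fetch = √Area.
* The hypolimnion relaxes toward the epilimnion at
  0.009/(H − z_mix) d⁻¹; the column mixes fully (volume-weighted) whenever
  the epilimnion is no warmer than the hypolimnion; water is floored at
  0 °C and surface exchange is attenuated 20-fold while air is below 0 °C
  (ice cap). The first forcing year is run twice and the spin-up copy
  discarded.
* The reported above-thermocline temperature subtracts a metalimnetic
  shading term s·(T_epi − T_hypo)·e^(−η·z_mix)·e^(−fetch/F₀)·min(H/D₀, 1)
  (s = 1.95, F₀ = 575 m, D₀ = 15.5 m): small, wind-sheltered, deep, clear
  lakes carry a cool gradient zone at the base of the mixed layer. This is
  the regime in which stronger stratification under warming can *lower*
  the above-thermocline maximum.

The coefficient set was calibrated once, as a whole, against four
qualitative targets — (i) the warming response of MWAT declines with
baseline July–August air temperature; (ii) at least one shipped small/deep
fixture preset shows ΔMWAT < 0 under a uniform +4 °C scenario; (iii) every
decrease case lies at geometry ratio < 10; (iv) uniformly warmer forcing
never lowers the multi-year mean epilimnion temperature — and then frozen
as the named `default` parameter set. Tests treat these constants as data.

Mechanistically, the declining temperature gradient comes from the
nonlinearity of saturation vapour pressure (evaporative damping grows with
water temperature), amplified at cold sites by ice-cover loss; the
decrease-prone corner comes from the shading term growing with summer
stability while the deep hypolimnion of an ice-bounded lake stays pinned
cold.

## Experimental design

Lake characteristics are sampled with a Sobol sequence (Joe–Kuo direction
numbers for dimensions 1–10 shipped as constants; Antonov–Saleev Gray-code
update; the all-zeros point is skipped by default, and tests that rely on
dyadic balance include it). Depth maps linearly onto [2, 30] m; area and
extinction map log-uniformly onto [0.1, 100] km² and [0.2, 4] m⁻¹, since
both span more than an order of magnitude. A 3-level factorial "archetype"
mode (27 lakes) is provided alongside the Sobol default. The training
experiment crosses locations × scenarios × lakes; the desk-scale default
is 3 × 3 × 27 = 243 runs of 10 simulated years each (the full-scale
analogue, 9 × 7 × 27 = 1,701, is a constructor call away but not the
tested default). The 1-D projections of the first 2^k Sobol points are
exactly dyadically stratified for the tested k ≤ 4; the full
(0, k, 3)-net property does not hold for the standard 3-D Sobol sequence
(it is a t = 1 sequence), so correctness is additionally anchored by
bitwise agreement with an independent reference generator.

## Predictors

Six features feed the GP by default: July–August mean air temperature
(day-of-year 182–243 on the 365-day calendar), January mean, annual total
FAO-56 Penman–Monteith reference evapotranspiration (mm/yr), extinction
(m⁻¹), geometry ratio Area^0.25/H_max (area in m², units m⁻⁰·⁵), and
maximum depth (m). A switch substitutes raw depth + area for the geometry
ratio. PET is aggregated to the mean annual total — an integral of the
radiation, humidity and wind information — because the aggregation window
is genuinely open; annual was chosen and kept. In the FAO-56 net-longwave
term the relative shortwave Rs/Rso is bounded to [0.3, 1.0] (the
standard's recommended limit), which also makes zero-radiation inputs
yield zero ET0 after the final floor at zero.

## Gaussian Process surrogate

Responses are normalized to zero mean and unit variance (constants stored
with the model); features are standardized per column. Kernels use ARD
lengthscales because the predictors carry heterogeneous units. The exact
log marginal likelihood is computed via Cholesky factorization with an
escalating jitter fallback (10⁻¹⁰ to 10⁻⁴ on the Gram diagonal; failure
beyond that is an error). Hyperparameters — signal variances,
lengthscales, the RQ shape α, and the observation-noise variance
(initialized at 0.1 on the normalized scale) — are optimized on the log
scale by L-BFGS-B with analytic gradients, 5 restarts by default, restart
lengthscales drawn log-uniform in [0.1, 10] of the standardized scale from
a seeded generator. Seven candidate forms (SE, RQ, Matérn 3/2, Matérn 5/2,
linear, SE+RQ, SE×RQ) are ranked by AIC = 2k − 2 ln L̂ with k the number
of optimized hyperparameters including noise (the convention is recorded in
output; alternatives exist since marginal-likelihood AIC is not uniquely
defined). Predictive 95 % limits are mean ± 1.96 sd on the denormalized
scale. Bootstrap cross-validation resamples training rows with
replacement, refits, and pools denormalized out-of-bag errors; replicates
with no out-of-bag rows are redrawn. Models serialize to JSON (kernel
tree, hyperparameters, normalization and standardization constants, and
the training matrix), sufficient to reproduce predictions bit-for-bit.

## Projection

Each lake in the synthetic table (areas log-uniform, depths uniform,
extinctions log-uniform; latitudes uniform on 28–48° N for location
assignment) is matched to the nearest climate location by latitude — the
synthetic analogue of per-lake downscaled grid cells. Monthly mean air
temperature and monthly PET totals are computed per ensemble member; the
headline mode predicts from the elementwise cross-member median series
(even member counts average the central pair), and a per-member mode
records member-wise predictions and their range. Exceedance uses a strict
">" at the 30 °C cold-water threshold. Per-lake 95 % limits are GP-only;
cross-member spread is reported separately rather than folded into them.
Feature vectors outside the training envelope are flagged as
extrapolations, and lake rows with missing characteristics are dropped
with a logged count.

## What the synthetic setting shows — and does not

Passing tests demonstrate that the pipeline's statistics are correct (the
GP matches dense-inverse oracles; MWAT matches exhaustive windows; PET
matches an independently coded standard; Sobol matches a reference
generator) and that the surrogate can emulate a smooth, physically
plausible teacher essentially perfectly (training R² ≈ 1.0 at n = 243,
versus 97 % for a real water-column model). The synthetic teacher is far
less noisy than a hydrodynamic model: residual variance, and hence
realistic cross-validation error magnitudes, are not reproduced — the
bootstrap's *unbiasedness* is the property carried over, not its error
scale. The frozen fixture contains decrease cases only in its small/deep
preset corner; the projected 898-lake cohort under the default ensemble
shows none, so the decreaser summary exercises its code path through
constructed cases in tests. Sub-daily dynamics, hypsography,
inflow/outflow budgets, snow and sediment heat flux, and real geographic
covariance of climate are all outside the generator, so quantitative
results (exceedance percentages, mean ΔMWAT) characterize the synthetic
cohort only.

## Problem sizes and determinism

Default sizes — 243 training runs of 10 years, n = 243 GP fits, B = 50
bootstrap replicates (B ≥ 10 enforced), 898 projected lakes — were chosen
so a full run completes in about a minute on one core while keeping the
design structure of the full-scale study. A single master seed expands
into per-stage seeds via a stage-name hash (crc32), recorded in every
output's metadata header; identical configurations reproduce outputs
byte-for-byte.
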