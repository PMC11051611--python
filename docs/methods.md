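# Methods

This note records the models implemented in `alanex`, the assumptions behind
them, the parameter choices that matter, and what the synthetic-data tests do
and do not demonstrate about real data.

## Exposure model

A participant's outdoor ALAN exposure is a functional of two inputs: a
georeferenced luminosity surface `NTL_p(x, y)` at pixel size `p` (band
radiance, nW·cm⁻²·sr⁻¹) and either a home location (residence-based
measurement, RBM) or a timestamped trajectory (mobility-oriented measurement,
MOM). Two spatial supports are offered: the *in-situ* value — the single
pixel containing the point — and the *buffer-zone average* — the area-weighted
mean over a disc of radius r,

    E_buf = ∫_buf NTL da / ∫_buf da .

MOM accumulates momentary exposures with left-constant temporal weights
`WT_i = (t_{i+1} − t_i)/D`, where `D = t_n − t_1` spans the whole recording,
the final fix carries weight zero, and the weights sum to one. Nighttime is
the open interval between local sunset and the next sunrise; momentary
exposures outside it are assigned zero while their intervals still count in
`D`. This is the *full-duration* mode and is the default; a
*night-renormalized* mode that divides by the nighttime weight instead is
available for sensitivity analysis (`duration_mode="night"`). The default
mode means MOM values scale with the nighttime share of the week (≈ 0.44 for
a June week at the Hong Kong anchor), which is worth remembering when
comparing MOM and RBM magnitudes.

Boundary conventions, fixed for bit-reproducibility: pixels are half-open
(`[x0, x0+p) × (y0−p, y0]`), so every point belongs to exactly one pixel; a
fix exactly at sunset or sunrise counts as daytime (a measure-zero choice).

## Buffer geometry

The disc integral is evaluated with exact closed-form disc–rectangle
intersection areas (the antiderivative `I(t) = ∫ √(r²−t²) dt` split at the
chord), so the estimator is accurate to machine precision rather than to a
supersampling or pixel-centre approximation; the area kernel depends only on
the disc centre's sub-pixel offset and is cached, which makes per-fix buffer
means over week-long trajectories affordable. Buffers that reach past the
raster edge or over nodata cells renormalize over the covered area — dropping
such participants would bias the synthetic experiments, and the covered-area
mean remains an unbiased local estimate under the surface's local
stationarity. Degenerate cases are handled algebraically (a window of
identical values returns that value exactly; a stationary trajectory reduces
to one disc evaluation times the night share), so two identities hold
bit-exactly, not merely to rounding: MOM equals RBM for stationary all-night
trajectories, and a constant surface returns the constant (times the night
share in full-duration mode).

## Solar events

Sunset and sunrise come from the NOAA general solar position calculations
(Julian-century ephemeris, equation of time, hour angle at zenith 90.833°),
evaluated at a fixed community anchor (default 114.1°E, 22.3°N, UTC+8).
Per-fix solar evaluation would change nothing material at city scale: across
a few kilometres, event times shift by well under a minute. Polar day/night
are reported as flags rather than timestamps.

## Cross-sensor calibration

Different sensors see different spectral slices of the same nightscape, so
calibrated radiances are made comparable by an affine model
`L_ref = a·L_pred + b` fitted by OLS on paired buffer-zone means (radius
1 km). Two design points matter:

- **Non-overlapping sample zones.** Overlapping buffers share texture and
  noise, leaving residuals spatially correlated and the nominal OLS standard
  errors roughly two-fold overconfident. `sample_buffer_pairs` therefore
  supports a minimum separation of `2r`, and the pipeline samples ~300
  disjoint 1-km zones from a citywide scene sized so that many fit — the
  sample size is capped by packing, which is also why a citywide campaign
  tops out near 300 zones.
- **Smooth district-scale variance.** The citywide scene carries a
  multiplicative brightness field with an 8-km correlation length. A shorter
  field (~1 km) interacts with the 500-m sensor footprint: block-averaging
  widens the effective smoothing kernel, attenuates the predictor's
  buffer-mean variance, and biases the recovered slope upward by many
  standard errors. With the 8-km field, slope/intercept recovery is unbiased
  with approximately standard-normal z-scores across seeds.

Cross-calibration is applied to the **final per-setting exposure scalar**
(`CC = a·raw + b`), not to the raster. Under an affine map, paired-test mean
differences and standard errors scale by `a` while t, df and p are exactly
unchanged — the signature pattern of raw vs cross-calibrated comparison rows.
Raster-level application is available (`apply_calibration` accepts rasters)
for sensitivity checks.

## Statistical batteries

Between-community disparities use Welch two-sample t-tests (no
equal-variance assumption, Welch–Satterthwaite df), with the brighter
community's mean first so differences read bright − dark. Within-participant
setting contrasts use paired t-tests; zero-variance differences return a
flagged degenerate row rather than aborting a battery. No multiple-testing
correction is applied by default — the battery is a sensitivity design, not a
discovery screen — but a Benjamini–Hochberg column is available
(`bh_correct=True`) and recorded in the output.

Health models are binary logistic regressions of dichotomized self-rated
health (healthy = top three of six categories) on one exposure setting plus
dummy-coded covariates (age, gender, income, education, marital status;
socio-economic status is operationalized as the income group). Exposure is
scaled per 100 nW·cm⁻²·sr⁻¹ so coefficients are readable; the scale is
recorded in every result. Fitting uses IRLS (GLM/binomial), which is markedly
more stable than Newton steps on small cohorts with few events;
non-convergence and (quasi-)separation are flagged on the result, never
silently accepted. Reference categories follow pandas' categorical ordering
with the first level dropped.

## The synthetic study

The generator produces, from a single seed, everything the analysis consumes.

**Nightscapes.** Two archetypes at 10 m resolution, means rescaled exactly to
their targets: an *old town* (mean 325.32 nW·cm⁻²·sr⁻¹) of 20-m bright street
canyons on an 80-m lattice, residential blocks whose ambient floor is lifted
by spillover, and sparse extra-bright commercial nodes (night markets) with a
100-m residential exclusion ring; and a *new town* (mean 210.78) of bright
venues of varying size on a much darker matrix, homes placed in a
uniform-distance band around the venues. Pixel texture is multiplicative
lognormal (CV 0.35 old town, 0.5 new town) — strictly positive and
right-skewed like urban radiance. A separate citywide lattice scene with the
smooth 8-km district field serves cross-calibration sampling.

**Sensors.** The fine product is the truth; 130-m and 500-m products are
block-mean degradations followed by the inverse affine distortion
(`y = x/a − b/a + ε`) with defaults a = 1.47, b = 23.14 (mid) and a = 2.20,
b = 11.71 (coarse) and iid pixel noise at CV 0.05 of the distorted signal.
The noise is deliberately small: buffer-mean regression of reference on
predictor suffers errors-in-variables attenuation proportional to the noise
variance, and at CV 0.05 the attenuation is negligible relative to the
standard error at n = 300, so recovery is an honest 2-SE check. The
distortion parameters are recorded as ground truth in the multisensor set.

**Trajectories.** One-minute fixes over 7 days. Daytime is a mean-reverting
wander around home (stationary spread ≈ 800 m) — daytime positions carry zero
exposure, so they only need to stay plausible and in-bounds. Nighttime is
spent at home except for excursions: their nightly count is Poisson with a
per-person Gamma-distributed rate (mean 2, shape 1.2 — many people stay in,
a few are out most evenings), each excursion walks out to one of 1–3
*habitual* spots drawn once per person within 500 m (people revisit the same
lit street or centre; this persistence is what gives nighttime mobility a
stable personal signature), dwells, and returns, for about an hour. Positions
snap to a half-metre lattice, consistent with GPS precision.

**Outcomes.** `healthy ~ Bernoulli(expit(intercept + β·(exposure/100 −
community mean) + covariate effects))`, with the true exposure defined as the
mobility-oriented 65-m buffer mean on the fine raster. Exposure enters as the
within-community deviation: the between-community brightness gap is treated
as confounded baseline, which matches the per-community health models that
estimate the effect. The default β = 30 per 100 units was set by a power
argument, not realism of the odds ratio: with within-community exposure
spread ≈ 0.13 scaled units and ~104 participants per community, it yields a
realized Wald z ≈ 4 for the true setting — strong enough to be identified
among 40 correlated models, weak enough to keep outcome probabilities off the
boundary (the Wald statistic is non-monotone in β, so pushing further buys
nothing). The intercept 2.3 keeps the realized healthy share near the ~0.88
level typical of self-rated general health in community cohorts.

**What the synthetic world does not emulate.** Real street networks and land
use, atmospheric and angular (eye-level) effects, indoor exposure, GPS
outages and urban-canyon multipath, seasonal nightscape change, and any
dependence of mobility on demographics. Passing tests therefore demonstrate
the correctness and statistical calibration of the pipeline, not the
substantive health findings one would obtain on real cohorts.

## Identifiability of the true setting

One end-to-end property deserves a candid note. When outcomes are generated
through the fine-scale mobility exposure, the corresponding setting
(MOM, 10 m, 65-m buffer) should attain the top |z| rank in the 40-model
health battery in most replicates. It does — at the default study seed the
fraction is ≈ 0.95 over 20 outcome replicates — but the margin depends on the
realized world: sibling settings (the 100-m buffer, the in-situ 10-m value)
track the true exposure at correlations of roughly 0.8–0.9, which caps the
per-replicate win probability at n = 104. Across different world seeds we
observed fractions from about 0.35 to 0.95 (mean ≈ 0.7). This mirrors the
real epidemiological situation: with ~100 participants per community, nearly
equivalent contextual settings are genuinely hard to distinguish, and a
single significant setting should be read as evidence about the *class* of
fine-scale mobility-oriented measurements rather than a sharp selection of
one radius.

## Problem sizes

Defaults were chosen so a full run is comfortable on one CPU: 650×650-pixel
(6.5 km) community scenes, a 4550-pixel (45.5 km) calibration scene, 104
participants per community with 10,080 fixes each, 300 calibration zones,
10,000 null replicates for test calibration, 500 replicates at n = 2000 for
logistic recovery, and 20 outcome replicates for the battery rank check. The
acceptance script runs the lot in a few minutes; the sub-pixel kernel cache
is what makes ~10⁵ exact per-fix buffer means per radius tractable.
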