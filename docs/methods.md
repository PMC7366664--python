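# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `cohmap`. Sections follow the pipeline order.

## Stimuli

**Screen geometry.** A flat monitor of extent *w* at distance *d* subtends
2·atan(w/2d); the default widefield screen (43 × 24 cm at 10 cm) spans
~130° of azimuth (0° nasal → 130° temporal) by ~100° of elevation (−50°
lower field → +50° upper field). `spherical_correction` maps flat screen
coordinates to spherical visual angles (azimuth = atan2(x, d), altitude =
atan2(y, √(x² + d²))) and its inverse is used to draw constant-angular-size
stimuli, removing the apparent shrinkage of flat stimuli near the screen
edges.

**RDKs.** Dots of 2° diameter move at 80°/s with a 60-frame lifetime; the
dot count is set so dots occupy 20 % of the screen (overlap ignored). At
coherence *c*, round(c·N) dots — a fixed seeded subset per coherence block —
share the coherent direction (one of 0°–315° in 45° steps); the rest hold
i.i.d. uniform directions assigned at birth. Dots that expire or exit are
reborn at uniform random positions with age reset. Coherence applies to
direction only; all dots share one speed. Widefield sessions use a blocked
(square-wave) trace visiting each of {3, 6, 12, 24, 48, 96} % once per
cycle in seeded random order, with blank-gray periods entered as coherence
0; two-photon sessions use a smooth trace that interpolates linearly
between randomly drawn target levels.

**Bars.** Retinotopy bars drift at 10.8°/s (width 9° for azimuth sweeps,
8° for elevation) carrying a 0.05 cpd checkerboard contrast-reversing at
2 Hz; receptive-field mapping uses 20°-wide flashing checker bars
(0.04 cpd, 5 Hz) at 30 elevation / 40 azimuth locations, 1 s per location
in seeded random order with 2 s gray between repeats. Generators return
frame-indexed logs; pixel rendering is optional because all downstream
synthetic analyses consume the logs.

## Synthetic ground truth

**Cortical sheet.** One large elliptical V1 patch (fractional radii
0.17 × 0.14 of the grid) plus up to six satellite patches (radius 0.09) at
fixed angles around it. Each patch carries an affine retinotopic gradient
spanning the central 90 % of the stimulus range (keeping preferences off
the span edges, where position phase wraps); the elevation gradient is the
azimuth gradient rotated ±90°, which sets the visual field sign, and signs
alternate between neighbours as in mirror-image maps (V1 +, LM −, AL +,
RL −, AM +, PM −, LI +). All areas cover almost the full visual field, so
distinct areas share coverage (they are separate retinotopic maps), while
a single area never covers any field location twice — exactly the
asymmetry the split/merge segmentation rule exploits.

**Widefield responses.** Per-pixel drive is the Gaussian receptive-field
overlap with the bar (σ = 10°, the coarse pooled receptive-field size of
widefield pixels) for bar sessions, or g(x, y)·m(t) for RDK/movie sessions
with the planted gain g = g₀ + s·elevation (defaults g₀ = 1,
s = −0.01 deg⁻¹, i.e. stronger coherent-motion drive in the lower field).
The drive is filtered by a causal single-exponential calcium kernel
(τ = 1.5 s, a GCaMP6s-like decay; unit DC gain, implemented as a first-order
IIR filter) and placed on a baseline with multiplicative Gaussian noise of
s.d. amplitude/SNR per frame. SNR is therefore defined as peak ΔF/F
response over per-frame noise s.d.; the headline recovery conditions use
SNR = 3.

**Two-photon fields.** Disjoint disk somata (radius 3 px) with receptive
fields on a planted retinotopic gradient (elevation along image rows),
von Mises direction tuning (default κ = 3), and coherence gains that again
decrease with elevation. Pixel fluorescence is cell · (1 + ΔF/F) on the
soma masks plus α·neuropil everywhere (α = 0.7 default, the planted mixing
coefficient) plus Gaussian pixel noise; the shared neuropil trace is slow
filtered noise, independent of the stimulus so that the α estimator is
unbiased. Rigid frame-to-frame motion (±2 px) is planted for the
registration stage to undo.

## Widefield retinotopy

**ΔF/F** divides by the per-pixel temporal median; non-positive medians
are flagged NaN, never divided.

**Fourier phase.** The response is projected onto e^(−2πi f t) at the sweep
frequency; a pixel with receptive field at position p along a forward sweep
(origin → far edge) responds with phase −2π·p/span plus a common delay.
Opposite sweeps are combined per pixel: re-referenced to mid-sweep, the
measured phases decompose as θ + δ and −θ + δ; the half-sum recovers the
delay δ and the delay-corrected forward phase recovers the position phase θ
on its full (−π, π] branch, so no spatial unwrapping is needed. This
requires |δ| < π/2 (a quarter sweep period), which a causal exponential
kernel always satisfies because its phase lag is −atan(ωτ) > −π/2. With a
planted 1.5 s kernel the residual position bias is below 2°. Pixels whose
response amplitude at the sweep frequency is under 4× the across-pixel
median (the noise floor) carry no retinotopic signal: their positions are
NaN and their field sign is set to 0 so they never cross the segmentation
threshold. (An optional quality-guided spatial unwrap is retained for
single-direction phase maps.)

**Field sign** is sin(∠∇elevation − ∠∇azimuth) with gradients of maps
smoothed by a NaN-aware Gaussian (σ = 2 px); angles use the array
convention atan2(∂/∂row, ∂/∂col), under which azimuth increasing along
+x and elevation along +y gives sign +1. Zero gradients give NaN.

**Segmentation.** |sign| > 0.3 per polarity, binary opening, connected
components, then iterative refinement: a patch is *split* (k-means on pixel
coordinates, k = 2) when its visual-field coverage is redundant — more than
10 % of occupied 10° × 10° field bins hold two or more spatially
disconnected pixel clusters of ≥ 5 px, the signature of two fused
retinotopic maps; adjacent same-sign patches are *merged* when they share
less than 10 % of their coverage (denominator: the smaller patch's
coverage). The refinement is idempotent on its own output. Surviving
patches are dilated without overlap (`expand_labels`, 3 px) to close
inter-area gaps and filtered at 100 px minimum size. Patches are named by
matching sign and centroid angle from the largest positive patch (V1)
against the canonical satellite layout, within a 45° angular tolerance;
unmatched patches are labelled "unknown".

## Motion analysis

**Reliability** R = mean over trials of CC(trial, leave-one-out mean);
degenerate (constant) trials contribute NaN terms that are excluded. For a
common signal of variance s² plus i.i.d. noise σ² over T trials,
E[R] ≈ s²/√((s² + σ²)(s² + σ²/(T − 1))) — the closed form the tests check
against at T = 20.

**Horn–Schunck flow** minimises the brightness-constancy residual plus a
smoothness penalty via the classic Jacobi iteration (defaults λ = 1,
100 iterations; these follow common toolbox settings — the original
publication of the method leaves them free). Spatial derivatives are
two-frame-averaged central differences. Note λ competes with the squared
image gradients: at very low image contrast the smoothness term dominates
and flow is biased toward zero, so callers working with unit-contrast
images should lower λ or normalise contrast. Motion energy is the
magnitude of the frame-summed flow vector (length frames − 1), resampled
to the imaging rate when used as a regressor.

**Coherent-motion correlation** M correlates the trial-averaged ΔF/F with
the regressor, after lagging the regressor by 0.5 s (configurable) to
compensate the indicator group delay. The methods define M on ΔF/F; an
optional "deconvolved" path instead inverse-filters the response with the
exponential kernel (the exact one-step inverse y_t − a·y_{t−1}, scaled),
and is off by default — both readings of the ambiguous source are
available. Gray periods enter the regressor as coherence 0. M is invariant
to per-pixel affine rescaling (a Pearson property), and block-shuffling the
regressor drives median |M| below 0.05 on synthetic sessions.

**Asymmetry.** Per-session, M is z-scored across masked pixels (z-scoring
leaves Pearson correlations unchanged but makes sessions comparable) and
correlated against preferred azimuth and elevation. With the planted
negative elevation gain gradient at SNR 3, the sign of r_elevation is
recovered in ≥ 95 % of seeded sessions while r_azimuth averages to zero.
Coherence-response curves (mean response per level, least-squares slope)
give a slope map spatially correlated (r > 0.8) with M — the two measures
agree — and the onset-amplitude map (post- minus pre-onset ΔF/F) provides
the visually-driven-activity control: a radially uniform planted drive
yields a uniformity index ≥ 0.8.

## Two-photon pipeline

**Registration**: per-frame integer shifts maximising the unnormalised 2-D
cross-correlation against the pixel-wise mean reference, iterated twice
(the reference sharpens after the first pass); shifts above 10 % of the
field flag the frame and are clamped.

**Activity map**: "modified kurtosis" — excess kurtosis with moments taken
about the temporal *median*, E[(F − med)⁴]/E[(F − med)²]² − 3. For a
quiescent pixel the median equals the mean and the score is ordinary
excess kurtosis (≈ 0 for Gaussian noise, 0 for a constant pixel); for
pixels with positive calcium transients the median stays at baseline, so
the score rises even when responses are frequent — unlike mean-centred
kurtosis, which is shift-invariant and loses sensitivity for dense
responses. Alternatives can be swapped in; this is the package's
definition of an estimator the source leaves unspecified.

**ROI extraction**: local-mean adaptive threshold (25 px window, floored at
mean + 1 s.d. of the map), binary opening, then distance-transform
watershed peeling with peaks at least half a cell diameter apart; somata
are gated on area (10 px … 4× the nominal soma area) and eccentricity
(≤ 0.95). On synthetic 50-cell fields recall and precision both exceed
0.9 at IoU ≥ 0.5.

**Neuropil correction**: the neuropil region is everything within 30 μm of
the ROI border excluding all ROIs (pixel size from the 425 μm field
width). Minimising |CC(F_soma − α·F_neuropil, F_neuropil)| over α ∈ [0, 1]
has the closed form α = clip(cov(F_soma, F_neuropil)/var(F_neuropil), 0, 1):
the correlation is affine in α with a single zero crossing at cov/var, so
the absolute value is minimised there (or at the nearer interval edge).
Minimising the *signed* correlation would run to α = 1 degenerately. A
1e-3-step grid search agrees with the closed form to 1e-3 and is kept as a
cross-check. **F₀** is the mode of a Gaussian KDE (Scott/Silverman
bandwidth) of the corrected trace on a 512-point grid, with a histogram
fallback implicit in the density evaluation; non-positive F₀ flags the
cell invalid.

**Receptive fields**: one-way ANOVA across bar locations screens for
location preference (p < 0.05; zero within-location variance with
differing means counts as responsive); passing cells get a bounded
least-squares 1-D Gaussian fit (amplitude, centre, σ, offset) whose centre
is the preferred location in degrees. Fit failure marks the cell
unresponsive.

**Session QC**: the observed |correlation| between receptive-field
preference and cell position along the retinotopic axis is compared with
the 99th percentile of 5000 position permutations; the position axis is
the image row, which is the axis the session's elevation bars map (the
source leaves the axis unspecified; fitting the axis from the same data
would bias the null, so it is fixed a priori). Null false-pass rate is the
nominal 1 % (≤ 2 % observed over 200 null sessions).

**Direction tuning**: per-direction coherence correlations M_d; the
preferred direction is the angle of Σ_d max(M_d, 0)·(cos θ_d, sin θ_d) —
negative correlations are floored at zero because null-direction responses
carry no directional evidence — and the best-direction correlation is the
maximum over the finite M_d. Planted von Mises preferences are recovered
within half a 45° step at κ ≥ 2 and SNR 5.

**Hodges–Ajne test**: m = minimal count in any closed half-circle,
computed from the sorted angles. The p-value uses the exact tail
(n − 2m)·C(n, m)·2^(1−n) for m < n/3 (evaluated in log space) and the
large-sample approximation √(2π)/A·exp(−π²/8A²), A = π√n/(2(n − 2m)),
otherwise; both branches agree with the simulated null to Monte-Carlo
accuracy. Because m is integer-valued, the attainable test level is
discrete: at n = 100 the largest rejection region with p ≤ 0.05 has true
level ≈ 0.03, and the level approaches the nominal 0.05 only for large
samples (≈ 0.044 at n = 3461, the cell count at which the package's
calibration is demonstrated). This conservatism is a property of the test
itself, not of the implementation.

**Elevation-binned tuning**: best-direction correlations are z-scored
across cells, averaged in 10° elevation bins (mean ± s.e.m.), and a
least-squares line is fit on the cell-level data with 1000-resample
bootstrap 95 % confidence intervals for slope and intercept (percentile
method; coverage is slightly below nominal at small cell counts, as usual
for percentile bootstraps).

## Statistics

All t tests are two-tailed. The two-sample test uses the pooled-variance
(Student) form to match Hedges' g pooling — g = J·(mean₁ − mean₂)/s_pooled,
J = 1 − 3/(4(n₁ + n₂) − 9) — with Welch available via a flag; one-sample
tests report the analogous one-sample g. Bonferroni thresholds are α/n.
Map z-scoring subtracts the masked mean and divides by the masked s.d.
Type-I error of the one-sample test is calibrated to 0.05 ± 0.015 over
2000 null simulations.

## Determinism and problem sizes

Every random operation draws from a generator derived deterministically
from the master seed and a stage name (`stage_rng`), so the full pipeline
is byte-reproducible under a fixed seed. The test and acceptance harnesses
run at desk scale by design: 64 × 64 sheets (48 × 48 for the 100-session
asymmetry sweep), 6 sweep cycles per bar direction, 3 coherence cycles ×
4 trials per RDK session, and 96 × 96 two-photon fields with 20 cells —
sizes at which all planted effects are comfortably recoverable and a full
run completes in minutes. The `paper_like` preset scales the grids up
(200 × 200 widefield, 256 × 256 two-photon).

## What the generators do not emulate

The synthetic data are a testbed, not a tissue model: noise is white and
multiplicative (no hemodynamic absorption, vascular artifacts, photon shot
statistics, or slow drift); there are no eye movements, so retinotopy is
perfectly stationary; calcium dynamics are a single exponential (no rise
time, saturation, or spike-level nonlinearity); cell responses are dense
compared with sparse cortical firing; and neuropil is a single shared
trace rather than a spatially varying field. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every artifact of real widefield or two-photon
data. Allen CCF atlas warping, eye tracking, hemodynamic correction, and
manual ROI curation are out of scope; cross-session comparison happens in
the synthetic common frame.
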