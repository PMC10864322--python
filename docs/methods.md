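# Methods

This note documents the models implemented in `prfaniso`, the choices made
where the design was genuinely open, and what the synthetic-data studies do
and do not establish.

## Scientific setting

A population receptive field (pRF) summarises the region of visual space
driving one fMRI voxel. Two topographic anisotropies can elongate spatial
representations: *radiality* (elongation along the fixation-to-centre axis)
and *co-axiality* (elongation along the stimulus's texture orientation).
Because orientation preference and polar angle are correlated in early
visual cortex, the two are confounded unless the mapping stimulus's
orientation is manipulated in polar coordinates — hence the radial- and
tangential-orientation conditions that run through every module. The same
question is asked of perception with a two-alternative circularity
judgment, and the package's group analysis relates the two levels across
individuals.

## Stimulus model (`prfaniso.stimulus`)

The mapping stimulus is a ring- or bowtie-wedge-shaped aperture of Gabor
patches stepping once per TR (1.5 s) and completing a cycle in 24 s
(16 frames/cycle, 9 cycles/scan, field radius 7.9°). Ring apertures visit
16 eccentricities from 1° to 7.3°; the Gabor minor radius (2σ of the
contrast envelope) grows linearly from 0.30° to 0.57°, and each step equals
the current half-width so that every location is stimulated for 2 TRs.
Wedge apertures hold 13 Gabors in two interleaved (zigzag) eccentricity
sets with their own linear size rule (0.30° at 1° to 0.69° at 6.64°) and
rotate in 11.25° steps, covering a half-turn per cycle (the mirrored bowtie
half covers the rest). Carrier spatial frequency follows
SF(e) = 3 − (5/6)·ln e cycles/degree.

Numerical/representational choices:

- The published eccentricity/size ladders are shipped as canonical
  constants. The generative step rule is exposed for testing; resolving the
  implicit "shift by the half-width" step with the radius evaluated at the
  midpoint of consecutive centres regenerates the published ladder to
  <0.02°.
- The forward model consumes only the binary envelope indicator
  s(x, y, t); the four Gabor packs appear sequentially within every TR, so
  the per-frame mask is the union of the full disc set at the current
  aperture position. Carrier phase, orientation and sub-TR flicker are
  metadata.
- Default raster: 0.1°/pixel (0.25°/pixel in the simulation studies; with
  matching generator and fitter grids the discretisation cancels in
  recovery studies). A grid step at or above the smallest Gabor radius is
  rejected.
- Because the ring is rotation-symmetric and the wedge is a mirrored
  bowtie, the stimulus cannot distinguish a pRF centre from its point
  reflection through fixation. Both optima are exact; every anisotropy
  quantity (σ_radial, σ_tangential, AR, all indices) is invariant to the
  reflection, and recovery studies score centre error modulo it.

## Hemodynamic impulse response (`prfaniso.hirf`)

h(t) is a difference of two gamma densities with six free parameters:
shape/scale of the positive lobe, shape/scale of the undershoot, the
undershoot's relative amplitude, and an overall amplitude (an additive
baseline is removed by mean-centering and not counted). Canonical start:
(6, 1, 16, 1, 1/6, 1), peaking near 5 s. The estimation scan is a 3-s
full-field pulse every 24 s, nine pulses, 144 frames with the first 16
discarded. Prediction convolves the pulse train at 10× TR oversampling
(the 3-s pulse would alias at TR resolution) and decimates to frame
onsets. Fitting is bounded Nelder–Mead over the five shape parameters with
the amplitude profiled in closed form per candidate; non-convergence is
flagged on the result, not raised. Noise-free self-recovery is exact to
<1% in kernel shape.

## pRF model and two-stage fit (`prfaniso.prf`)

Predicted response: y(t) = h(t) ∗ Σ_{x,y} s(x,y,t)·g(x,y), with g an
elliptical Gaussian whose axes are frozen to the radial/tangential
directions of its centre: widths σ√AR (radial) and σ/√AR (tangential), so
σ_radial·σ_tangential = σ² identically. Cost is 1 − r between observed and
predicted series, making fits invariant to signal scale and offset.

- Stage 1 (isotropic) localises the centre: a pre-evaluated coarse grid
  (centres at 1° spacing × σ ∈ {0.5, 1, 2}) seeds bounded Nelder–Mead over
  (eccentricity, angle, σ), with eccentricity ∈ [0.7°, 7.9°] and
  σ ∈ [0.1°, 5°].
- Stage 2 freezes the centre and its radial axis and optimises (σ, ln AR)
  with |ln AR| ≤ 2 (natural log; the bound is configurable and results are
  stable when widened to 3).
- Bounds are enforced with sine-transform reparameterisation (the bounded-
  simplex contract); cost tolerance 1e−6, parameter tolerance 1e−3 (a
  thousandth of a degree).
- Convolution edge handling treats each scan as preceded by copies of its
  final cycle (steady state), matching an acquisition whose initial
  transient frames were discarded.
- Series from several scans are concatenated per orientation condition and
  fitted once per voxel per condition.

Noiseless recovery: centre to <0.05° (modulo the reflection above), σ to
<5%, AR to a few percent at moderate eccentricity. One property of the
frozen-centre scheme is worth knowing: under elliptical truth the isotropic
stage-1 centre acquires a small radial bias (a few hundredths of a degree),
and beyond ~4° eccentricity the tangential width becomes hypersensitive to
exactly that error — a ±0.03° radial centre displacement moves σ_tangential
by ∓15% at 5° eccentricity, while refitting with the true centre recovers
both widths to <0.5%. Voxel-averaged indices inherit only the net effect,
but single-voxel widths at far eccentricities should be read with this in
mind. Per-voxel AR is only weakly identified at
realistic noise: the predicted series for AR = 1.3 and AR = 1/1.3 correlate
at >0.99, so single-voxel sign judgments saturate near 60–80% accuracy even
for an ideal observer, and reliable anisotropy estimates come from
averaging over many voxels — as in the real analysis.

## Voxel screening (`prfaniso.selection`)

A voxel is analysed only if, in *every* traveling scan, its correlation
with the best-fitting stimulus-frequency sinusoid exceeds 0.4 and its
Fourier SNR (stimulus-bin amplitude over the mean amplitude of all bins at
≥3× the stimulus frequency) exceeds 2; if its hemodynamic phase on the
pulsed scan lies within ±π/4 of the fitted HIRF's predicted response phase;
if its variance is not in the top decile (draining-vein proxy;
linear-interpolation percentile, ties retained); and if the final pRF fit
reaches r > 0.25 in every scan. Each rejection carries a reason code, and
selection is monotone in every metric. The ≥3f band (rather than the single
3f bin) and the per-scan AND-combination are the defaults; both
alternatives are available behind options.

## Observer model (`prfaniso.psychophysics`)

Perceived log aspect ratios of probe and standard are Gaussian with common
SD σ and a common multiplicative bias β (the perceived AR of the physically
isotropic standard): X_P ~ N(μ_p + ln β, σ), X_S ~ N(ln β, σ), and the
standard is chosen when X_S² < X_P², plus a small additive constant
(lapse ∈ [0, 0.2]) with probabilities clipped away from {0, 1}. The outer
integral over X_P is evaluated with 201-node Gauss–Legendre quadrature
split at x = 0, where the integrand has a derivative kink; agreement with a
10⁷-sample Monte-Carlo oracle is ≲10⁻³. The psychometric curve attains its
minimum at the probe AR 1/β, so β itself is the perceived AR and ln β is
the perceptual radial bias index. MLE fits (σ, β, lapse) per orientation
condition by bounded Nelder–Mead from multiple β starts on the per-level
binomial likelihood.

Open-point resolutions: all logs are natural (a literal mixed-base variant,
with the bias entering as log₂ β, is available via `log_base="mixed"` and
reports the same perceived AR after bias conversion); the constant-σ form
is the default (the magnitude-scaled-noise phrasing is not implemented as
the printed equations carry a single σ); the lapse constant is additive
with clipping, bounded [0, 0.2].

## Indices and group analysis (`prfaniso.anisotropy`)

RI_pRF = σ_radial − σ_tangential (subtractive, in degrees; a divisive
log-ratio variant is exported alongside and always agrees in sign),
averaged over selected voxels (unweighted across areas when areas exist;
count-weighting is an option). CMI_pRF = RI_pRF(radial cond) −
RI_pRF(tangential cond). RI_perc = ln AR_perc; CI_perc flips the sign in
the tangential condition; mean CI averages the two conditions. These
identities are enforced as exact invariants on every pipeline output.
Group statistics: paired t (RI_pRF between conditions), one-sample t
(RI_perc per condition), Pearson r with one-tailed p for a positive
association plus regression lines (RI_perc on RI_pRF per condition;
mean CI on CMI), and 95% t-intervals on means. Zero-variance inputs yield
flagged NaNs, never silent values.

## Synthetic cohorts (`prfaniso.synthetic`)

The generator inverts the package's own forward models. Per individual, a
latent radial bias (mean 0.11°, SD 0.12°) and co-axial modulation (mean
0.055°, SD 0.10°) set the per-condition target RI; each driven voxel gets a
random centre (eccentricity 1.5–6°), width (0.5–1.1°), and the AR that
realises the target RI at its width, with 0.10 log-units of voxel-level
jitter. Index means/SDs and the perceptual intercepts (+0.26 / −0.20 log
units) match the magnitudes reported for early-visual-cortex cohorts of
this size. BOLD series are the forward model scaled to a 2-psc peak plus
i.i.d. Gaussian noise calibrated to a Fourier SNR of 6 (noise SD ≈ 0.8 psc,
typical of 3-T cortex); "noise" voxels carry the same noise floor and
"vessel" voxels 3× the typical driven total variance. Perceptual biases
follow a linear per-condition link ln β = intercept + slope·(RI_pRF −
mean) + ε with the residual SD chosen to give a specified latent
correlation (default ρ = 0.6). Trials are generated by drawing X_S, X_P and
applying the decision rule; the additive lapse is realised by flipping
probe choices to the standard with the level-dependent probability
c/(1 − p_model), so the generator's marginal choice probability equals the
likelihood's additive form exactly. All randomness flows from one seeded
generator; identical seeds give identical bundles.

What the generator does *not* emulate: temporally correlated (AR(1)-type)
physiological noise, voxel-to-voxel noise correlations, hemodynamic
nonlinearity, eye movements, and retinotopic area structure (the synthetic
cortex is a single area). Passing recovery tests therefore demonstrates
correctness of the estimation chain under the model's own assumptions, not
robustness to every property of real data.

## Study problem sizes

The validation studies are scaled to single-CPU minutes: simulation raster
0.25°/px; two traveling scans (one ring, one wedge) per orientation
condition in the cohort studies versus four in the full design; 24 driven +
3 noise + 3 vessel voxels per synthetic individual (roughly 10–15 survive
screening, versus ~500 analyzed voxels per observer at full scale); 500
trials per condition; 27 individuals; 3 cohort replicates. The
threshold-noise sign study uses the full four-scan condition design at
Fourier SNR 2 with 200 voxels. At these sizes the cohort-level correlation
estimate carries both the genuine n = 27 sampling spread (z-SD ≈ 0.2) and
mild attenuation from per-individual measurement noise; the coverage check
accounts for the former explicitly and the latter is visible as a mean r̂
slightly below the latent ρ.

## Known limitations

- Per-voxel aspect-ratio signs are unreliable at threshold noise (an
  information limit of the mapping stimulus, quantified above); only
  voxel-averaged anisotropy is interpretable there.
- pRF centres are identified modulo point reflection through fixation.
- The elongation axis is constrained to radial/tangential; free-angle
  ellipses, compressive spatial summation and surround suppression are out
  of scope.
- The real-data adapter (reading deposited preprocessed series) is not
  implemented; all inputs are synthetic or user-supplied tables.
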