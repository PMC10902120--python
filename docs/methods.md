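# Methods

## DESS signal model

The steady state of the two-echo DESS sequence is modeled under ideal
spoiling: exactly one cycle (2π) of spoiler dephasing per TR across each
voxel, no diffusion attenuation, no magnetization transfer, and a single
T2 component. Two independent computations are provided.

The *closed forms* use the standard SSFP parameterization with
E1 = exp(−TR/T1), E2 = exp(−TR/T2) and flip angle α:

    p  = 1 − E1 cos α − E2² (E1 − cos α)
    q  = E2 (1 − E1)(1 + cos α)
    r  = (1 − E2²) / sqrt(p² − q²)
    S1 = M0 tan(α/2) [1 − (E1 − cos α) r]      (transverse magnitude just after the pulse)
    S2 = M0 tan(α/2) [1 − (1 − E1 cos α) r]    (just before the next pulse)

The *oracle* simulates isochromats spanning the 2π of spoiler dephasing
through RF/precession/relaxation cycles until both echo amplitudes change
by less than a relative tolerance per TR (default 1e-9, iteration cap
well above 10·T1/TR). The two agree to ~1e-7 relative over the validation
grid T1 ∈ {1400, 1600} ms × T2 ∈ {3..300} ms × flip ∈ {15°, 25°, 35°};
the suite enforces 0.1%.

**Echo timing.** S+ is sampled TE after the pulse and S− TE before the
next pulse, assuming echo-centered (gradient-refocused) readouts:
S+ = S1·e^(−TE/T2) and S− = S2·e^(+TE/T2), because every coherence
pathway contributing to the pre-pulse echo refocuses exactly at the
pulse. This symmetric convention yields the 2(TR−TE) exponent of the
ratio equation.

**Acquisition defaults.** The study's exact protocol constants are in
supplementary material not available here; the defaults TR = 20 ms,
TE = 5 ms, flip = 20° are typical for musculoskeletal DESS and are
configurable everywhere; all outputs record the parameters used.

## Dictionary correction

The ratio equation T2 ≈ −2(TR−TE)/ln(S−/S+) systematically
underestimates the full-model T2 (verified for every grid entry at the
defaults). The correction dictionary tabulates, for each actual T2 on the
3–300 ms grid in 0.1 ms steps (2,971 entries), the ratio-equation value
of the analytic signals at the assumed T1 — 1600 ms for nerve, 1400 ms
for muscle. Lookup is nearest neighbor in approximate-T2 space (the
0.1 ms grid makes interpolation pointless and keeps outputs on the
printed grid); strict monotonicity of the approximate values is enforced
at build time and a violation is a hard error, never silently repaired.
Out-of-range values clamp to the grid ends and carry clamp flags into the
T2 map, where ROI statistics report them and can exclude them (included
by default). Unusable voxels (non-positive signal, ratio ≥ 1, background)
carry NaN — never 0, which would look like a legal T2.

## MESE fitting with B1+ correction

CPMG trains are computed with the extended phase graph: excitation
90°·b1, refocusing pulses 180°·b1, unit crusher dephasing per half echo
spacing (crusher-selected pathways only; slice-profile integration is not
modeled). At b1 = 1 the train is exactly mono-exponential; the EPG
implementation matches an independent brute-force isochromat CPMG
simulation to machine precision. The corrected fit grid-searches
T2 (3–300 ms, step 0.5) × B1 (0.7–1.3, step 0.01) with the amplitude
profiled out analytically; grid bounds and steps are configurable. The
magnitude curves are invariant under b1 → 2 − b1, so B1 is identified
only up to that reflection; T2 is unaffected. The log-linear fit is
retained as the naive comparator that the correction must beat whenever
b1 ≠ 1.

## Synthetic phantoms, noise, and the surrogate denoiser

Phantoms are boxes and cylinders rasterized by voxel-center membership at
0.3 × 0.3 × 1.6 mm, with later structures taking precedence on overlap.
They emulate geometry and ground-truth relaxation only — no realistic
anatomy, coil sensitivities, partial-volume fat, or motion — so passing
tests demonstrate correctness of the estimation chain, not robustness to
clinical confounds.

Rician noise replaces each voxel v by |(v+g1) + i·g2| with iid Gaussians
of SD σ in both quadratures, the same σ for both echoes (single-coil
magnitude model; sum-of-squares multi-coil statistics are out of scope).
σ may be given directly or via SNR defined as mean muscle S+ over σ; the
bias experiments run at SNR 20, where the Rayleigh floor and the
convexity of the ratio→T2 transform bias ROI-mean T2 measurably upward.

The vendor deep-learning reconstruction is deliberately **not**
re-implemented. The surrogate is a declared classical denoiser (isotropic
Gaussian, SD 1 voxel by default, or non-local means); at the default
strength it cuts uniform-region noise SD by well over 2× with <1% mean
change. Only the direction of the induced T2 change — noisy above truth,
denoised closer to truth — is claimed to correspond to the reported
behavior of deep-learning reconstruction; magnitudes are not comparable.
On thin structures the spatial filter introduces partial-volume blurring
(see the README example), a known limitation of the surrogate.

## Cohort generator

Each subject contributes eight condition cells (nerve/muscle ×
abnormal/normal × standard/DLR reconstruction) whose marginal means and
SDs default to the study's reported values. The cells of a tissue are
coupled by a Gaussian factor model:

* a standardized EMG-grade factor loads on the two abnormal-muscle cells
  with loading a = slope·sd(grade)/SD(cell), making E[T2 | MUR grade]
  exactly linear at the configured slope (default 9.10 ms/grade) while
  keeping the marginal moments exact;
* a correlated residual supplies the reconstruction-pair correlation
  (default 0.99) and the abnormal-vs-normal within-subject correlation
  (defaults: nerve 0.95, muscle 0.70). Infeasible combinations (residual
  correlation above 1, non-PSD residual matrix) raise errors.

The study reports no within-subject covariance, so these correlations
were set by calibration to its reported inference pattern: via the
noncentral-t power function, they are the values at which a cohort of 25
subjects reproduces the abnormal-vs-normal Bonferroni-adjusted p < 0.001
(DLR reconstruction) for both tissues in ≥95% of replicates. Lower
values (e.g. 0.5 throughout) cannot reproduce that pattern at n = 25
regardless of seed — the nerve comparison's power tops out near 0.985
even as the correlation approaches 1, which also means reproducing all
four cross-reconstruction pairs simultaneously is not attainable; the
reproduction experiments therefore use the DLR pair.

The MUR grade marginal defaults to (0.05, 0.50, 0.40, 0.05) over grades
0–3. A uniform marginal is infeasible: the slope would then contribute
more variance (9.10²·1.25) than the configured abnormal-muscle SD (9.11²)
allows, and the generator raises an error if asked for it. FP/PSW grades
(0–4, per-muscle maximum of the two) are drawn independently of T2,
matching the reported absence of association. Nerve cells carry no grade
loading (the reported nerve association was not significant, and a
loading of that size would cap the nerve within-subject correlation below
the calibrated value).

Two raters are modeled as the latent condition value plus independent
noise sized so the inter-rater correlation is 0.95 (configurable);
analyses use the rater average, whose SD is inflated ~1.3% over the
latent SD — the moment tests account for this. Additive rater noise
leaves the grade slope unattenuated. All randomness flows through
explicit seeds; no global state.

## Statistics

Pearson, Kendall tau-b and paired t-tests come from scipy; the one-way
within-subjects ANOVA from statsmodels (AnovaRM), verified in tests
against the definitional sums of squares. No sphericity correction is
applied by default; Greenhouse–Geisser is available behind a flag (the
epsilon computed from the double-centered condition covariance, checked
against pingouin). Type-I calibration is demonstrated on exchangeable
(compound-symmetric) null cohorts, where the uncorrected F is exact; the
study-condition covariance is deliberately non-spherical, and the
uncorrected F would be anticonservative there. Bonferroni adjustment is
min(1, 6·p) over the six pairs of four conditions; a zero-variance pair
is reported with an error marker rather than aborting the other pairs.

"Generalized linear model" associations are identity-link Gaussian fits
(ordinary least squares) of T2 on the numeric 0-based grade, since the
quantity of interest is a linear ms-per-grade slope. The sample-size
routine scans n upward and returns the first n whose exact noncentral-t
power (df = n−1, noncentrality (δ/σ_d)√n) reaches the target; at the
study's inputs (δ = 5.5 ms, σ_d = 6.9 ms, α = 0.05, power 0.80) it
returns n = 15, consistent with (and below) the study's stated
requirement of 16, which may include a rounding or safety margin.

## Problem sizes

The validation suite uses a 36-point signal-model grid with 2,000
isochromats at tolerance 1e-9; 20 noise replicates on a 48×48×8 phantom
for the bias-direction experiment; 500 null and 100 study-condition
cohort replicates at n = 25; and 10,000 Monte-Carlo replicates for the
power cross-check. These sizes were chosen so the whole suite runs in
well under a minute of statistics and a few tens of seconds of physics
while leaving every Monte-Carlo band at 3 standard errors or better.

## Known limitations

* Diffusion weighting of S−, fat suppression, flow, and multi-component
  T2 are not modeled; the dictionary assumes a single fixed T1 per tissue
  class, and a wrong T1 assumption biases the corrected T2 (demonstrated
  in tests).
* The surrogate denoiser shares no mechanism with vendor deep-learning
  reconstruction; conclusions transfer in direction only.
* The cohort generator's correlation structure is calibrated, not
  measured; it should not be read as an estimate of the true
  within-subject covariance.
* MESE slice-profile effects are ignored; B1 is identified only up to
  the 2 − b1 reflection.
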