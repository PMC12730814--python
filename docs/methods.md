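# Methods

## Signal models

Both models have exactly three free parameters, matching the degrees of
freedom of the pixel-wise fit used on the scanner data this package
emulates.

**T1 (variable TR).** `S(TR) = a · (1 − b · e^(−TR/T1))`. Saturation
recovery with a free recovery fraction `b` is the standard three-parameter
model for a variable-TR fast-spin-echo series: the constant, short echo
time (3 ms) multiplies every image by the same T2-decay factor, which `a`
absorbs, and `b` absorbs incomplete saturation or residual inversion
effects (`b = 1` is ideal). The model is monotonically non-decreasing in TR
for `0 < b ≤ 1`.

**T2 (variable TE).** `S(TE) = a · e^(−TE/T2) + c`. Monoexponential decay
with a constant offset; on magnitude images the Rician noise floor does not
decay to zero, and `c` absorbs it. The fixed TR of 10,000 ms leaves a small
residual T1 weighting (at T1 ≈ 1350 ms the recovery factor is 0.9994) that
`a` absorbs; the model treats the two contrasts as separable.

All times are milliseconds; signal is in arbitrary scanner units.

**Acquisition grids.** The default protocol is 12 TR values
(50, 100, 200, 500, 700, 1000, 1500, 2000, 3000, 5000, 10000, 15000 ms) at
TE = 3 ms, and 11 TE values
(10, 20, 42, 68, 85, 102, 130, 160, 200, 230, 260 ms) at TR = 10,000 ms.
Grids are user-overridable through the YAML config
(`tr_values_ms`/`fixed_te_ms`, `te_values_ms`/`fixed_tr_ms`).

## Phantom simulator

A phantom is a set of disjoint piecewise-constant tissue regions (discs)
on a zero-signal background. Each pixel's noiseless value is the forward
model evaluated at its region's ground-truth (T1, T2, proton density);
noise is Rician, `out = sqrt((S + g1·σ)² + (g2·σ)²)` with independent
standard-normal `g1, g2` — the exact statistics of magnitude-reconstructed
MR data with complex Gaussian channel noise. At zero signal this reduces to
Rayleigh with mean `σ·sqrt(π/2)`; at SNR ≥ 50 the magnitude bias is below
0.5 % (both properties are asserted by the test suite).

Defaults and their rationale:

- **Tissue ground truths**: the per-group ex vivo reference means and SDs —
  healthy 1351.7 ± 271.1 / 93.5 ± 20.3 ms, NMIBC 727.7 ± 145.0 /
  78.5 ± 20.4 ms, NMIBC after PDT 368.9 ± 65.2 / 55.7 ± 6.1 ms (T1/T2).
- **Noise scale** σ = 20 at proton density 1000, i.e. SNR 50 at peak
  signal. No scanner noise level is published for this protocol; SNR 50 is
  a realistic figure for a small flex coil on a 1.5 T system with NEX = 2,
  and it is a config parameter (`noise_sigma`).
- **Geometry**: 64 × 64 matrices at desk scale (the scanner matrix
  320 × 224 is available via config); cohort phantoms hold one disc of
  radius `min(shape)/5` (~500 pixels), three-tissue phantoms three discs of
  radius `min(shape)/8`.
- **Cohort draws**: per-sample (T1, T2) from a normal truncated at zero
  with the group's mean/SD (only group moments are known; rejection
  sampling, means are many SDs above zero). The NMIBC and NMIBC-after-PDT
  specs with the same index share a sample_id, modelling the same physical
  specimen measured before and after therapy; their ground truths are drawn
  independently because no within-specimen correlation is published — the
  paired delta test is therefore conservative on synthetic cohorts.
- **Seeding**: one master seed; per-sample generators are spawned from
  `numpy.random.SeedSequence(master).spawn(...)` in a fixed order, so any
  cohort element is reproducible independently of evaluation order.

What the simulator does *not* emulate: partial-volume mixing at region
boundaries, coil-sensitivity shading, B0/B1 inhomogeneity, slice-profile
effects, k-space sampling artefacts, spatially correlated noise, and
multi-exponential relaxation within a voxel. Passing tests therefore
demonstrate correctness of the estimation chain under the stated noise
model, not robustness to those instrumental effects.

## Pixel-wise fitting

Bounded trust-region-reflective nonlinear least squares (analytic
Jacobians), tolerance 1e-8 on relative parameter/cost change, at most 200
function evaluations — deterministic, no random restarts, so maps are
bit-reproducible.

- **Bounds.** T1 fit: `a ∈ (0, 10·max(S)]`, `b ∈ (0, 2]`,
  `T1 ∈ [1, 20000]` ms. T2 fit: `a ∈ (0, 10·max(S)]`, `T2 ∈ [1, 2000]` ms,
  `c ∈ [0, max(S)]`.
- **Initialisation.** T1: `a0 = max(S)`, `b0 = 1`, `T1_0` = the first TR at
  which the signal exceeds `(1 − 1/e)·a0` (median TR as fallback). T2:
  `c0 = min(S)` and `(a0, T2_0)` from a log-linear regression of
  `S − c0` on TE.
- **Degenerate inputs.** All-zero or constant signals return
  `converged = False` with a diagnostic code, never an exception.
- **Boundary policy.** A parameter landing on a bound marks the pixel
  non-converged rather than silently accepted — with one deliberate
  exception: a baseline estimated at `c = 0` is the physically meaningful
  value for noiseless or high-SNR data (no noise floor), so the lower bound
  of `c` does not trigger the flag.
- **R².** `1 − SS_res/SS_tot` per pixel; the map keeps only converged
  pixels and reports counts of excluded ones (QC summary). The default ROI
  filter is `r2_min = 0` (no published R² cut exists for this protocol);
  the threshold is exposed in the config because the R² maps are the
  fit-quality control surface.
- **Foreground.** Before fitting, background is excluded by thresholding
  the highest-signal image (longest TR / shortest TE) at a fraction of its
  maximum; 0.05 for noiseless work, 0.1 as the pipeline default (5 noise
  SDs above the Rayleigh background at the default SNR).

**Estimator precision.** The test suite verifies that at SNR 50 the T1
estimator attains the Cramér–Rao bound of the three-parameter model on the
default TR grid (median relative error within ±30 % of the bound's
half-normal prediction, about 3 %). This is the information limit of the
protocol itself: per-pixel precision on these grids cannot be better, and
ROI averaging over hundreds of pixels is what makes the per-sample index
precise.

## ROI indices

A sample's T1 (or T2) index is the mean of the map over
`ROI ∩ converged-mask ∩ {R² ≥ r2_min}`; the within-ROI SD uses the sample
convention (n − 1). Pooling two disjoint ROI parts weighted by pixel count
reproduces the whole-ROI mean exactly (tested).

## Group statistics

- **Omnibus**: classical one-way ANOVA (`F = MS_between/MS_within`,
  df = (k − 1, N − k)) across healthy / NMIBC / NMIBC_PDT.
- **Summary-statistics ANOVA**: F reconstructed from per-group
  (n, mean, SD) only; algebraically identical to the raw-data ANOVA
  (property-tested to 1e-10) and usable as an audit oracle when only
  published summaries are available. Applied to the reference tissue
  moments with n = 25 per group it gives F ≈ 187.8 for T1 — a pooled-
  variance reconstruction, not an assertion about any particular published
  analysis, whose exact ANOVA variant is generally unknowable from
  summaries alone.
- **Post hoc**: Tukey HSD by default (Bonferroni-adjusted t tests
  optional); significance reported at α = 0.05, 0.01, 0.001.
- **Paired analysis**: the pre-/post-PDT tumour measurements are the same
  physical specimens, so a paired t test on the deltas is provided and run
  by the pipeline alongside the (unpaired) three-group ANOVA, which remains
  the primary analysis for comparability with the unpaired design.
- **Diagnostics**: Levene's variance-homogeneity test is reported but never
  gates the analysis.
- Calibration properties asserted by the acceptance tests: type-I error
  0.05 ± 0.01 under the three-group null (n = 25, 2000 replicates), and at
  the reference T1 effect sizes ≥ 99 % of replicate cohorts reject the
  omnibus null at p < 1e-4 with all three Tukey pairs significant at
  p < 0.001 in ≥ 95 %.

## Dosimetry

Irradiance = P/A; fluence = (P/1000)/A · t, assuming a uniform top-hat beam
over the stated square field (no beam profile is modelled). The default
protocol (665 nm, 350 mW, 2.5 × 2.5 cm², 600 s) gives 56 mW/cm² and
33.6 J/cm².

## Pipeline

One YAML config drives simulate → fit → ROI → stats → report; CLI flags
override config values, and the resolved config is archived beside the
outputs together with a SHA-256 manifest and a JSON-lines log of stage
durations and convergence counts. Runs are deterministic given
(config, seed): the cohort CSV and stats JSON are byte-identical across
repeats. The default run — 75 samples of 64 × 64 phantoms, both series per
sample — takes on the order of two minutes on a single core; these problem
sizes are the package's desk-scale defaults, with the full scanner matrix
available through the config.

## Known limitations

- Monoexponential models only; multi-compartment T2, inversion-recovery or
  Look-Locker T1, and B1/B0 corrections are out of scope.
- Least squares assumes additive Gaussian residuals; at low SNR the Rician
  magnitude floor biases T2 slightly downward and the baseline upward
  (mitigated, not removed, by the free `c`).
- ROI masks are supplied as files; no interactive or automated
  segmentation.
- DICOM support is read-only (RepetitionTime/EchoTime tags); the native
  output dialect is NIfTI + JSON sidecar.
- The T2 series inherits a ~0.1 % residual T1 weighting from the finite TR,
  absorbed into the amplitude.
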