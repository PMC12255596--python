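# Methods

## The model

Tissue magnetic susceptibility χ (ppm) perturbs the main field through a
convolution with the unit dipole kernel; in k-space

    ΔB(k) = D(k) χ(k),    D(k) = 1/3 − k_b0² / |k|²,

where k_b0 is the frequency component along the main-field axis. D vanishes
on a double cone and, in particular, at the origin: the DC term of any
susceptibility map is undetermined, so reconstructed maps are relative.
`dipole_kernel` builds D on the unshifted discrete frequency lattice
(`numpy.fft.fftfreq` with voxel-size scaling), sets D(0) = 0 exactly, and
defaults the B0 axis to the third lattice axis (configurable). Consequences
verified by the test suite: every forward field has zero lattice mean,
forward+inverse is blind to constant susceptibility offsets, and uniform χ
produces no field.

Two classical direct inversions serve as reconstruction emulators:

- **TKD** — spectral division by D with |D| < δ replaced by sign(D)·δ
  (sign 0 → +), default δ = 0.2;
- **Tikhonov** — multiplication by D/(D² + λ), default λ = 0.05.

The defaults were chosen to be well-conditioned on the fixture phantom (the
methods are standard; their parameters are not prescribed by any dataset).
`reconstruction_suite` fans one phantom out over δ ∈ {0.1, 0.2, 0.3} and
λ ∈ {0.01, 0.05, 0.15} to emulate a set of imperfect "submissions" sharing
one ground truth.

## The phantom

`build_phantom` is parametric — nine disjoint spheres (CSF, corpus
callosum, internal capsule, amygdala, caudate, pallidum, putamen, thalamus,
hippocampus) inside a spherical brain on a 48³ lattice by default — rather
than anatomical. The trade: no realistic anatomy, but every ROI mean is
exact by construction, which is what the accuracy statistics need. Default
χ values are typical literature magnitudes (pallidum 0.13 ppm, putamen
0.09, caudate 0.05, white matter −0.03 to −0.05, CSF 0). For reconstruction
experiments the phantom is smoothed with a Gaussian (σ = 1 voxel) first;
a strictly piecewise-constant target has zero within-ROI variance, which
degenerates the voxelwise t tests.

The R2\* phantom assigns 1 Hz to CSF and ≥ 20 Hz to everything else, so the
4 Hz fluid threshold has a crisp noiseless answer. Multi-echo magnitudes
follow `m0·exp(−R2*·TE)` with seeded Gaussian noise clipped at zero —
Gaussian on magnitude, not Rician; at the simulated SNR (≈50) the
difference is negligible, but it is a known limitation at low SNR.

## R2\* estimation

`fit_r2s` implements the autoregressive closed-form estimator over equally
spaced echoes: for each consecutive echo triplet the Simpson-rule integral
of the signal equals T2\* times the difference of the outer echoes for an
exact mono-exponential, and the triplets are combined by the
autoregressive least-squares form

    T2* = (Σsᵢ² + (ΔTE/3)Σsᵢdᵢ) / (Σsᵢdᵢ + (ΔTE/3)Σdᵢ²),

with sᵢ the Simpson integrals, dᵢ the outer-echo differences. Negative or
undefined estimates clip to 0 Hz. A log-linear least-squares fit
(`fit_r2s_loglinear`) is kept as an independent cross-check; the two agree
within 2% on noiseless fixtures and the autoregressive fit recovers
noiseless decay rates within 1%.

## Referencing strategies

All strategies reduce to "subtract one scalar from every voxel", which
shifts means and leaves every fixed voxel set's variance untouched.

- **Anatomical**: mean (default) or median over a labelled ROI. The mean
  is the default because the referenced region then re-references to
  exactly zero; the median is available.
- **Whole brain**: mean over the brain mask. Since the inversion already
  leaves the lattice mean at zero, this is nearly a no-op on
  reconstructions — verified to change statistics by < 1e−8 on demeaned
  maps.
- **Relative variance**: voxels in the lowest percentile (default 3) of
  the across-volume ratio Var/mean. Ranking uses the *absolute* ratio:
  the ratio's sign is meaningless where the mean is negative, and voxels
  with zero mean get +inf so they can never be selected. Percentiles use
  linear interpolation between order statistics (numpy's default), so
  selected-voxel counts are reproducible. No registration is performed —
  all volumes must share one grid (synthetic subjects do by
  construction).
- **R2\* threshold**: in-brain voxels with R2\* strictly below 4 Hz
  (default). An empty region raises with the advice to raise the
  threshold.

## Cohort sampling model

`simulate_cohort` draws, for subject s in group g and each ROI,

    mean(s, roi) = μ[g, roi] + b_s + β·(age_s − midrange) + ε(s, roi),

with b_s ~ N(0, τ²) shared across all of a subject's ROIs (the global
susceptibility shift referencing is designed to remove), ε ~ N(0, σ_roi²)
independent, and ages uniform on 16–67 years. ROIs designated as reference
regions can receive a per-group shift, modelling disease in a would-be
reference region. Defaults: groups 27/19/17 (HC/LTLE/RTLE), σ_roi =
0.01 ppm, τ = 0.005 ppm, age slope 0.0005 ppm/year — magnitudes typical of
deep-grey-matter QSM cohorts; τ < σ was chosen so that referencing is not
automatically beneficial, which keeps both directions of the variance
trade-off reachable. Per-strategy reference values are generated jointly:
the anatomical strategies equal the subject's simulated reference-ROI
mean; the R2\* strategy tracks CSF and the relative-variance strategy
tracks the corpus callosum, each with a small independent selection jitter
(0.002 / 0.003 ppm); the whole-brain reference is N(0, 0.0005²),
reflecting the near-zero brain mean of demeaned reconstructions. The
empirical covariance of any two ROI columns is τ² (tested at n = 2000).

What this generator does *not* emulate: spatial error structure of real
inversions at the cohort level (cohorts are summary-level), streaking
artifacts, segmentation error, registration, hemispheric asymmetry, and
non-Gaussian tails. Passing tests therefore demonstrate the statistical
behaviour of referencing under the stated normal model, not robustness to
those real-data effects.

## Statistics

- **Welch t** exactly as `(x̄−ȳ)/S_d` with S_d² = S_X²/n + S_Y²/m,
  Welch–Satterthwaite degrees of freedom (the statistic alone does not fix
  df; this is the standard completion), two-sided p. Degenerate zero-S_d
  cases: t = 0, p = 1 for equal means, |t| = ∞, p = 0 otherwise.
- **Accuracy classification**: voxels within an ROI are treated as
  independent samples; a reconstruction's ROI is accurate when its
  referenced voxel mean is not significantly different from the referenced
  ground truth (unpaired Welch, α = 0.05). The statistic is computed from
  shifted means with unshifted variances, so referencing an ROI to its own
  mean yields t = 0 *exactly*, never just numerically small.
- **ANOVA + Tukey–Kramer**: classical one-way F per ROI; post-hoc
  studentized-range pairs (Kramer's unequal-n form) computed only for ROIs
  with ANOVA p < α. No additional across-ROI multiplicity correction is
  applied — the protocol is ANOVA gating plus within-ROI Tukey. The
  Tukey implementation is cross-checked against an independent one in the
  tests.
- **Age correction**: pooled simple linear regression of the referenced
  ROI mean on age, returning residuals plus the grand mean; a per-group
  variant is available behind a flag. Order is fixed: reference →
  age-correct → ANOVA.
- **Variance change**: `100·[Var(roi−ref) − Var(roi)]/Var(roi)` with
  unbiased variances, computed before age correction.
- Sample variances are unbiased (n−1) everywhere.

## Variance theory checks

With equal variances σ² and correlation ρ between test and reference ROI
means, Var(X−R) = (2−2ρ)σ² ∈ [0, 4σ²]. `variance_bound_scan` verifies the
analytic curve by simulation, constructing |ρ| = 1 via exact linear maps so
the sample-moment ratio attains 4 and 0 exactly rather than in
expectation. `hypothesis_equivalence_sim` and `power_curve` quantify the
practical consequences at the default cohort sizes (27 vs 19): a clean
reference leaves the referenced and unreferenced tests equally calibrated;
a reference region carrying a group effect inflates only the referenced
test's rejection rate; a reference sharing the subject offset buys power
while an independent one costs it. The full-pipeline type-I error is
estimated over 1000 re-simulated cohorts (~6 s), judged against the 99%
binomial band around α.

## Numerical conventions

χ in ppm, R2\* in Hz, echo times in ms, ages in years; 0-based voxel
coordinates; masks are inclusive; erosion uses the radius-1 Euclidean ball
(the 6-neighbour cross — the 26-neighbourhood would be radius √3),
applied iteratively; trimming bounds are inclusive and computed after
erosion, per subject per ROI; CSV reports are written with fixed column
order and precision so reruns are byte-identical. Problem sizes throughout
(48³ phantom, 10⁵ Monte-Carlo pairs per correlation point, 1000–2000
simulation replicates) were chosen as the smallest at which the sampling
error of each check is comfortably below the effect it measures.

## Known limitations

Summary-level cohorts (no per-subject volumes in the statistical
workflows); Gaussian magnitude noise; no phase simulation, background
fields, or phase unwrapping; no anisotropy or microstructure; no
registration or template construction; parametric rather than anatomical
phantom geometry.
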