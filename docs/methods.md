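# Methods

## The measure

Regional homogeneity (ReHo) quantifies how synchronously a voxel's BOLD
time course moves with its immediate neighbourhood. For K time series of
n time points, each converted to mid-ranks over time, with R_t the rank
sum at time t and S = Σ_t (R_t − R̄)², Kendall's coefficient of
concordance is

    W = 12·S / (K²(n³ − n) − K·Σ_j T_j),        T_j = Σ_g (t_g³ − t_g),

where T_j is the tie correction of series j over its tie groups g.
W = 1 when all K rank orderings agree, and E[W] = 1/K for independent
series. A ReHo map assigns each in-mask voxel the W of its own series
together with its 26 nearest neighbours (6 faces + 12 edges + 8 corners;
7- and 19-voxel stencils are available for comparability with the wider
ReHo literature).

Implementation notes:

- Ranks are computed once per subject; neighbourhood rank sums are
  accumulated by shifting the rank volume across the stencil, so the map
  is a handful of vectorised passes rather than a per-voxel loop.
- The tie term is recovered from the mid-rank variance identity
  Σ_t (r_t − (n+1)/2)² = (n³−n)/12 − T_j/12, which is exact and avoids
  run-length bookkeeping. Tie correction defaults to on and is
  switchable (`tie_correction=False`) because some historical
  implementations omit it; continuous BOLD essentially never ties, but
  quantised or synthetic data can.
- Mask-edge voxels use the in-mask neighbours they have (reduced K)
  rather than being dropped; voxels left with K < 2 are set to 0,
  flagged, excluded from the standardisation mean, and excluded from
  group inference (their value is a policy artifact, not data).
- An all-constant neighbourhood has an undefined W (zero denominator);
  it is returned as 0 with a warning.

## Single-subject pipeline

Per subject, in order: discard of the first `n_discard = 10` volumes
(scanner equilibration); motion QC; per-voxel linear detrending (the
fitted line is removed and the temporal mean restored — cosmetic for a
rank statistic, but it makes the contract testable); ideal band-pass to
0.01–0.08 Hz; the ReHo map; division by the map's own within-mask mean
(so every subject's map has mask mean exactly 1); isotropic Gaussian
smoothing at 6 mm FWHM, in the stated order (standardise, then smooth).

- The band-pass is frequency-rectangular: DFT bins whose exact frequency
  lies in [low, high] inclusive are kept, all others zeroed, and the DC
  component is retained so the mean is unchanged. Nyquist at TR 3 s is
  0.167 Hz.
- Motion QC fails a subject if any per-axis |translation| > 1.5 mm or
  any |rotation| > 1°. Motion files are the 6-column SPM `rp_*.txt`
  dialect; the reader requires the rotation unit to be declared
  (radians for SPM) because a silent degree/radian mix-up is the classic
  QC failure mode. The rule is applied to the retained (post-discard)
  volumes; files with rows for all original volumes are truncated from
  the front, and any other row count is an error.
- Smoothing converts FWHM to σ = FWHM / (2√(2 ln 2)) per axis in voxel
  units from the affine, truncates the kernel at 5σ (omitted tail mass
  < 1e-6, so the impulse response matches the closed-form Gaussian at
  that tolerance), and excludes out-of-mask voxels from the kernel with
  renormalisation, so a constant map stays constant up to the mask edge.

## Group model

Voxelwise OLS of the standardized smoothed maps on
[intercept, group (group1 = 1), age, sex, education], continuous
covariates mean-centred (the group t is unchanged; conditioning
improves). The group-difference statistic is
t = β_group / SE(β_group) with df = N − 5; with no covariates this is
algebraically the pooled-variance two-sample t. Sex enters as a single
0/1 indicator. A rank-deficient design is an error naming the collinear
columns.

## Cluster-extent correction

The voxelwise two-tailed threshold (p < 0.01, t quantile at the model's
df) is combined with a minimum cluster extent derived by Monte-Carlo
simulation. Each null iteration fills the mask's bounding grid with
white Gaussian noise, smooths it to a target FWHM, restricts to the
mask, re-standardises to unit variance in the mask, thresholds two-tailed
at the matching normal quantile, and records the maximum cluster size
over both signs. The extent threshold k for corrected alpha is the
smallest size whose exceedance fraction under that null is ≤ alpha;
clusters of size ≥ k are significant. Positive and negative clusters are
labelled separately (a two-tailed correction with signed clusters), with
6-connectivity (faces) by default, the same labelling object used for
both the null and the observed map.

**Smoothness: estimated, not nominal.** The null field's smoothness must
match the *statistic map*, not the applied smoothing kernel: a ReHo map
of spatially smooth noise is already smooth before the 6 mm kernel is
applied (neighbouring voxels share 18 of 27 neighbourhood series), so
the final maps are smoother than 6 mm — about 8.4 mm FWHM under the
default synthetic conditions. Simulating the null at the nominal 6 mm
would under-estimate null cluster sizes and inflate the family-wise
error. The pipeline therefore estimates per-axis FWHM from the group-GLM
residual maps via the Gaussian-autocorrelation identity
ρ(1) = exp(−1/(4σ²)) (σ² = −1/(4 ln ρ), with ρ = 1 − MSD/2V from the
mean squared difference of in-mask neighbours), pooled across subjects —
the variance-of-differences estimator long used for this purpose.
`mc_fwhm` accepts `"estimate"` (default), `"nominal"`, or an explicit
value in mm.

The extent rule is applied as size ≥ k with k from the null (recorded in
the report header), which makes the correction calibration-exact
in-sample; peak ties within a cluster break to the smallest linear
voxel index; peak coordinates are reported in voxel indices and in
world mm through the affine.

## Post-hoc clinical correlations

For each significant cluster, the cluster-mean standardized ReHo per
subject is correlated with each clinical variable (cigarettes/day, years
smoking, craving) in the case group only — the controls have no clinical
scores — controlling for age, sex and education by partial correlation:
both variables are residualised on [1, covariates], r is the Pearson
correlation of residuals, and the two-tailed p uses
t = r·√(df/(1−r²)), df = N − 2 − k. No multiplicity correction is
applied, mirroring the uncorrected exploratory convention. A variable
lying exactly in the covariate span has a zero residual vector, which is
orthogonal to everything; it is reported as r = 0, p = 1 rather than an
error (only constant inputs are errors).

## Synthetic cohorts

The generator emulates a two-group resting-state study: per subject a
4D image whose background is white Gaussian noise, spatially smoothed to
`noise_fwhm_mm` (default 6 mm — chosen so the correction's Gaussian-field
assumption is met by construction), passed through a variance-preserving
AR(1) recursion along time (coefficient 0.3, a plausible BOLD
autocorrelation at TR 3 s), globally scaled to unit variance, plus a
per-voxel random linear drift (SD 0.5 noise units over the run) that the
detrending stage removes. Inside each spherical effect region every
voxel's series is mixed as √(1−w²)·private + w·shared, where the shared
signal is band-limited to 0.01–0.08 Hz (so the effect survives filtering
by construction) and w is the group's synchrony weight; w = 0 reduces
exactly to background, and the in-region pairwise correlation is w².
Motion tables are small-amplitude random walks (translation steps
SD 0.02 mm, rotation steps SD 5e-4 rad), which occasionally cross the QC
thresholds — exercising, realistically, the exclusion path (5 of 89
subjects in the worked example).

Demographics default to the emulated case-control layout: 45 cases
(age 27.9 ± 5.6 y, education 13.1 ± 3.0 y, 8 F by exact count,
cigarettes/day 20.3 ± 7.6, years smoking 10.2 ± 5.8, craving
6.41 ± 1.7, each clipped to its reported range) versus 44 controls
(26.3 ± 5.8 y, 15.0 ± 2.6 y, 10 F); clinical variables exist only for
cases. Sex is assigned by exact count rather than Bernoulli draws — a
case-control table reports counts — which also keeps the sex column
non-constant in small cohorts. An optional clinical link couples one
region's subject-level weight (jitter SD 0.1, clipped to [0, 0.95]) to a
clinical variable's z-score with a chosen correlation; the strength is a
free parameter of the generator, not an estimate of any real effect
size. Everything is driven by a spawned `SeedSequence` tree, so a
(config, seed) pair reproduces the cohort bit-for-bit, including the
gzipped NIfTI bytes.

What the generator does **not** emulate: scanner artifacts (spikes,
nonlinear drift, physiological cycles), non-Gaussian spatial
autocorrelation (real BOLD smoothness has heavier-than-Gaussian tails,
the known failure mode of cluster corrections on real data),
registration error, anatomical structure in the mask, or
group differences in noise level. Passing calibration here shows the
chain is internally correct under its stated assumptions — not that the
corrected threshold is exact on scanner data.

## Experiment scales

The calibration and recovery experiments run the full pipeline at a
reduced problem size chosen as the package's standard desk-scale
configuration: 10+10 subjects, 16³ voxels at 3 mm, 60 volumes (50 after
discard), per-cohort Monte-Carlo nulls of 1000 iterations (the pipeline
default is 5000). Family-wise error is measured over 100 independent
null cohorts, each thresholded with its own null; planted-effect
recovery uses one sphere of radius 2.5 voxels with weights 0.8 vs 0.2
over 10 seeded cohorts, requiring a correct-signed significant cluster
with Dice > 0.3 against the sphere. The worked example in the README
runs the full 45+44 design on a 24³ grid with 180 volumes.

## Known limitations

- The Monte-Carlo null assumes a stationary Gaussian spatial
  autocorrelation; the estimator returns a per-axis FWHM and cannot
  capture non-Gaussian or non-stationary smoothness.
- Voxelwise exactness of the group t relies on approximate normality of
  standardized ReHo across subjects; at very short series or tiny K the
  W distribution is visibly discrete/skewed.
- The ideal filter's brick-wall response leaks energy of off-bin
  out-of-band sinusoids near the series edges (about 3% RMS for a
  0.12 Hz tone at 170 × 3 s); this is inherent to the frequency-
  rectangular convention, not a defect of the implementation.
- Anatomical labelling of clusters is a free-text passthrough; no atlas
  lookup is performed.
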