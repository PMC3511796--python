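# rehopipe

Regional homogeneity (ReHo) analysis of resting-state fMRI for two-group
case-control studies — from 4D BOLD images to Kendall's-W ReHo maps,
covariate-adjusted group-difference t maps, Monte-Carlo cluster-extent
corrected cluster tables, and post-hoc partial correlations between
cluster ReHo and clinical variables. A seeded synthetic-cohort generator
makes the entire chain testable without scanner data.

ReHo measures local temporal synchrony: for each voxel, Kendall's
coefficient of concordance

W = 12 Σ_t (R_t − R̄)² / (K²(n³ − n) − K Σ_j T_j)

across the K = 27 time series of the voxel and its 26 nearest neighbours
(n time points, mid-ranks over time, T_j the tie correction), so W = 1
for perfectly concordant series and E[W] = 1/K under independence.
Subject maps are divided by their within-mask mean and smoothed (6 mm
FWHM); groups are compared voxelwise by OLS with age, sex and education
as nuisance covariates; and the voxelwise threshold (two-tailed
p < 0.01) is combined with a cluster-extent threshold derived from
Monte-Carlo simulation of smooth Gaussian null fields in the mask, at a
corrected two-tailed alpha of 0.01. See `docs/methods.md` for the model,
the smoothness-matching rationale, and the generator's assumptions.

Intended users: neuroimaging researchers who want a transparent,
fully-seeded reimplementation of the classic ReHo + AlphaSim-style
workflow whose statistical behaviour (family-wise error, power,
exactness of each stage) is itself under test.

## Worked example

The `analysis/` scripts run the whole study on a synthetic cohort
emulating a smoker vs non-smoker comparison (45 + 44 subjects, 180
volumes at TR 3 s, 3 mm voxels on a 24³ grid), with one planted region
of *decreased* and one of *increased* case-group synchrony and a
clinical coupling between craving and the increased region:

```sh
python analysis/01_simulate_cohort.py      # writes scratch/cohort/
python analysis/02_group_analysis.py       # full pipeline, 5000-iteration MC null
python analysis/03_fwe_calibration.py      # 100 null cohorts (scaled)
python analysis/04_planted_effect_recovery.py
```

`02_group_analysis.py` prints (numbers from the run committed under
`results/group/`):

```
subjects analysed: 84 (df=79)
estimated map smoothness: 8.3/8.3/8.2 mm FWHM
cluster-extent threshold: k=50 voxels (|t| > 2.64, corrected alpha 0.01)
significant clusters: 2
sign  size     peak_t  i  j  k  x_mm  y_mm  z_mm label
   +    90  14.539925 16 17 16  13.5  16.5  13.5
   -    86 -33.546618  7  7  7 -13.5 -13.5 -13.5
```

Five of the 89 subjects were excluded by the motion rule (>1.5 mm
translation or >1° rotation), leaving 84 subjects and
df = 84 − 5 design columns = 79. The two
significant clusters sit on the planted spheres with the planted signs:
smokers' synchrony lower at (−13.5, −13.5, −13.5) mm and higher at
(13.5, 16.5, 13.5) mm. The post-hoc table shows the planted clinical
coupling — craving vs cluster-mean ReHo in the increased cluster,
r = 0.57, p = 1.3e-4 controlling age/sex/education — and no association
with the unlinked variables (all p > 0.5).

`03_fwe_calibration.py` reports that 0/100 null cohorts produced any
significant cluster at corrected alpha 0.01 (bound 0.030), with
per-cohort extent thresholds of median 35 voxels (range 31–39), and
`04_planted_effect_recovery.py` recovers a planted 0.8-vs-0.2 synchrony
difference in 10/10 cohorts with Dice 0.62–0.92 against the planted
sphere.

There is also a thin CLI:

```sh
reho simulate --out cohort/ --n-group1 4 --n-group2 4 --grid 12 --volumes 60
reho compute --bold cohort/sub-group1001_bold.nii.gz --mask mask.nii.gz \
     --neighborhood 27 --fwhm 6 --out reho.nii.gz
reho mc-threshold --mask mask.nii.gz --voxel-p 0.01 --fwhm 6 --iters 5000 \
     --alpha 0.01 --connectivity 6 --seed 1
reho run --config run.yaml
```

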