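"""Calibration and recovery experiments on synthetic cohorts.

These drive the whole pipeline at a deliberately small problem size —
16^3 grids, 60 volumes, 10 subjects per group — chosen so that hundreds of
full pipeline runs complete on one CPU while keeping every stage (discard,
detrend, band-pass, KCC over 27 neighbours, standardise, smooth, covariate
GLM, Monte-Carlo extent threshold) statistically non-trivial.

``fwe_calibration`` is the headline property: on null cohorts (no planted
effect) the fraction of runs producing any significant cluster must stay
at or below the corrected alpha, up to binomial noise.

``planted_effect_recovery`` checks power and localisation: a group
difference in one region's synchrony weight must surface as a significant
cluster overlapping that region.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .pipeline import RunConfig, analyze_group, subject_reho
from .images import BrainMask
from .synthetic import CohortConfig, EffectROI, simulate_cohort_arrays, sphere_mask

__all__ = [
    "scaled_cohort_config",
    "scaled_run_config",
    "fwe_calibration",
    "planted_effect_recovery",
]


def scaled_cohort_config(seed: int, effect_rois=()) -> CohortConfig:
    """Desk-scale cohort: 10+10 subjects, 16^3 grid at 3 mm, 60 volumes at
    TR 3 s, 6 mm background smoothness, AR(1) 0.3."""
    return CohortConfig(
        n_group1=10,
        n_group2=10,
        grid_shape=(16, 16, 16),
        n_volumes=60,
        effect_rois=tuple(effect_rois),
        seed=seed,
    )


def scaled_run_config(n_iterations: int = 1000, seed: int = 0) -> RunConfig:
    """Pipeline parameters of the emulated study, with the Monte-Carlo null
    reduced from 5000 to ``n_iterations`` iterations."""
    return RunConfig(n_iterations=n_iterations, seed=seed)


def _run_cohort(cohort_cfg: CohortConfig, run_cfg: RunConfig, mc_seed: int):
    bolds, _, table = simulate_cohort_arrays(cohort_cfg)
    mask = BrainMask.full(cohort_cfg.grid_shape, cohort_cfg.affine)
    maps = [subject_reho(b, mask, run_cfg) for b in bolds]
    return analyze_group(maps, table, run_cfg, mc_seed=mc_seed), table, maps


@dataclasses.dataclass
class FweResult:
    n_cohorts: int
    n_with_cluster: int
    fraction: float
    corrected_alpha: float
    binomial_se: float
    extent_ks: list[int]
    fwhm_est_mm: list[tuple[float, float, float]]


def fwe_calibration(
    n_cohorts: int = 100,
    n_iterations: int = 1000,
    corrected_alpha: float = 0.01,
    seed: int = 0,
) -> FweResult:
    """Empirical family-wise error of the full pipeline on null cohorts.

    Each cohort is generated, analysed and thresholded independently (its
    own Monte-Carlo null, seeded from the cohort seed); the result is the
    fraction of cohorts with at least one significant cluster.
    """
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(2 * n_cohorts) % (2**31)
    hits = 0
    ks, fwhms = [], []
    run_cfg = scaled_run_config(n_iterations)
    run_cfg = dataclasses.replace(run_cfg, corrected_alpha=corrected_alpha)
    for c in range(n_cohorts):
        cohort_cfg = scaled_cohort_config(seed=int(child_seeds[2 * c]))
        result, _, _ = _run_cohort(cohort_cfg, run_cfg, mc_seed=int(child_seeds[2 * c + 1]))
        ks.append(result.extent_k)
        fwhms.append(result.mc_fwhm_mm)
        if result.report.clusters:
            hits += 1
    se = float(np.sqrt(corrected_alpha * (1 - corrected_alpha) / n_cohorts))
    return FweResult(
        n_cohorts=n_cohorts,
        n_with_cluster=hits,
        fraction=hits / n_cohorts,
        corrected_alpha=corrected_alpha,
        binomial_se=se,
        extent_ks=ks,
        fwhm_est_mm=fwhms,
    )


@dataclasses.dataclass
class RecoveryResult:
    n_seeds: int
    n_recovered: int
    dice: list[float]
    cluster_sizes: list[int]


def planted_effect_recovery(
    n_seeds: int = 10,
    w_group1: float = 0.8,
    w_group2: float = 0.2,
    roi_center: tuple[int, int, int] = (8, 8, 8),
    roi_radius: float = 2.5,
    n_iterations: int = 1000,
    dice_threshold: float = 0.3,
    seed: int = 0,
) -> RecoveryResult:
    """Recovery of a planted group difference in regional synchrony.

    A cohort is 'recovered' when some significant cluster has Dice overlap
    > ``dice_threshold`` with the planted sphere and the correct sign
    (group1 weight above group2 -> positive group contrast).
    """
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(2 * n_seeds) % (2**31)
    roi = EffectROI(
        center=roi_center,
        radius_vox=roi_radius,
        sync_weight_group1=w_group1,
        sync_weight_group2=w_group2,
    )
    run_cfg = scaled_run_config(n_iterations)
    expected_sign = 1 if w_group1 >= w_group2 else -1
    dices, sizes = [], []
    recovered = 0
    for s in range(n_seeds):
        cohort_cfg = scaled_cohort_config(seed=int(child_seeds[2 * s]), effect_rois=[roi])
        result, _, _ = _run_cohort(cohort_cfg, run_cfg, mc_seed=int(child_seeds[2 * s + 1]))
        roi_mask = sphere_mask(cohort_cfg.grid_shape, roi.center, roi.radius_vox)
        best = 0.0
        best_size = 0
        for cluster in result.report.clusters:
            if cluster.sign != expected_sign:
                continue
            cl = np.zeros(cohort_cfg.grid_shape, dtype=bool)
            cl[cluster.voxels[:, 0], cluster.voxels[:, 1], cluster.voxels[:, 2]] = True
            inter = (cl & roi_mask).sum()
            dice = 2.0 * inter / (cl.sum() + roi_mask.sum())
            if dice > best:
                best, best_size = float(dice), cluster.size
        dices.append(best)
        sizes.append(best_size)
        if best > dice_threshold:
            recovered += 1
    return RecoveryResult(
        n_seeds=n_seeds, n_recovered=recovered, dice=dices, cluster_sizes=sizes
    )
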