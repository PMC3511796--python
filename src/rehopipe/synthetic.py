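"""Seeded synthetic resting-state cohorts.

Generates two-group cohorts (images + subject table + motion files) with
the statistical structure the ReHo analysis assumes: spatially smooth,
temporally autocorrelated background noise, and spherical regions in which
voxel time courses share a band-limited common signal whose mixing weight
differs by group.  Inside an effect region a voxel's series is

    sqrt(1 - w^2) * private_noise + w * shared_signal,

with unit-variance components, so w (the "synchrony weight") directly sets
the pairwise correlation w^2 between region voxels and hence the expected
local concordance.  w = 0 reduces exactly to background.

Demographics default to a smoker / non-smoker case-control layout
(45 vs 44 subjects; smokers carry cigarettes-per-day, years-smoking and
craving scores; non-smokers do not).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .images import Bold4D
from .preprocess import FilterSpec, bandlimit_series
from .reho import fwhm_to_sigma

__all__ = [
    "ContinuousSpec",
    "GroupSpec",
    "EffectROI",
    "ClinicalLink",
    "CohortConfig",
    "default_covariate_spec",
    "generate_subject_bold",
    "generate_cohort",
    "generate_subject_table",
    "simulate_cohort_arrays",
    "sphere_mask",
]

TABLE_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "cigarettes_per_day",
    "years_smoking",
    "craving",
    "image_path",
    "motion_path",
]


@dataclasses.dataclass(frozen=True)
class ContinuousSpec:
    """Truncated-normal draw: mean/sd with optional clipping range."""

    mean: float
    sd: float
    low: float | None = None
    high: float | None = None

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.normal(self.mean, self.sd, size=n)
        lo = -np.inf if self.low is None else self.low
        hi = np.inf if self.high is None else self.high
        return np.clip(x, lo, hi)


@dataclasses.dataclass(frozen=True)
class GroupSpec:
    """Per-group covariate distributions; ``clinical`` variables exist only
    for the case group (group1)."""

    age: ContinuousSpec
    education: ContinuousSpec
    female_prop: float
    clinical: Mapping[str, ContinuousSpec] = dataclasses.field(default_factory=dict)


def default_covariate_spec() -> dict[str, GroupSpec]:
    """Case-control demographics of the emulated study: smokers aged
    27.9 +/- 5.6 y (range 19-39) with 13.1 +/- 3.0 y education and 8/45
    women; controls 26.3 +/- 5.8 y (19-38), 15.0 +/- 2.6 y education,
    10/44 women.  Smokers additionally carry cigarettes/day 20.3 +/- 7.6
    (10-40), years smoking 10.2 +/- 5.8 (1.5-21) and craving score
    6.41 +/- 1.7 (3-10)."""
    return {
        "group1": GroupSpec(
            age=ContinuousSpec(27.9, 5.6, 19, 39),
            education=ContinuousSpec(13.1, 3.0, 5, 22),
            female_prop=8 / 45,
            clinical={
                "cigarettes_per_day": ContinuousSpec(20.3, 7.6, 10, 40),
                "years_smoking": ContinuousSpec(10.2, 5.8, 1.5, 21),
                "craving": ContinuousSpec(6.41, 1.7, 3, 10),
            },
        ),
        "group2": GroupSpec(
            age=ContinuousSpec(26.3, 5.8, 19, 38),
            education=ContinuousSpec(15.0, 2.6, 5, 22),
            female_prop=10 / 44,
        ),
    }


@dataclasses.dataclass(frozen=True)
class EffectROI:
    """Spherical region of elevated (or suppressed) local synchrony."""

    center: tuple[int, int, int]
    radius_vox: float
    sync_weight_group1: float
    sync_weight_group2: float


@dataclasses.dataclass(frozen=True)
class ClinicalLink:
    """Couples a clinical variable to subject-level synchrony in one ROI:
    the latent per-subject weight perturbation and the clinical z-score
    share correlation ``strength`` (group1 subjects only)."""

    roi_index: int
    variable: str
    strength: float


@dataclasses.dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; identical (config, seed) pairs
    produce bit-identical cohorts."""

    n_group1: int = 45
    n_group2: int = 44
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_volumes: int = 180
    tr_s: float = 3.0
    noise_fwhm_mm: float = 6.0
    ar1_coef: float = 0.3
    drift_sd: float = 0.5  # per-voxel linear drift amplitude, units of noise SD
    effect_rois: Sequence[EffectROI] = ()
    covariate_spec: Mapping[str, GroupSpec] = dataclasses.field(
        default_factory=default_covariate_spec
    )
    clinical_link: ClinicalLink | None = None
    weight_jitter_sd: float = 0.1  # subject-level sync-weight spread when linked
    origin_mm: tuple[float, float, float] | None = None  # None: grid-centred
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 <= 0 or self.n_group2 <= 0:
            raise ValueError(
                f"both groups need at least one subject, got "
                f"{self.n_group1}/{self.n_group2} (degenerate design)"
            )
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError(f"ar1_coef must be in [0, 1), got {self.ar1_coef}")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        for i, roi in enumerate(self.effect_rois):
            for w in (roi.sync_weight_group1, roi.sync_weight_group2):
                if not 0 <= w < 1:
                    raise ValueError(f"effect ROI {i}: sync weight {w} not in [0, 1)")
            for ax in range(3):
                c, r = roi.center[ax], roi.radius_vox
                if c - r < 0 or c + r > self.grid_shape[ax] - 1:
                    raise ValueError(
                        f"effect ROI {i} (center {roi.center}, radius {r}) "
                        f"extends outside the {self.grid_shape} grid"
                    )
        if self.clinical_link is not None:
            if not 0 <= self.clinical_link.roi_index < len(self.effect_rois):
                raise ValueError(
                    f"clinical_link names ROI {self.clinical_link.roi_index}, "
                    f"but only {len(self.effect_rois)} ROIs are defined"
                )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        if self.origin_mm is None:
            origin = tuple(
                -(n - 1) / 2.0 * v for n, v in zip(self.grid_shape, self.voxel_size_mm)
            )
        else:
            origin = self.origin_mm
        aff[:3, 3] = origin
        return aff


def sphere_mask(
    grid_shape: tuple[int, int, int], center: tuple[int, int, int], radius_vox: float
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius_vox**2


def _background_noise(
    config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Spatially smoothed, temporally AR(1), approximately unit-variance
    4D noise.  Innovations are white across voxels; spatial smoothing is
    applied per volume, then the AR(1) recursion along time with variance-
    preserving innovation scaling."""
    shape = tuple(config.grid_shape) + (config.n_volumes,)
    noise = rng.standard_normal(shape)
    if config.noise_fwhm_mm > 0:
        sigma_vox = fwhm_to_sigma(config.noise_fwhm_mm) / np.asarray(
            config.voxel_size_mm
        )
        noise = gaussian_filter(noise, sigma=tuple(sigma_vox) + (0.0,))
    a = config.ar1_coef
    if a > 0:
        scale = np.sqrt(1.0 - a * a)
        for t in range(1, config.n_volumes):
            noise[..., t] = a * noise[..., t - 1] + scale * noise[..., t]
    noise /= noise.std()
    return noise


def _shared_signal(
    config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance common signal band-limited to the analysis passband, so
    the planted synchrony survives temporal filtering by construction."""
    raw = rng.standard_normal(config.n_volumes)
    sig = bandlimit_series(raw, config.tr_s, FilterSpec())
    sd = sig.std()
    if sd <= 0:
        raise ValueError(
            "band-limited signal is degenerate; series too short for the passband"
        )
    return sig / sd


def generate_subject_bold(
    config: CohortConfig,
    group: str,
    seed: int | np.random.SeedSequence,
    sync_weights: Sequence[float] | None = None,
) -> tuple[Bold4D, np.ndarray]:
    """One subject's 4D image and motion table.

    ``sync_weights`` optionally overrides the per-ROI weight of this
    subject's group (used for subject-level clinical coupling).  The motion
    table is a small-amplitude random walk: T rows of 3 translations (mm)
    and 3 rotations (radians, SPM dialect).
    """
    if group not in ("group1", "group2"):
        raise ValueError(f"group must be 'group1' or 'group2', got {group!r}")
    rng = np.random.default_rng(seed)
    data = _background_noise(config, rng)
    for i, roi in enumerate(config.effect_rois):
        if sync_weights is not None:
            w = float(sync_weights[i])
        else:
            w = roi.sync_weight_group1 if group == "group1" else roi.sync_weight_group2
        if not 0 <= w < 1:
            raise ValueError(f"effect ROI {i}: sync weight {w} not in [0, 1)")
        shared = _shared_signal(config, rng)
        if w > 0:
            m = sphere_mask(config.grid_shape, roi.center, roi.radius_vox)
            data[m] = np.sqrt(1.0 - w * w) * data[m] + w * shared
    if config.drift_sd > 0:
        trend = np.linspace(-0.5, 0.5, config.n_volumes)
        slopes = rng.normal(0.0, config.drift_sd, size=config.grid_shape)
        data += slopes[..., None] * trend
    motion = np.cumsum(
        rng.normal(0.0, [0.02] * 3 + [0.0005] * 3, size=(config.n_volumes, 6)), axis=0
    )
    bold = Bold4D(data=data, affine=config.affine, tr_s=config.tr_s)
    return bold, motion


def _draw_table(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Subject table plus, when a clinical link is configured, the latent
    per-subject z that couples the linked clinical variable to synchrony."""
    rows = []
    link = config.clinical_link
    latent = None
    n1 = config.n_group1
    if link is not None:
        latent = rng.standard_normal(n1)
    for gi, (group, n) in enumerate(
        [("group1", n1), ("group2", config.n_group2)]
    ):
        spec = config.covariate_spec[group]
        age = spec.age.draw(rng, n)
        edu = spec.education.draw(rng, n)
        # exact sex counts (a case-control table reports counts, not rates);
        # also keeps the sex column non-constant in small cohorts
        n_female = int(round(spec.female_prop * n))
        sex = rng.permutation(np.array(["F"] * n_female + ["M"] * (n - n_female)))
        clinical = {
            name: cspec.draw(rng, n) for name, cspec in spec.clinical.items()
        }
        if link is not None and group == "group1":
            cspec = spec.clinical.get(link.variable)
            if cspec is None:
                raise ValueError(
                    f"clinical_link variable {link.variable!r} not in group1 spec"
                )
            s = link.strength
            eps = rng.standard_normal(n)
            z = s * latent + np.sqrt(max(0.0, 1.0 - s * s)) * eps
            clinical[link.variable] = np.clip(
                cspec.mean + cspec.sd * z,
                -np.inf if cspec.low is None else cspec.low,
                np.inf if cspec.high is None else cspec.high,
            )
        for i in range(n):
            row = {
                "subject_id": f"sub-{group}{i + 1:03d}",
                "group": group,
                "age": float(age[i]),
                "sex": str(sex[i]),
                "education": float(edu[i]),
                "cigarettes_per_day": np.nan,
                "years_smoking": np.nan,
                "craving": np.nan,
                "image_path": "",
                "motion_path": "",
            }
            for name, vals in clinical.items():
                row[name] = float(vals[i])
            rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS), latent


def _subject_weights(
    config: CohortConfig, table: pd.DataFrame, latent: np.ndarray | None
) -> list[list[float] | None]:
    """Per-subject ROI weight overrides (only the linked ROI is jittered)."""
    link = config.clinical_link
    if link is None:
        return [None] * len(table)
    out: list[list[float] | None] = []
    i1 = 0
    for _, row in table.iterrows():
        group = row["group"]
        ws = [
            roi.sync_weight_group1 if group == "group1" else roi.sync_weight_group2
            for roi in config.effect_rois
        ]
        if group == "group1":
            ws[link.roi_index] = float(
                np.clip(
                    ws[link.roi_index] + config.weight_jitter_sd * latent[i1],
                    0.0,
                    0.95,
                )
            )
            i1 += 1
        out.append(ws)
    return out


def generate_subject_table(config: CohortConfig) -> pd.DataFrame:
    """Just the subject table (no images), on the same seed path as
    :func:`simulate_cohort_arrays` so the demographics agree."""
    root = np.random.SeedSequence(config.seed)
    table_seq = root.spawn(1)[0]
    table, _ = _draw_table(config, np.random.default_rng(table_seq))
    return table


def simulate_cohort_arrays(
    config: CohortConfig,
) -> tuple[list[Bold4D], list[np.ndarray], pd.DataFrame]:
    """In-memory cohort: per-subject Bold4D images, motion tables, and the
    subject table, fully determined by (config, config.seed)."""
    root = np.random.SeedSequence(config.seed)
    table_seq, *subject_seqs = root.spawn(1 + config.n_group1 + config.n_group2)
    table, latent = _draw_table(config, np.random.default_rng(table_seq))
    weights = _subject_weights(config, table, latent)
    bolds, motions = [], []
    for seq, (_, row), w in zip(subject_seqs, table.iterrows(), weights):
        bold, motion = generate_subject_bold(config, row["group"], seq, sync_weights=w)
        bolds.append(bold)
        motions.append(motion)
    return bolds, motions, table


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write the cohort to disk: one .nii.gz and one rp_<id>.txt per
    subject plus subjects.tsv; returns the table with file paths filled in."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bolds, motions, table = simulate_cohort_arrays(config)
    image_paths, motion_paths = [], []
    for bold, motion, sid in zip(bolds, motions, table["subject_id"]):
        ipath = out_dir / f"{sid}_bold.nii.gz"
        mpath = out_dir / f"rp_{sid}.txt"
        bold.save(ipath)
        np.savetxt(mpath, motion, fmt="%.8e")
        image_paths.append(str(ipath))
        motion_paths.append(str(mpath))
    table = table.copy()
    table["image_path"] = image_paths
    table["motion_path"] = motion_paths
    table.to_csv(out_dir / "subjects.tsv", sep="\t", index=False, float_format="%.6g")
    return table
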