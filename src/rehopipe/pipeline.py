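"""End-to-end orchestration: subject table in, cluster report out.

The stage order is fixed: volume discard -> motion QC gate -> linear
detrend -> ideal band-pass -> ReHo map -> standardise -> smooth ->
group GLM with nuisance covariates -> Monte-Carlo extent threshold ->
cluster report -> post-hoc partial correlations of cluster-mean ReHo with
clinical variables (case group only, controlling the same nuisance set).

Every run writes a provenance record (config, seeds, package versions,
excluded subjects with reasons, derived thresholds) sufficient to
reproduce each number in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .images import Bold4D, BrainMask
from .preprocess import (
    FilterSpec,
    MotionParams,
    bandpass_ideal,
    detrend_linear,
    discard_initial_volumes,
    qc_motion,
    read_motion,
)
from .reho import RehoMap, reho_map, smooth_gaussian, standardize
from .glm import (
    DesignMatrix,
    StatMap,
    build_design,
    fit_group_glm,
    partial_correlation,
)
from .cluster import (
    ClusterReport,
    MCNullDistribution,
    alphasim_null,
    estimate_fwhm_mm,
    extent_threshold,
    report_clusters,
)

logger = logging.getLogger("rehopipe")

DEFAULT_CLINICAL = ("cigarettes_per_day", "years_smoking", "craving")


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters, with the emulated study's defaults."""

    subject_table: str = ""
    mask_path: str | None = None  # None: full grid of the first image
    out_dir: str = "reho_out"
    tr_s: float | None = None  # None: read from NIfTI headers
    n_discard: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    qc_max_trans_mm: float = 1.5
    qc_max_rot_deg: float = 1.0
    motion_rotation_unit: str = "radians"
    neighborhood: int = 27
    tie_correction: bool = True
    smooth_fwhm_mm: float = 6.0
    voxel_p: float = 0.01
    corrected_alpha: float = 0.01
    n_iterations: int = 5000
    connectivity: int = 6
    mc_fwhm: str | float = "estimate"  # "estimate", "nominal", or explicit mm
    covariates: tuple[str, ...] = ("age", "sex", "education")
    clinical_vars: tuple[str, ...] = DEFAULT_CLINICAL
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "clinical_vars"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        d["clinical_vars"] = list(d["clinical_vars"])
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path


def preprocess_subject(bold: Bold4D, cfg: RunConfig) -> Bold4D:
    """Discard -> detrend -> band-pass for one subject."""
    out = discard_initial_volumes(bold, cfg.n_discard)
    out = detrend_linear(out)
    return bandpass_ideal(out, FilterSpec(cfg.band_low_hz, cfg.band_high_hz))


def subject_reho(bold: Bold4D, mask: BrainMask, cfg: RunConfig) -> RehoMap:
    """Full single-subject chain: preprocessing, KCC map, standardisation,
    smoothing (in that order)."""
    clean = preprocess_subject(bold, cfg)
    rmap = reho_map(clean, mask, cfg.neighborhood, tie_correction=cfg.tie_correction)
    rmap = standardize(rmap)
    return smooth_gaussian(rmap, cfg.smooth_fwhm_mm)


@dataclasses.dataclass
class GroupResult:
    """Everything the group stage produces, for reporting and reuse."""

    stat: StatMap
    design: DesignMatrix
    null: MCNullDistribution
    extent_k: int
    report: ClusterReport
    mc_fwhm_mm: tuple[float, float, float]
    posthoc: pd.DataFrame | None = None


def analyze_group(
    maps: Sequence[RehoMap],
    table: pd.DataFrame,
    cfg: RunConfig,
    mc_seed: int | None = None,
) -> GroupResult:
    """Group GLM, Monte-Carlo extent threshold, and cluster report for a
    stack of standardized, smoothed subject maps (rows of ``table`` aligned
    with ``maps``)."""
    design = build_design(table, covariates=cfg.covariates)
    stat, resid = fit_group_glm(list(maps), design, return_residuals=True)
    if cfg.mc_fwhm == "estimate":
        fwhm = estimate_fwhm_mm(resid, stat.mask)
    elif cfg.mc_fwhm == "nominal":
        fwhm = (cfg.smooth_fwhm_mm,) * 3
    else:
        fwhm = (float(cfg.mc_fwhm),) * 3
    null = alphasim_null(
        stat.mask,
        voxel_p=cfg.voxel_p,
        fwhm_mm=fwhm,
        n_iterations=cfg.n_iterations,
        connectivity=cfg.connectivity,
        seed=cfg.seed if mc_seed is None else mc_seed,
    )
    k = extent_threshold(null, cfg.corrected_alpha)
    report = report_clusters(stat, cfg.voxel_p, k, cfg.connectivity)
    return GroupResult(
        stat=stat, design=design, null=null, extent_k=k, report=report, mc_fwhm_mm=fwhm
    )


def posthoc_partial_correlations(
    maps: Sequence[RehoMap],
    table: pd.DataFrame,
    result: GroupResult,
    cfg: RunConfig,
    group: str = "group1",
) -> pd.DataFrame:
    """Partial correlation of each significant cluster's mean standardized
    ReHo with each clinical variable, in the case group only, controlling
    for the nuisance covariates.  No multiplicity correction is applied."""
    rows = []
    idx = np.flatnonzero((table["group"] == group).to_numpy())
    if idx.size == 0 or not result.report.clusters:
        return pd.DataFrame(
            columns=["cluster", "sign", "variable", "n", "r", "p"]
        )
    cov_cols = []
    sub = table.iloc[idx]
    for cov in cfg.covariates:
        v = sub[cov]
        cov_cols.append(
            (v != "F").to_numpy(dtype=float)
            if v.dtype == object
            else v.to_numpy(dtype=float)
        )
    covariates = np.column_stack(cov_cols) if cov_cols else None
    for ci, cluster in enumerate(result.report.clusters):
        vox = cluster.voxels
        means = np.array(
            [m.values[vox[:, 0], vox[:, 1], vox[:, 2]].mean() for m in maps]
        )[idx]
        for var in cfg.clinical_vars:
            if var not in table.columns:
                continue
            y = sub[var].to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() <= (0 if covariates is None else covariates.shape[1]) + 2:
                continue
            res = partial_correlation(
                means[ok], y[ok], None if covariates is None else covariates[ok]
            )
            rows.append(
                {
                    "cluster": ci,
                    "sign": "+" if cluster.sign > 0 else "-",
                    "variable": var,
                    "n": res.n,
                    "r": res.r,
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "sign", "variable", "n", "r", "p"])


def _sha1(path: Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> GroupResult:
    """Run the whole analysis from a subject table on disk.

    Writes, under ``cfg.out_dir``: per-subject ReHo maps, the QC log, the
    t map with its df sidecar, the null distribution, the cluster report,
    the post-hoc correlation table, and a provenance JSON from which every
    reported number can be re-derived.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = Path(cfg.subject_table)
    table = pd.read_csv(table_path, sep="\t")

    mask: BrainMask | None = None
    if cfg.mask_path:
        mask = BrainMask.load(cfg.mask_path)

    maps: list[RehoMap] = []
    kept_rows: list[int] = []
    qc_rows: list[dict] = []
    excluded: list[dict] = []
    for i, row in table.iterrows():
        sid = row["subject_id"]
        try:
            bold = Bold4D.load(row["image_path"], tr_s=cfg.tr_s)
            if mask is None:
                mask = BrainMask.full(bold.grid_shape, bold.affine)
            retained = bold.n_volumes - cfg.n_discard
            motion = read_motion(
                row["motion_path"], rotation_unit=cfg.motion_rotation_unit
            ).truncate_to(retained)
            qc = qc_motion(motion, cfg.qc_max_trans_mm, cfg.qc_max_rot_deg)
            qc_rows.append(
                {
                    "subject_id": sid,
                    "passed": qc.passed,
                    **{
                        f"max_trans_{ax}_mm": v
                        for ax, v in zip("xyz", qc.max_translation_mm)
                    },
                    **{
                        f"max_rot_{ax}_deg": v
                        for ax, v in zip("xyz", qc.max_rotation_deg)
                    },
                }
            )
            if not qc.passed:
                excluded.append({"subject_id": sid, "reason": "motion QC"})
                logger.warning("excluding %s: motion QC failed", sid)
                continue
            rmap = subject_reho(bold, mask, cfg)
            rmap.save(out_dir / f"{sid}_reho.nii.gz")
            maps.append(rmap)
            kept_rows.append(i)
        except Exception as exc:
            raise RuntimeError(f"stage failure for subject {sid}: {exc}") from exc

    pd.DataFrame(qc_rows).to_csv(
        out_dir / "qc_log.tsv", sep="\t", index=False, float_format="%.6g"
    )
    kept = table.iloc[kept_rows].reset_index(drop=True)
    result = analyze_group(maps, kept, cfg)
    result.posthoc = posthoc_partial_correlations(maps, kept, result, cfg)

    result.stat.save(out_dir / "group_tmap.nii.gz")
    result.null.save(out_dir / "mc_null.tsv")
    result.report.save(out_dir / "clusters.tsv")
    result.posthoc.to_csv(
        out_dir / "posthoc_partial_correlations.tsv",
        sep="\t",
        index=False,
        float_format="%.6g",
    )
    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg))),
        "subject_table_sha1": _sha1(table_path),
        "n_subjects_in": int(len(table)),
        "n_subjects_analyzed": int(len(kept)),
        "excluded": excluded,
        "df": int(result.stat.df),
        "mc_fwhm_mm": [float(v) for v in result.mc_fwhm_mm],
        "extent_k": int(result.extent_k),
        "t_crit": float(result.report.t_crit),
        "n_significant_clusters": len(result.report.clusters),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1) + "\n")
    return result
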