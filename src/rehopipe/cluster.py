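"""Monte-Carlo cluster-extent correction (AlphaSim-style).

The family-wise error of the voxelwise two-tailed threshold is controlled
by a cluster-size criterion derived from simulation: smooth Gaussian noise
fields are generated in the analysis mask, thresholded at the same
voxelwise p, and the maximum cluster size over both signs recorded per
iteration.  The extent threshold k for a corrected alpha is the smallest
cluster size whose exceedance probability under that null is <= alpha.

The smoothness (FWHM) fed to the null simulation can be the nominal
smoothing kernel or — the default in the pipeline — estimated from the
group-model residual maps, since the statistic map's smoothness, not the
applied kernel, is what the correction must match.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .images import BrainMask, voxel_sizes_mm
from .glm import StatMap, threshold_two_tailed
from .reho import FWHM_PER_SIGMA

__all__ = [
    "Cluster",
    "ClusterReport",
    "MCNullDistribution",
    "connectivity_structure",
    "label_clusters",
    "alphasim_null",
    "extent_threshold",
    "report_clusters",
    "estimate_fwhm_mm",
]


def connectivity_structure(connectivity: int) -> np.ndarray:
    """scipy.ndimage binary structure for 6- (faces), 18- (faces+edges) or
    26- (faces+edges+corners) connectivity."""
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank)


@dataclasses.dataclass(frozen=True)
class Cluster:
    sign: int  # +1 or -1
    size: int
    voxels: np.ndarray  # (size, 3) voxel indices


def label_clusters(signed_map: np.ndarray, connectivity: int = 6) -> list[Cluster]:
    """Connected components of a signed binary (+1/0/-1) map, the positive
    and negative sets labelled separately; every suprathreshold voxel lands
    in exactly one cluster."""
    signed_map = np.asarray(signed_map)
    structure = connectivity_structure(connectivity)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        labels, n = ndimage.label(signed_map == sign, structure=structure)
        for lab in range(1, n + 1):
            voxels = np.argwhere(labels == lab)
            clusters.append(Cluster(sign=sign, size=voxels.shape[0], voxels=voxels))
    return clusters


def _max_cluster_size(binary: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


@dataclasses.dataclass
class MCNullDistribution:
    """Per-iteration maximum cluster sizes of the simulated null, together
    with every parameter that shaped it."""

    max_cluster_sizes: np.ndarray
    n_iterations: int
    voxel_p: float
    fwhm_mm: tuple[float, float, float]
    connectivity: int
    mask_id: str
    seed: int

    def __post_init__(self) -> None:
        self.max_cluster_sizes = np.asarray(self.max_cluster_sizes, dtype=int)
        if self.max_cluster_sizes.shape != (self.n_iterations,):
            raise ValueError("need one max cluster size per iteration")
        if (self.max_cluster_sizes < 0).any():
            raise ValueError("cluster sizes must be >= 0")

    def save(self, path: str | Path) -> Path:
        """TSV of (iteration, max_size) plus a JSON parameter sidecar."""
        path = Path(path)
        pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "max_size": self.max_cluster_sizes,
            }
        ).to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "n_iterations": self.n_iterations,
                    "voxel_p": self.voxel_p,
                    "fwhm_mm": list(self.fwhm_mm),
                    "connectivity": self.connectivity,
                    "mask_id": self.mask_id,
                    "seed": self.seed,
                },
                indent=1,
            )
            + "\n"
        )
        return path


def _as_triple(fwhm_mm: float | tuple[float, float, float]) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(fwhm_mm, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3 or (arr < 0).any():
        raise ValueError(f"fwhm_mm must be a scalar or 3 non-negative values, got {fwhm_mm}")
    return tuple(float(v) for v in arr)


def alphasim_null(
    mask: BrainMask,
    voxel_p: float = 0.01,
    fwhm_mm: float | tuple[float, float, float] = 6.0,
    n_iterations: int = 5000,
    connectivity: int = 6,
    seed: int = 0,
) -> MCNullDistribution:
    """Simulate the null distribution of the maximum cluster size.

    Each iteration: i.i.d. standard Gaussian noise on the mask's bounding
    grid, Gaussian-smoothed to ``fwhm_mm``, restricted to the mask,
    re-standardised to zero mean / unit variance within the mask, two-tail
    thresholded at ``voxel_p``, and the maximum cluster size over both
    signs recorded (0 if no voxel survives).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    fwhm = _as_triple(fwhm_mm)
    sigma_vox = np.array(fwhm) / FWHM_PER_SIGMA / voxel_sizes_mm(mask.affine)
    structure = connectivity_structure(connectivity)
    z_crit = float(stats.norm.ppf(1.0 - voxel_p / 2.0))
    m = mask.data
    rng = np.random.default_rng(seed)
    max_sizes = np.zeros(n_iterations, dtype=int)
    for it in range(n_iterations):
        field = rng.standard_normal(m.shape)
        if sigma_vox.max() > 0:
            field = ndimage.gaussian_filter(field, sigma=sigma_vox)
        vals = field[m]
        field = (field - vals.mean()) / vals.std()
        hot = m & (field > z_crit)
        cold = m & (field < -z_crit)
        max_sizes[it] = max(
            _max_cluster_size(hot, structure), _max_cluster_size(cold, structure)
        )
    return MCNullDistribution(
        max_cluster_sizes=max_sizes,
        n_iterations=n_iterations,
        voxel_p=voxel_p,
        fwhm_mm=fwhm,
        connectivity=connectivity,
        mask_id=mask.checksum(),
        seed=seed,
    )


def extent_threshold(null: MCNullDistribution, corrected_alpha: float) -> int:
    """Smallest k with P(max cluster size >= k) <= corrected_alpha under the
    simulated null; clusters of size >= k are declared significant."""
    if corrected_alpha <= 0:
        raise ValueError("corrected_alpha must be > 0")
    if corrected_alpha >= 1:
        return 1
    sizes = np.sort(null.max_cluster_sizes)
    n = sizes.size
    for k in range(1, int(sizes[-1]) + 2):
        exceed = n - np.searchsorted(sizes, k, side="left")
        if exceed / n <= corrected_alpha:
            return k
    return int(sizes[-1]) + 1  # pragma: no cover


@dataclasses.dataclass(frozen=True)
class ClusterPeak:
    sign: int
    size: int
    peak_t: float
    peak_ijk: tuple[int, int, int]
    peak_xyz_mm: tuple[float, float, float]
    label: str = ""
    voxels: np.ndarray | None = None  # (size, 3) indices; not serialised


@dataclasses.dataclass
class ClusterReport:
    """Table of significant clusters: sign, extent, peak t and its voxel and
    world (mm) coordinates, plus a free-text anatomical label column."""

    clusters: list[ClusterPeak]
    t_crit: float
    extent_k: int
    connectivity: int
    df: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "sign": "+" if c.sign > 0 else "-",
                "size": c.size,
                "peak_t": c.peak_t,
                "i": c.peak_ijk[0],
                "j": c.peak_ijk[1],
                "k": c.peak_ijk[2],
                "x_mm": c.peak_xyz_mm[0],
                "y_mm": c.peak_xyz_mm[1],
                "z_mm": c.peak_xyz_mm[2],
                "label": c.label,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=["sign", "size", "peak_t", "i", "j", "k", "x_mm", "y_mm", "z_mm", "label"],
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(
                f"# t_crit={self.t_crit:.6g} extent_k={self.extent_k} "
                f"connectivity={self.connectivity} df={self.df}\n"
            )
            self.to_dataframe().to_csv(fh, sep="\t", index=False, float_format="%.6g")
        return path


def report_clusters(
    stat: StatMap,
    voxel_p: float,
    extent_k: int,
    connectivity: int = 6,
) -> ClusterReport:
    """Threshold the t map two-tailed at ``voxel_p``, keep clusters of size
    >= ``extent_k``, and report each cluster's peak |t| voxel in voxel and
    world coordinates (ties broken by smallest linear index)."""
    signed = threshold_two_tailed(stat, voxel_p)
    t_crit = float(stats.t.ppf(1.0 - voxel_p / 2.0, stat.df))
    affine = stat.mask.affine
    shape = stat.t_values.shape
    peaks: list[ClusterPeak] = []
    for cluster in label_clusters(signed, connectivity):
        if cluster.size < extent_k:
            continue
        idx = cluster.voxels
        t_here = stat.t_values[idx[:, 0], idx[:, 1], idx[:, 2]]
        best_abs = np.abs(t_here).max()
        linear = np.ravel_multi_index(idx.T, shape)
        candidates = np.flatnonzero(np.abs(t_here) >= best_abs - 1e-300)
        winner = candidates[np.argmin(linear[candidates])]
        ijk = tuple(int(v) for v in idx[winner])
        xyz = affine @ np.array([*ijk, 1.0])
        peaks.append(
            ClusterPeak(
                sign=cluster.sign,
                size=cluster.size,
                peak_t=float(t_here[winner]),
                peak_ijk=ijk,
                peak_xyz_mm=tuple(float(v) for v in xyz[:3]),
                voxels=idx,
            )
        )
    peaks.sort(key=lambda c: (-c.size, c.peak_ijk))
    return ClusterReport(
        clusters=peaks,
        t_crit=t_crit,
        extent_k=extent_k,
        connectivity=connectivity,
        df=stat.df,
    )


def estimate_fwhm_mm(
    resid_maps: np.ndarray, mask: BrainMask
) -> tuple[float, float, float]:
    """Estimate the per-axis spatial FWHM (mm) of a stack of maps.

    Uses the Gaussian-autocorrelation identity for white noise smoothed
    with a Gaussian kernel: the lag-1 correlation along an axis is
    rho = exp(-d^2 / (4 sigma^2)), so sigma = sqrt(-1 / (4 ln rho)) voxels.
    rho is estimated per map as 1 - MSD / (2 V) (MSD the mean squared
    difference of in-mask neighbours, V the in-mask variance) and pooled
    across maps; non-positive rho (rougher than white) maps to FWHM 0.
    """
    resid_maps = np.asarray(resid_maps, dtype=np.float64)
    if resid_maps.ndim == 3:
        resid_maps = resid_maps[None]
    m = mask.data
    vox = voxel_sizes_mm(mask.affine)
    fwhm = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        pair = m[tuple(sl_a)] & m[tuple(sl_b)]
        msd_num = 0.0
        var_num = 0.0
        for vol in resid_maps:
            centered = vol - vol[m].mean()
            d = centered[tuple(sl_b)] - centered[tuple(sl_a)]
            msd_num += float((d[pair] ** 2).mean())
            var_num += float((centered[m] ** 2).mean())
        rho = 1.0 - msd_num / (2.0 * var_num)
        if rho <= 0:
            fwhm.append(0.0)
        else:
            sigma_vox = np.sqrt(-1.0 / (4.0 * np.log(rho)))
            fwhm.append(float(FWHM_PER_SIGMA * sigma_vox * vox[axis]))
    return tuple(fwhm)
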