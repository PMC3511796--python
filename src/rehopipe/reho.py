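"""Regional homogeneity: Kendall's coefficient of concordance over voxel
neighbourhoods.

The ReHo value of a voxel is Kendall's W between its BOLD time course and
those of its nearest neighbours.  With K series of n time points, each
series converted to mid-ranks over time, R_t the rank sum at time t and
S = sum_t (R_t - mean R)^2,

    W = 12 S / (K^2 (n^3 - n) - K sum_j T_j),

where T_j = sum over tie groups g of series j of (t_g^3 - t_g) is the
standard tie correction.  W is 1 when all K rank orderings coincide, ~0 for
discordant series, and has null expectation 1/K for independent series.

The per-voxel map computation is fully vectorised: time-courses are ranked
once, and neighbourhood rank sums are accumulated by shifting the rank
volume over the 7/19/27-voxel stencil.  The tie term is recovered from the
mid-rank variance identity  sum_t (r_t - (n+1)/2)^2 = (n^3 - n)/12 - T_j/12,
which avoids any per-voxel run-length bookkeeping.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata

from .images import Bold4D, BrainMask, voxel_sizes_mm

__all__ = [
    "RehoMap",
    "kcc",
    "reho_map",
    "standardize",
    "smooth_gaussian",
    "neighborhood_offsets",
    "fwhm_to_sigma",
]

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian kernel.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Kernel truncation radius in standard deviations.  5 sigma keeps the
#: omitted tail mass below ~6e-7 so the impulse response matches the
#: closed-form Gaussian to better than 1e-6.
_TRUNCATE_SD = 5.0


def fwhm_to_sigma(fwhm_mm: float) -> float:
    return float(fwhm_mm) / FWHM_PER_SIGMA


def neighborhood_offsets(neighborhood: int) -> np.ndarray:
    """Voxel offsets (including the centre) for the 7-, 19- or 27-voxel
    stencil: faces only, faces+edges, or faces+edges+corners."""
    if neighborhood not in (7, 19, 27):
        raise ValueError(f"neighborhood must be one of 7, 19, 27, got {neighborhood}")
    offsets = []
    max_manhattan = {7: 1, 19: 2, 27: 3}[neighborhood]
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if abs(di) + abs(dj) + abs(dk) <= max_manhattan:
                    offsets.append((di, dj, dk))
    return np.array(offsets, dtype=int)


@dataclasses.dataclass
class RehoMap:
    """Voxelwise Kendall's W map with its provenance flags.

    ``flagged`` marks voxels whose neighbourhood had fewer than 2 in-mask
    series (their value is set to 0 and they are excluded from the
    standardisation mean and from group inference).
    """

    values: np.ndarray
    mask: BrainMask
    n_timepoints: int
    neighborhood: int
    standardized: bool = False
    smoothed_fwhm_mm: float | None = None
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.mask.data.shape:
            raise ValueError("values and mask grids differ")
        if self.flagged is None:
            self.flagged = np.zeros_like(self.mask.data)

    @property
    def valid_mask(self) -> np.ndarray:
        """In-mask voxels carrying a real KCC value (not flagged)."""
        return self.mask.data & ~self.flagged

    def metadata(self) -> dict:
        return {
            "n_timepoints": int(self.n_timepoints),
            "neighborhood": int(self.neighborhood),
            "standardized": bool(self.standardized),
            "smoothed_fwhm_mm": self.smoothed_fwhm_mm,
            "n_flagged": int(self.flagged.sum()),
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.values.astype(np.float32), self.mask.affine)
        img.to_filename(str(path))
        sidecar = path.with_name(path.name.split(".")[0] + ".json")
        sidecar.write_text(json.dumps(self.metadata(), indent=1) + "\n")
        return path


def _tie_term_from_ranks(ranks: np.ndarray) -> np.ndarray:
    """T_j = (n^3 - n) - 12 sum_t (r_t - (n+1)/2)^2, exact for mid-ranks."""
    n = ranks.shape[-1]
    dev = ranks - (n + 1) / 2.0
    t = (n**3 - n) - 12.0 * np.einsum("...t,...t->...", dev, dev)
    # clip tiny negative rounding noise; exact values are >= 0
    return np.maximum(t, 0.0)


def kcc(series_matrix: np.ndarray, tie_correction: bool = True) -> float:
    """Kendall's coefficient of concordance of K time series over n points.

    Parameters
    ----------
    series_matrix
        (K, n) array, one row per series.
    tie_correction
        Apply the mid-rank tie correction term (default). With it off, tied
        data bias W downward, matching implementations that ignore ties.

    Returns
    -------
    W in [0, 1].  An all-constant set of series has an undefined W (zero
    denominator); it is returned as 0.0 with a warning.
    """
    x = np.asarray(series_matrix, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"series_matrix must be 2-D (K, n), got ndim={x.ndim}")
    k, n = x.shape
    if k < 2:
        raise ValueError(f"need at least 2 series, got K={k}")
    if n < 2:
        raise ValueError(f"need at least 2 time points, got n={n}")
    ranks = rankdata(x, axis=1)
    r_t = ranks.sum(axis=0)
    s = float(((r_t - k * (n + 1) / 2.0) ** 2).sum())
    tie_sum = float(_tie_term_from_ranks(ranks).sum()) if tie_correction else 0.0
    denom = k * k * (n**3 - n) - k * tie_sum
    if denom <= 0:
        warnings.warn("all series constant: Kendall's W undefined, returning 0")
        return 0.0
    return float(np.clip(12.0 * s / denom, 0.0, 1.0))


def _neighbor_sum(volume: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Sum of ``volume`` over the stencil, zero outside the grid.

    Works for 3-D volumes and 4-D (…, T) stacks alike.
    """
    pad = [(1, 1), (1, 1), (1, 1)] + [(0, 0)] * (volume.ndim - 3)
    padded = np.pad(volume, pad, mode="constant")
    out = np.zeros_like(volume, dtype=np.float64)
    nx, ny, nz = volume.shape[:3]
    for di, dj, dk in offsets:
        out += padded[1 + di : 1 + di + nx, 1 + dj : 1 + dj + ny, 1 + dk : 1 + dk + nz]
    return out


def reho_map(
    bold: Bold4D,
    mask: BrainMask,
    neighborhood: int = 27,
    tie_correction: bool = True,
) -> RehoMap:
    """Voxelwise Kendall's W over each in-mask voxel's neighbourhood.

    K at a voxel is 1 + the number of in-mask neighbours under the chosen
    stencil; mask-edge voxels simply use the neighbours they have.  Voxels
    with K < 2 are set to 0 and flagged.
    """
    if not mask.same_grid(bold):
        raise ValueError("BOLD image and mask are on different grids")
    data = np.asarray(bold.data, dtype=np.float64)
    n_t = data.shape[3]
    offsets = neighborhood_offsets(neighborhood)
    m = mask.data

    ranks = rankdata(data, axis=3)
    if tie_correction:
        tie = _tie_term_from_ranks(ranks) * m
    else:
        tie = np.zeros(data.shape[:3])
    ranks *= m[..., None]

    k_map = _neighbor_sum(m.astype(np.float64), offsets)  # series count per voxel
    r_sum = _neighbor_sum(ranks, offsets)  # (X, Y, Z, T) rank sums
    tie_sum = _neighbor_sum(tie, offsets)

    dev = r_sum - k_map[..., None] * (n_t + 1) / 2.0
    s = np.einsum("...t,...t->...", dev, dev)
    denom = k_map**2 * (n_t**3 - n_t) - k_map * tie_sum

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, 12.0 * s / np.where(denom > 0, denom, 1.0), 0.0)
    w = np.clip(w, 0.0, 1.0)
    flagged = m & (k_map < 2)
    w[~m | flagged] = 0.0
    return RehoMap(
        values=w,
        mask=mask,
        n_timepoints=n_t,
        neighborhood=neighborhood,
        flagged=flagged,
    )


def standardize(rmap: RehoMap) -> RehoMap:
    """Divide the map by its own mean over the (unflagged) mask, so the
    within-mask mean becomes exactly 1.  Subject maps standardised this way
    are comparable across subjects regardless of each one's overall KCC
    level."""
    valid = rmap.valid_mask
    mean = float(rmap.values[valid].mean()) if valid.any() else 0.0
    if mean <= 0:
        raise ValueError(f"within-mask mean ReHo is {mean}; cannot standardize")
    values = rmap.values / mean
    values[~valid] = 0.0
    return RehoMap(
        values=values,
        mask=rmap.mask,
        n_timepoints=rmap.n_timepoints,
        neighborhood=rmap.neighborhood,
        standardized=True,
        smoothed_fwhm_mm=rmap.smoothed_fwhm_mm,
        flagged=rmap.flagged,
    )


def _masked_gaussian(
    values: np.ndarray, mask: np.ndarray, sigma_vox: np.ndarray
) -> np.ndarray:
    """Gaussian smoothing with out-of-mask voxels excluded from the kernel:
    smooth(values * mask) / smooth(mask), re-zeroed outside the mask."""
    num = gaussian_filter(
        values * mask, sigma=sigma_vox, mode="constant", truncate=_TRUNCATE_SD
    )
    den = gaussian_filter(
        mask.astype(np.float64), sigma=sigma_vox, mode="constant", truncate=_TRUNCATE_SD
    )
    out = np.zeros_like(num)
    inside = mask.astype(bool)
    out[inside] = num[inside] / den[inside]
    return out


def smooth_gaussian(rmap: RehoMap, fwhm_mm: float) -> RehoMap:
    """Isotropic Gaussian smoothing (FWHM in mm, converted per axis to
    voxels from the affine), restricted to the mask.  FWHM 0 is the
    identity; a constant map stays constant because the masked kernel is
    renormalised."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        values = rmap.values.copy()
    else:
        sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_sizes_mm(rmap.mask.affine)
        values = _masked_gaussian(rmap.values, rmap.valid_mask, sigma_vox)
    return RehoMap(
        values=values,
        mask=rmap.mask,
        n_timepoints=rmap.n_timepoints,
        neighborhood=rmap.neighborhood,
        standardized=rmap.standardized,
        smoothed_fwhm_mm=float(fwhm_mm),
        flagged=rmap.flagged,
    )
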