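"""Core image containers: 4D BOLD series and 3D brain masks.

Thin dataclass wrappers around numpy arrays plus a NIfTI-1 voxel-to-world
affine, with load/save going through nibabel. The time axis is always last
(X, Y, Z, T) and the repetition time (TR) is carried explicitly in seconds;
on save it is stored in the NIfTI header's fourth zoom so a round trip
preserves it.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Bold4D", "BrainMask", "voxel_sizes_mm"]


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (norms of the affine's spatial columns)."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular (zero voxel volume)")
    return affine


@dataclasses.dataclass
class Bold4D:
    """A single subject's 4D BOLD time series.

    Parameters
    ----------
    data
        Array of shape (X, Y, Z, T), T >= 2.
    affine
        4x4 voxel-to-world transform in mm (invertible).
    tr_s
        Repetition time (sampling interval of volumes) in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 volumes")
        if not self.tr_s > 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        self.affine = _check_affine(self.affine)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(tuple(voxel_sizes_mm(self.affine)) + (self.tr_s,))
        img.header.set_xyzt_units("mm", "sec")
        img.to_filename(str(path))
        return path

    @classmethod
    def load(cls, path: str | Path, tr_s: float | None = None) -> "Bold4D":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if tr_s is None:
            zooms = img.header.get_zooms()
            if len(zooms) < 4 or zooms[3] <= 0:
                raise ValueError(
                    f"{path}: TR not recorded in header; pass tr_s explicitly"
                )
            tr_s = float(zooms[3])
        return cls(data=data, affine=img.affine, tr_s=tr_s)


@dataclasses.dataclass
class BrainMask:
    """Boolean analysis mask on the same grid as the images it masks."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        if not self.data.any():
            raise ValueError("mask contains no voxels")
        self.affine = _check_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def checksum(self) -> str:
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.data).tobytes())
        h.update(np.ascontiguousarray(self.affine).tobytes())
        return h.hexdigest()[:12]

    def same_grid(self, other: "Bold4D | BrainMask") -> bool:
        shape = other.data.shape[:3]
        return shape == self.data.shape and np.allclose(other.affine, self.affine)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        img.to_filename(str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BrainMask":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.dataobj) > 0, affine=img.affine)

    @classmethod
    def full(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "BrainMask":
        return cls(data=np.ones(shape, dtype=bool), affine=affine)
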