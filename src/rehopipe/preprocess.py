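"""Single-subject temporal preprocessing.

Stages, in pipeline order: discard of initial (pre-steady-state) volumes,
motion QC gating, per-voxel linear detrending, and ideal (frequency-
rectangular) band-pass filtering of the low-frequency fluctuation band.
Spatial steps (slice timing, realignment, normalisation) are out of scope:
inputs are assumed to already live on a common grid.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .images import Bold4D

__all__ = [
    "FilterSpec",
    "MotionParams",
    "QCResult",
    "read_motion",
    "discard_initial_volumes",
    "qc_motion",
    "detrend_linear",
    "bandpass_ideal",
    "bandlimit_series",
]

#: Low-frequency fluctuation band conventionally used for resting-state ReHo.
DEFAULT_BAND_HZ = (0.01, 0.08)
DEFAULT_N_DISCARD = 10
DEFAULT_MAX_TRANS_MM = 1.5
DEFAULT_MAX_ROT_DEG = 1.0


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Pass band [low_hz, high_hz] for the ideal temporal filter."""

    low_hz: float = DEFAULT_BAND_HZ[0]
    high_hz: float = DEFAULT_BAND_HZ[1]

    def validate(self, tr_s: float) -> None:
        nyquist = 1.0 / (2.0 * tr_s)
        if not (0.0 <= self.low_hz < self.high_hz):
            raise ValueError(f"need 0 <= low < high, got [{self.low_hz}, {self.high_hz}]")
        if self.high_hz > nyquist + 1e-12:
            raise ValueError(
                f"high_hz={self.high_hz} exceeds Nyquist {nyquist:.4g} Hz at TR={tr_s}s"
            )


@dataclasses.dataclass
class MotionParams:
    """Rigid-body motion estimates, one row per volume.

    ``rotation_unit`` must be declared explicitly ("radians" for the SPM
    rp_*.txt dialect, "degrees" otherwise); silently guessing the unit is
    the classic way to break the QC rule, so there is no default.
    """

    translations: np.ndarray  # (T, 3) mm
    rotations: np.ndarray  # (T, 3)
    rotation_unit: str

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (T, 3)")
        if self.translations.shape[0] < 1:
            raise ValueError("motion table needs at least one row")
        if self.rotation_unit not in ("radians", "degrees"):
            raise ValueError(
                f"rotation_unit must be 'radians' or 'degrees', got {self.rotation_unit!r}"
            )

    @property
    def n_rows(self) -> int:
        return self.translations.shape[0]

    def rotations_deg(self) -> np.ndarray:
        if self.rotation_unit == "degrees":
            return self.rotations
        return np.degrees(self.rotations)

    def truncate_to(self, n_volumes: int) -> "MotionParams":
        """Match the retained volumes: T rows are truncated from the front
        (the discarded volumes are the initial ones); a table that already
        has ``n_volumes`` rows passes through; any other length is an error.
        """
        if self.n_rows == n_volumes:
            return self
        if self.n_rows > n_volumes:
            return MotionParams(
                translations=self.translations[self.n_rows - n_volumes :],
                rotations=self.rotations[self.n_rows - n_volumes :],
                rotation_unit=self.rotation_unit,
            )
        raise ValueError(
            f"motion table has {self.n_rows} rows but {n_volumes} volumes are retained"
        )


def read_motion(path: str | Path, rotation_unit: str) -> MotionParams:
    """Read a whitespace-delimited 6-column motion file (SPM rp_*.txt dialect:
    3 translations in mm then 3 rotations). The caller must declare the
    rotation unit."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {arr.shape[1]}")
    return MotionParams(
        translations=arr[:, :3], rotations=arr[:, 3:], rotation_unit=rotation_unit
    )


@dataclasses.dataclass(frozen=True)
class QCResult:
    passed: bool
    max_translation_mm: tuple[float, float, float]
    max_rotation_deg: tuple[float, float, float]
    max_trans_threshold_mm: float
    max_rot_threshold_deg: float


def discard_initial_volumes(bold: Bold4D, n_discard: int = DEFAULT_N_DISCARD) -> Bold4D:
    """Drop the first ``n_discard`` volumes (scanner equilibration period).

    The retained volumes are preserved bit-exactly; affine and TR are
    unchanged.
    """
    n_discard = int(n_discard)
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= bold.n_volumes:
        raise ValueError(
            f"discarding {n_discard} of {bold.n_volumes} volumes would leave no data"
        )
    return Bold4D(
        data=bold.data[..., n_discard:].copy(), affine=bold.affine, tr_s=bold.tr_s
    )


def qc_motion(
    motion: MotionParams,
    max_trans_mm: float = DEFAULT_MAX_TRANS_MM,
    max_rot_deg: float = DEFAULT_MAX_ROT_DEG,
) -> QCResult:
    """Head-motion exclusion rule: fail if any |translation| exceeds
    ``max_trans_mm`` on any axis or any |rotation| exceeds ``max_rot_deg``.

    The report carries the six per-axis absolute maxima so exclusions can be
    audited.
    """
    t_max = np.abs(motion.translations).max(axis=0)
    r_max = np.abs(motion.rotations_deg()).max(axis=0)
    passed = bool((t_max <= max_trans_mm).all() and (r_max <= max_rot_deg).all())
    return QCResult(
        passed=passed,
        max_translation_mm=tuple(float(v) for v in t_max),
        max_rotation_deg=tuple(float(v) for v in r_max),
        max_trans_threshold_mm=float(max_trans_mm),
        max_rot_threshold_deg=float(max_rot_deg),
    )


def detrend_linear(bold: Bold4D) -> Bold4D:
    """Remove the per-voxel least-squares linear trend, keeping the temporal mean.

    Writing the fitted line as a + b t, the output is x - b (t - t_bar): the
    slope and the intercept's deviation are removed and the original mean is
    restored exactly.
    """
    data = np.asarray(bold.data, dtype=np.float64)
    n_t = data.shape[3]
    if n_t < 3:
        raise ValueError("detrending needs at least 3 time points")
    t = np.arange(n_t, dtype=np.float64)
    tc = t - t.mean()
    denom = float((tc**2).sum())
    slope = data @ tc / denom  # (X, Y, Z)
    out = data - slope[..., None] * tc
    return Bold4D(data=out, affine=bold.affine, tr_s=bold.tr_s)


def _band_mask(n_t: int, tr_s: float, spec: FilterSpec) -> np.ndarray:
    """Boolean keep-mask over rfft bins: DC always kept; a bin is in band if
    its exact DFT frequency lies within [low, high] inclusive."""
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    keep = (freqs >= spec.low_hz) & (freqs <= spec.high_hz)
    keep[0] = True  # DC re-added so the output mean equals the input mean
    return keep


def bandpass_ideal(bold: Bold4D, spec: FilterSpec = FilterSpec()) -> Bold4D:
    """Ideal (frequency-rectangular) band-pass along time.

    DFT components with frequency in [low_hz, high_hz] (inclusive at the
    exact bin frequencies) are kept, all others zeroed; the zero-frequency
    component is retained so the temporal mean is unchanged.
    """
    spec.validate(bold.tr_s)
    data = np.asarray(bold.data, dtype=np.float64)
    n_t = data.shape[3]
    spectrum = np.fft.rfft(data, axis=3)
    spectrum[..., ~_band_mask(n_t, bold.tr_s, spec)] = 0.0
    out = np.fft.irfft(spectrum, n=n_t, axis=3)
    return Bold4D(data=out, affine=bold.affine, tr_s=bold.tr_s)


def bandlimit_series(
    series: np.ndarray, tr_s: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Apply the same ideal band-pass to a bare 1-D series (mean removed)."""
    series = np.asarray(series, dtype=np.float64)
    n_t = series.shape[-1]
    spectrum = np.fft.rfft(series, axis=-1)
    keep = _band_mask(n_t, tr_s, spec)
    keep = keep.copy()
    keep[0] = False
    spectrum[..., ~keep] = 0.0
    return np.fft.irfft(spectrum, n=n_t, axis=-1)
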