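"""Second-level group inference on standardized ReHo maps.

A voxelwise ordinary-least-squares fit of subject ReHo on a design with an
intercept, a group indicator, and nuisance covariates of no interest (age,
sex, education).  The group-difference t statistic and its df = N - p feed
the cluster-extent correction; post-hoc partial correlations relate
cluster-mean ReHo to clinical variables controlling for the same nuisance
set.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from .images import BrainMask
from .reho import RehoMap

__all__ = [
    "DesignMatrix",
    "StatMap",
    "build_design",
    "fit_group_glm",
    "threshold_two_tailed",
    "partial_correlation",
    "PartialCorrResult",
]

DEFAULT_COVARIATES = ("age", "sex", "education")


@dataclasses.dataclass
class DesignMatrix:
    """Subject-level design: intercept, group indicator (group1=1), then
    covariates.  Continuous covariates are mean-centered (the group
    coefficient and its t are unchanged; conditioning improves)."""

    matrix: np.ndarray  # (N, p)
    columns: list[str]
    group_column: str = "group"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] <= self.matrix.shape[1]:
            raise ValueError("design must be (N, p) with N > p")
        if self.group_column not in self.columns:
            raise ValueError(f"no {self.group_column!r} column in design")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            raise ValueError(
                "rank-deficient design: collinear columns "
                f"{self._collinear_columns()}"
            )

    def _collinear_columns(self) -> list[str]:
        x = self.matrix
        bad = []
        for j in range(x.shape[1]):
            others = np.delete(x, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
            if np.allclose(others @ beta, x[:, j], atol=1e-8):
                bad.append(self.columns[j])
        return bad

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def df(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]

    @property
    def group_index(self) -> int:
        return self.columns.index(self.group_column)


def build_design(
    table: pd.DataFrame,
    group_col: str = "group",
    group1: str = "group1",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    sex_reference: str = "F",
) -> DesignMatrix:
    """Design matrix from a subject table, row order preserved.

    Sex becomes a 0/1 indicator (``sex_reference`` coded 0); other
    covariates are treated as continuous and mean-centered.
    """
    cols = [np.ones(len(table))]
    names = ["intercept"]
    group = (table[group_col] == group1).to_numpy(dtype=float)
    cols.append(group)
    names.append("group")
    for cov in covariates:
        v = table[cov]
        if cov == "sex" or v.dtype == object:
            x = (v != sex_reference).to_numpy(dtype=float)
        else:
            x = v.to_numpy(dtype=float)
            x = x - x.mean()
        cols.append(x)
        names.append(cov)
    return DesignMatrix(matrix=np.column_stack(cols), columns=names)


@dataclasses.dataclass
class StatMap:
    """Voxelwise t statistics for one contrast, with df = N - p."""

    t_values: np.ndarray
    df: int
    contrast: str
    mask: BrainMask

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=np.float64)
        if self.t_values.shape != self.mask.data.shape:
            raise ValueError("t map and mask grids differ")
        if not np.isfinite(self.t_values[self.mask.data]).all():
            raise ValueError("non-finite t values inside the mask")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.t_values.astype(np.float32), self.mask.affine)
        img.to_filename(str(path))
        sidecar = path.with_name(path.name.split(".")[0] + ".json")
        sidecar.write_text(
            json.dumps({"df": int(self.df), "contrast": self.contrast}, indent=1) + "\n"
        )
        return path


def fit_group_glm(
    maps: list[RehoMap],
    design: DesignMatrix,
    return_residuals: bool = False,
) -> StatMap | tuple[StatMap, np.ndarray]:
    """Voxelwise OLS of ReHo on the design; t for the group column.

    Voxels flagged in any subject's map (edge voxels with too few
    neighbours) are excluded from inference — their ReHo is a policy
    artifact, not data.  With ``return_residuals`` the (N, X, Y, Z) residual
    stack is also returned, for smoothness estimation.
    """
    if len(maps) != design.n_subjects:
        raise ValueError(f"{len(maps)} maps but design has {design.n_subjects} rows")
    groups = design.matrix[:, design.group_index]
    if (groups == 1).sum() < 2 or (groups == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    mask0 = maps[0].mask
    for m in maps:
        if not mask0.same_grid(m.mask):
            raise ValueError("subject maps are on different grids/masks")
    valid = np.logical_and.reduce([m.valid_mask for m in maps])
    if not valid.any():
        raise ValueError("no voxel is valid across all subjects")

    y = np.stack([m.values[valid] for m in maps])  # (N, V)
    x = design.matrix
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    g = design.group_index
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[g, g], 1e-300))
    t_vals = beta[g] / se

    t_map = np.zeros(mask0.data.shape)
    t_map[valid] = t_vals
    stat = StatMap(
        t_values=t_map,
        df=df,
        contrast="group1 - group2",
        mask=BrainMask(data=valid, affine=mask0.affine),
    )
    if not return_residuals:
        return stat
    resid_maps = np.zeros((n,) + mask0.data.shape)
    resid_maps[:, valid] = resid
    return stat, resid_maps


def threshold_two_tailed(stat: StatMap, voxel_p: float) -> np.ndarray:
    """Signed binary map: +1 where t > t_crit, -1 where t < -t_crit, with
    t_crit the upper voxel_p/2 quantile of t(df)."""
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    t_crit = float(stats.t.ppf(1.0 - voxel_p / 2.0, stat.df))
    out = np.zeros(stat.t_values.shape, dtype=np.int8)
    inside = stat.mask.data
    out[inside & (stat.t_values > t_crit)] = 1
    out[inside & (stat.t_values < -t_crit)] = -1
    return out


@dataclasses.dataclass(frozen=True)
class PartialCorrResult:
    r: float
    p: float
    n: int
    df: int


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> PartialCorrResult:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualised on [intercept, covariates] by OLS; r is
    the Pearson correlation of the residuals, and the two-tailed p comes
    from t = r sqrt(df / (1 - r^2)) with df = N - 2 - k (k covariates).
    With no covariates this reduces exactly to the plain Pearson
    correlation and its p value.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=np.float64)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = c.shape[1]
    if n <= k + 2:
        raise ValueError(f"need N > k + 2 observations, got N={n}, k={k}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable: partial correlation undefined")
    z = np.column_stack([np.ones(n), c])
    proj = z @ np.linalg.lstsq(z, np.column_stack([x, y]), rcond=None)[0]
    rx = x - proj[:, 0]
    ry = y - proj[:, 1]
    sx, sy = np.sqrt((rx**2).sum()), np.sqrt((ry**2).sum())
    df = n - 2 - k
    if sx <= 1e-12 * np.abs(x).max() or sy <= 1e-12 * np.abs(y).max():
        # the variable lies in the covariate span: its residual is the zero
        # vector, orthogonal to everything, so the partial correlation is 0
        return PartialCorrResult(r=0.0, p=1.0, n=n, df=df)
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p=p, n=n, df=df)
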