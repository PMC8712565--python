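"""Block-design GLM: first-level contrast t-maps and second-level t-tests.

First level is plain per-voxel ordinary least squares of each subject's
(preprocessed) timeseries on HRF-convolved condition regressors — a fixed
effects model without prewhitening. Contrasts are tested with Student t
statistics; second-level inference uses one-sample and paired t-tests over
subjects' first-level contrast values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import GridSpec, SubjectTimeseries
from .synthetic import ACTIVE, STATIC, BlockDesign

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "TMap",
    "build_design",
    "fit_glm",
    "contrast_tmap",
    "one_sample_tmap",
    "paired_tmap",
    "threshold_tmap",
]

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """Time x regressors matrix with stable column names."""

    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("one name per design column required")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < "
                f"{self.matrix.shape[1]} columns: {self.names})"
            )

    def contrast_vector(self, contrast: str) -> np.ndarray:
        """Named contrasts: 'active', 'static' or 'active-minus-static'."""
        c = np.zeros(self.matrix.shape[1])
        if contrast == "active-minus-static":
            c[self.names.index(ACTIVE)] = 1.0
            c[self.names.index(STATIC)] = -1.0
        elif contrast in self.names:
            c[self.names.index(contrast)] = 1.0
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
        return c


@dataclass
class GlmFit:
    betas: np.ndarray          # voxels x regressors
    sigma2: np.ndarray         # per-voxel residual variance
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray


@dataclass
class TMap:
    """Per-voxel contrast t statistics over masked voxels."""

    t: np.ndarray
    df: int
    level: str = "first"          # 'first' or 'second'
    contrast: str = ""
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")


def build_design(
    design: BlockDesign,
    hrf: np.ndarray,
    highpass_applied: bool = True,
    conditions: tuple[str, ...] = (ACTIVE, STATIC),
) -> DesignMatrix:
    """Condition boxcars convolved with the HRF, initial volumes dropped.

    An intercept is added only when the data were *not* high-pass filtered:
    with both condition regressors present, the constant is (after HRF
    convolution, nearly) a linear combination of them, and the DCT drift
    basis already removed the mean.
    """
    hrf = np.asarray(hrf, dtype=float)
    cols, names = [], []
    for cond in conditions:
        reg = np.convolve(design.boxcar(cond), hrf)[: design.n_volumes]
        cols.append(reg[design.drop_initial:])
        names.append(cond)
    if not highpass_applied:
        cols.append(np.ones(design.n_analyzed))
        names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), names=tuple(names))


def fit_glm(ts: SubjectTimeseries | np.ndarray, X: DesignMatrix) -> GlmFit:
    """Per-voxel ordinary least squares."""
    data = ts.data if isinstance(ts, SubjectTimeseries) else np.asarray(ts, float)
    mat = X.matrix
    if mat.shape[0] != data.shape[1]:
        raise ValueError(
            f"design has {mat.shape[0]} rows but data has {data.shape[1]} "
            "time points"
        )
    xtx = mat.T @ mat
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("X'X is singular or near-singular")
    xtx_inv = np.linalg.inv(xtx)
    betas = data @ mat @ xtx_inv          # voxels x p
    resid = data - betas @ mat.T
    df = mat.shape[0] - np.linalg.matrix_rank(mat)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.einsum("vt,vt->v", resid, resid) / df
    return GlmFit(betas=betas, sigma2=sigma2, df=df, design=X, xtx_inv=xtx_inv)


def contrast_tmap(
    fit: GlmFit, c: np.ndarray, grid: GridSpec | None = None,
    contrast_name: str = "",
) -> TMap:
    """t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c) per voxel.

    Voxels with exactly zero residual variance get t = 0 when the effect is
    also zero and signed infinity otherwise (noiseless planted effects).
    """
    c = np.asarray(c, dtype=float)
    if c.size != fit.betas.shape[1]:
        raise ValueError(
            f"contrast length {c.size} != {fit.betas.shape[1]} regressors"
        )
    var_c = float(c @ fit.xtx_inv @ c)
    if c.any() and var_c <= 0:
        raise ValueError("contrast variance c'(X'X)^-1 c is not positive")
    effect = fit.betas @ c
    if not c.any():
        return TMap(t=np.zeros_like(effect), df=fit.df, grid=grid,
                    contrast=contrast_name)
    denom = np.sqrt(fit.sigma2 * var_c)
    t = np.zeros_like(effect)
    ok = denom > 0
    t[ok] = effect[ok] / denom[ok]
    degenerate = ~ok & (effect != 0)
    if degenerate.any():
        logger.warning(
            "%d voxels have zero residual variance with nonzero effect; "
            "t set to signed infinity", int(degenerate.sum()),
        )
        t[degenerate] = np.sign(effect[degenerate]) * np.inf
    return TMap(t=t, df=fit.df, level="first", contrast=contrast_name,
                grid=grid)


def _one_sample_t(values: np.ndarray) -> tuple[np.ndarray, int]:
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    t = np.zeros_like(mean)
    ok = se > 0
    t[ok] = mean[ok] / se[ok]
    degenerate = ~ok & (mean != 0)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    return t, n - 1


def one_sample_tmap(
    contrast_values: np.ndarray, grid: GridSpec | None = None,
    contrast_name: str = "",
) -> TMap:
    """Second-level one-sample t over subjects (rows) per voxel (columns)."""
    contrast_values = np.asarray(contrast_values, dtype=float)
    if contrast_values.ndim != 2 or contrast_values.shape[0] < 2:
        raise ValueError("need a subjects x voxels matrix with >= 2 subjects")
    t, df = _one_sample_t(contrast_values)
    return TMap(t=t, df=df, level="second", contrast=contrast_name, grid=grid)


def paired_tmap(
    arm_a: np.ndarray, arm_b: np.ndarray, grid: GridSpec | None = None,
    contrast_name: str = "",
) -> TMap:
    """Paired t on per-voxel differences ``arm_b - arm_a``.

    Positive t means arm B (conventionally the gCCA-processed arm) exceeds
    arm A.
    """
    arm_a = np.asarray(arm_a, dtype=float)
    arm_b = np.asarray(arm_b, dtype=float)
    if arm_a.shape != arm_b.shape:
        raise ValueError(
            f"arms have mismatched shapes {arm_a.shape} vs {arm_b.shape}"
        )
    if arm_a.ndim != 2 or arm_a.shape[0] < 2:
        raise ValueError("need subjects x voxels matrices with >= 2 subjects")
    t, df = _one_sample_t(arm_b - arm_a)
    return TMap(t=t, df=df, level="second", contrast=contrast_name, grid=grid)


def threshold_tmap(
    tmap: TMap, p_uncorrected: float, tail: str = "positive"
) -> np.ndarray:
    """Boolean suprathreshold mask at a one-tailed uncorrected p threshold."""
    if not 0 < p_uncorrected < 1:
        raise ValueError("p_uncorrected must lie in (0, 1)")
    t_crit = stats.t.ppf(1.0 - p_uncorrected, tmap.df)
    logger.info(
        "thresholding at p<%g one-tailed (df=%d): t_crit=%.4f",
        p_uncorrected, tmap.df, t_crit,
    )
    if tail == "positive":
        return tmap.t > t_crit
    if tail == "negative":
        return -tmap.t > t_crit
    raise ValueError("tail must be 'positive' or 'negative'")
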