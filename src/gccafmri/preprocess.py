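"""Conventional preprocessing: spatial smoothing and DCT high-pass filtering.

Both pipeline arms receive the identical treatment: isotropic Gaussian
smoothing of each volume (FWHM in mm, zero-padded outside the grid, then
re-masked) followed by removal of a discrete-cosine drift basis with periods
longer than the cutoff — the SPM-style high-pass. The drift basis includes
the constant, so filtered voxel timeseries have zero mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridSpec, SubjectTimeseries

__all__ = ["PreprocessConfig", "smooth_volumes", "smooth_masked",
           "dct_drift_basis", "highpass", "preprocess_subject"]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PreprocessConfig:
    smooth_fwhm_mm: float = 8.0
    highpass_cutoff_s: float = 128.0
    smooth_first: bool = True

    def __post_init__(self) -> None:
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be non-negative")
        if self.highpass_cutoff_s <= 0:
            raise ValueError("highpass_cutoff_s must be positive")


def smooth_volumes(ts: SubjectTimeseries, fwhm_mm: float) -> SubjectTimeseries:
    """Convolve every time-point's volume with an isotropic Gaussian.

    Values outside the mask are treated as zero; the result is re-masked.
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return ts.copy_with(ts.data.copy())
    grid = ts.grid
    sigma_vox = [fwhm_mm / (_FWHM_TO_SIGMA * v) for v in grid.voxel_size_mm]
    vols = grid.embed(ts.data)  # (x, y, z, t), zeros outside mask
    smoothed = ndimage.gaussian_filter(
        vols, sigma=sigma_vox + [0.0], mode="constant", cval=0.0
    )
    return ts.copy_with(grid.extract(smoothed))


def smooth_masked(grid: GridSpec, values: np.ndarray, fwhm_mm: float) -> np.ndarray:
    """Smooth a single masked-voxel vector with the same kernel as the data."""
    if fwhm_mm <= 0:
        return np.asarray(values, dtype=float).copy()
    sigma_vox = [fwhm_mm / (_FWHM_TO_SIGMA * v) for v in grid.voxel_size_mm]
    vol = ndimage.gaussian_filter(
        grid.embed(np.asarray(values, dtype=float)), sigma=sigma_vox,
        mode="constant", cval=0.0,
    )
    return grid.extract(vol)


def dct_drift_basis(n_timepoints: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift regressors with periods >= ``cutoff_s``.

    Column r (r = 0, 1, ...) is cos(pi * r * (2t+1) / (2T)); the constant
    (r = 0) is always included. The number of columns follows the SPM
    convention ``floor(2 T TR / cutoff) + 1``.
    """
    T = n_timepoints
    n_basis = int(np.floor(2.0 * T * tr_s / cutoff_s)) + 1
    n_basis = max(1, min(n_basis, T))
    t = np.arange(T)
    basis = np.cos(
        np.pi * np.outer(2 * t + 1, np.arange(n_basis)) / (2.0 * T)
    )
    # Orthonormalize (DCT-II columns are orthogonal; normalize for stability)
    basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def highpass(ts: SubjectTimeseries, cutoff_s: float) -> SubjectTimeseries:
    """Project out the DCT drift basis (including the constant) per voxel."""
    if cutoff_s <= 0:
        raise ValueError("cutoff_s must be positive")
    if ts.n_timepoints < 2:
        raise ValueError("need at least 2 time points to high-pass filter")
    basis = dct_drift_basis(ts.n_timepoints, ts.tr_s, cutoff_s)
    # residual of per-voxel OLS on the orthonormal basis
    fitted = (ts.data @ basis) @ basis.T
    return ts.copy_with(ts.data - fitted)


def preprocess_subject(
    ts: SubjectTimeseries, config: PreprocessConfig
) -> tuple[SubjectTimeseries, np.ndarray]:
    """Smooth then high-pass filter (order configurable).

    Returns the filtered timeseries together with the per-voxel temporal
    mean taken just before filtering — the signal level the high-pass
    removes, needed later for paper-style SNR estimation.
    """
    if config.smooth_first:
        ts = smooth_volumes(ts, config.smooth_fwhm_mm)
        mean = ts.data.mean(axis=1)
        ts = highpass(ts, config.highpass_cutoff_s)
    else:
        mean = ts.data.mean(axis=1)
        ts = highpass(ts, config.highpass_cutoff_s)
        ts = smooth_volumes(ts, config.smooth_fwhm_mm)
    return ts, mean
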