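"""ROI-level statistics and the original-vs-gCCA comparison report.

Covers the region-of-interest measures used to quantify the sensitivity
gain: suprathreshold extent and peak t per ROI, the temporal SNR (ROI grand
mean over the temporal standard deviation of a noise-region-averaged
timeseries), Monte-Carlo cluster-extent thresholds on smoothed Gaussian
noise, and percent-change / paired-t / repeated-measures-ANOVA summaries
across subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import TMap, threshold_tmap
from .grids import GridSpec, SubjectTimeseries

__all__ = [
    "RoiReport",
    "roi_extent_and_peak",
    "roi_snr",
    "cluster_label",
    "monte_carlo_cluster_threshold",
    "rm_anova_two_way",
    "compare_arms",
]

logger = logging.getLogger(__name__)

METRICS = ("extent", "peak_t", "snr")


def _roi_indices(grid: GridSpec, roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != grid.dims:
        raise ValueError(f"ROI shape {roi.shape} != grid dims {grid.dims}")
    inside = grid.extract(roi)
    if not inside.any():
        raise ValueError("ROI contains no masked voxels")
    return inside


def roi_extent_and_peak(
    tmap: TMap, roi: np.ndarray, p_thresh: float = 0.01,
    grid: GridSpec | None = None,
) -> tuple[int, float]:
    """Suprathreshold voxel count and peak t inside an ROI.

    The peak is reported even when it falls below the extent criterion (a
    warning is logged in that case).
    """
    grid = grid or tmap.grid
    if grid is None:
        raise ValueError("a GridSpec is required to interpret the ROI mask")
    inside = _roi_indices(grid, roi)
    supra = threshold_tmap(tmap, p_thresh, tail="positive")
    extent = int(np.sum(supra & inside))
    peak = float(np.max(tmap.t[inside]))
    if extent == 0:
        logger.info("peak t %.3f reported below the extent criterion", peak)
    return extent, peak


def roi_snr(
    ts: SubjectTimeseries, roi: np.ndarray, noise_region: np.ndarray
) -> float:
    """Temporal SNR: ROI grand-mean signal / sd of the noise-region-averaged series.

    The numerator is the mean of the timeseries across all ROI voxels and
    time points (identical to the temporal mean of the voxel-averaged
    series); the denominator is the standard deviation over time of the
    spatial average across the noise-reference region.
    """
    grid = ts.grid
    roi_in = _roi_indices(grid, roi)
    noise_in = _roi_indices(grid, noise_region)
    numerator = float(ts.data[roi_in].mean())
    noise_avg = ts.data[noise_in].mean(axis=0)
    denom = float(noise_avg.std(ddof=0))
    if denom == 0:
        raise ValueError("noise-region-averaged timeseries has zero variance")
    return numerator / denom


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_label(
    binary: np.ndarray, connectivity: int = 18
) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a boolean volume.

    Returns the labeled volume (0 = background) and an array of cluster
    sizes (sizes[i] is the voxel count of label i+1).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


def monte_carlo_cluster_threshold(
    grid: GridSpec,
    fwhm_mm: float,
    p_voxel: float = 0.001,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
    connectivity: int = 18,
) -> int:
    """Cluster-extent threshold from smoothed-Gaussian-noise simulations.

    Each iteration draws white Gaussian noise on the grid, smooths it to the
    stated FWHM, standardizes within the mask, thresholds at the one-tailed
    normal quantile for ``p_voxel`` and records the largest cluster. The
    returned extent k is the smallest cluster size whose empirical
    familywise probability P(max cluster >= k) is at most ``alpha``.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    if not (0 < p_voxel < 1 and 0 < alpha < 1):
        raise ValueError("p_voxel and alpha must lie in (0, 1)")
    if grid.n_voxels < 10:
        raise ValueError("mask too small for cluster simulation")
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.ppf(1.0 - p_voxel)
    sigma_vox = [
        fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)) * v)
        for v in grid.voxel_size_mm
    ] if fwhm_mm > 0 else None
    max_sizes = np.zeros(n_iter, dtype=int)
    for i in range(n_iter):
        vol = rng.standard_normal(grid.dims)
        if sigma_vox is not None:
            vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
        vals = vol[grid.mask]
        vals = (vals - vals.mean()) / vals.std(ddof=0)
        supra = np.zeros(grid.dims, dtype=bool)
        supra[grid.mask] = vals > z_crit
        _, sizes = cluster_label(supra, connectivity)
        max_sizes[i] = sizes.max() if sizes.size else 0
    biggest = int(max_sizes.max())
    for k in range(1, biggest + 2):
        if np.mean(max_sizes >= k) <= alpha:
            break
    if k > grid.n_voxels:
        warnings.warn(
            f"alpha={alpha} unreachable: every iteration fills the mask; "
            f"returned threshold {k} exceeds the mask size", stacklevel=2,
        )
    logger.info(
        "Monte-Carlo cluster threshold: k=%d voxels (fwhm=%.1f mm, "
        "p_voxel=%g, alpha=%g, %d iterations)", k, fwhm_mm, p_voxel, alpha,
        n_iter,
    )
    return int(k)


def rm_anova_two_way(values: np.ndarray,
                     factor_names: tuple[str, str] = ("roi", "dataset"),
                     ) -> pd.DataFrame:
    """Two-way fully within-subjects ANOVA from sums of squares.

    ``values`` has shape (subjects, levels of factor A, levels of factor B).
    Each effect is tested against its own effect-by-subject interaction, the
    standard univariate repeated-measures decomposition.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValueError("values must be subjects x A-levels x B-levels")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    m = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_a = n * b * np.sum((m_a - m) ** 2)
    ss_b = n * a * np.sum((m_b - m) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - m
    )
    ss_abs = np.sum(resid ** 2)

    # effects that are zero up to round-off must not yield spurious F ratios
    ss_scale = max(np.sum((y - m) ** 2), np.finfo(float).tiny)
    tol = ss_scale * 1e-12

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in [
        (factor_names[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (factor_names[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{factor_names[0]} x {factor_names[1]}", ss_ab,
         (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]:
        ms_eff = (ss_eff if ss_eff > tol else 0.0) / df_eff
        ms_err = (ss_err if ss_err > tol else 0.0) / df_err
        f = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        p = float(stats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
        rows.append({
            "effect": name, "ss": ss_eff, "df1": df_eff,
            "ss_error": ss_err, "df2": df_err, "F": f, "p": p,
        })
    return pd.DataFrame(rows)


@dataclass
class RoiReport:
    """Per-ROI comparison of the original and gCCA-processed arms.

    ``subject_table`` holds one row per subject x ROI x arm with extent,
    peak t and SNR; ``per_roi`` aggregates percent changes and paired
    t-tests per ROI; ``anova`` maps each metric to its ROI x dataset
    repeated-measures ANOVA table.
    """

    subject_table: pd.DataFrame
    per_roi: pd.DataFrame
    anova: dict[str, pd.DataFrame] = field(default_factory=dict)


def compare_arms(subject_table: pd.DataFrame) -> RoiReport:
    """Build the comparison report from a long-format subject table.

    Expects columns ``subject, roi, arm, extent, peak_t, snr`` with arms
    named ``original`` and ``gcca``. Percent change is
    100 (gcca - original) / original per subject and ROI; cells with a zero
    original value are reported missing.
    """
    required = {"subject", "roi", "arm", *METRICS}
    missing = required - set(subject_table.columns)
    if missing:
        raise ValueError(f"subject table lacks columns {sorted(missing)}")
    arms = set(subject_table["arm"])
    if arms != {"original", "gcca"}:
        raise ValueError(f"expected arms 'original' and 'gcca', got {arms}")

    wide = subject_table.pivot_table(
        index=["subject", "roi"], columns="arm", values=list(METRICS)
    )
    counts = wide.isna().any(axis=None)
    if counts:
        raise ValueError("subject x ROI x arm table is incomplete")

    rows = []
    for roi, sub in wide.groupby(level="roi"):
        row: dict[str, object] = {"roi": roi, "n_subjects": len(sub)}
        for metric in METRICS:
            orig = sub[(metric, "original")].to_numpy(float)
            gcca = sub[(metric, "gcca")].to_numpy(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = np.where(orig != 0, 100.0 * (gcca - orig) / orig, np.nan)
            row[f"mean_{metric}_original"] = orig.mean()
            row[f"mean_{metric}_gcca"] = gcca.mean()
            row[f"pct_change_{metric}_mean"] = float(np.nanmean(pct)) \
                if np.any(~np.isnan(pct)) else np.nan
            row[f"pct_change_{metric}_sd"] = float(np.nanstd(pct, ddof=1)) \
                if np.sum(~np.isnan(pct)) > 1 else np.nan
            diff = gcca - orig
            if np.allclose(diff, 0):
                t_val, p_val = 0.0, 1.0
            else:
                t_val, p_val = stats.ttest_rel(gcca, orig)
            row[f"paired_t_{metric}"] = float(t_val)
            row[f"paired_p_{metric}"] = float(p_val)
        rows.append(row)
    per_roi = pd.DataFrame(rows).sort_values("roi").reset_index(drop=True)

    rois = sorted(subject_table["roi"].unique())
    subjects = sorted(subject_table["subject"].unique())
    anova = {}
    for metric in METRICS:
        cube = np.empty((len(subjects), len(rois), 2))
        for ai, arm in enumerate(("original", "gcca")):
            for ri, roi in enumerate(rois):
                col = wide[(metric, arm)].unstack("roi")[roi]
                cube[:, ri, ai] = col.loc[subjects].to_numpy(float)
        anova[metric] = rm_anova_two_way(cube)
    return RoiReport(subject_table=subject_table, per_roi=per_roi, anova=anova)
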