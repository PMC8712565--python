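"""Synthetic multi-subject block-design fMRI cohorts with full ground truth.

The generative model writes each subject's masked timeseries as a linear
superposition of three groups of components:

1. a task-evoked component with a spatial map and HRF-convolved temporal
   response *common to all subjects up to a per-subject intensity* ``c_k``;
2. background ("resting-state") components with spatial maps common across
   subjects but *subject-specific* slow timecourses;
3. strong additive noise, independent across subjects, with AR(1) temporal
   autocorrelation.

Everything the simulator draws is retained in :class:`GroundTruth` so that
subspace-recovery and sensitivity experiments can score themselves against
the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import gamma

from .grids import GridSpec, SubjectTimeseries

__all__ = [
    "BlockDesign",
    "GroundTruth",
    "make_block_design",
    "canonical_hrf",
    "make_task_timecourse",
    "make_spatial_map",
    "simulate_cohort",
]

ACTIVE = "active"
STATIC = "static"


@dataclass(frozen=True)
class BlockDesign:
    """Alternating active/static block paradigm sampled at the scanner TR."""

    tr_s: float
    block_length_s: float
    n_active_blocks: int
    n_baseline_blocks: int
    drop_initial: int
    order: tuple[str, ...]

    @property
    def vols_per_block(self) -> int:
        return int(round(self.block_length_s / self.tr_s))

    @property
    def n_volumes(self) -> int:
        return self.vols_per_block * len(self.order)

    @property
    def n_analyzed(self) -> int:
        """Volumes remaining after the initial drop."""
        return self.n_volumes - self.drop_initial

    def boxcar(self, condition: str) -> np.ndarray:
        """0/1 indicator of ``condition`` over all ``n_volumes`` time points."""
        out = np.zeros(self.n_volumes)
        for i, label in enumerate(self.order):
            if label == condition:
                out[i * self.vols_per_block:(i + 1) * self.vols_per_block] = 1.0
        return out


def make_block_design(
    n_active: int,
    n_baseline: int,
    block_length_s: float,
    tr_s: float,
    drop_initial: int = 0,
    order_start: str = STATIC,
) -> BlockDesign:
    """Build an alternating block design.

    The default paradigm of the package (4 active + 4 static 35 s blocks at
    TR 3.5 s, first 5 volumes dropped) gives 80 volumes of which 75 are
    analyzed.
    """
    if n_active < 1 or n_baseline < 1:
        raise ValueError("need at least one active and one baseline block")
    if tr_s <= 0 or block_length_s <= 0:
        raise ValueError("tr_s and block_length_s must be positive")
    ratio = block_length_s / tr_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"block length {block_length_s} s is not an integer multiple of "
            f"TR {tr_s} s"
        )
    if order_start not in (ACTIVE, STATIC):
        raise ValueError(f"order_start must be '{ACTIVE}' or '{STATIC}'")

    order: list[str] = []
    counts = {ACTIVE: n_active, STATIC: n_baseline}
    current = order_start
    other = ACTIVE if order_start == STATIC else STATIC
    while counts[ACTIVE] or counts[STATIC]:
        if counts[current]:
            order.append(current)
            counts[current] -= 1
        elif counts[other]:
            order.append(other)
            counts[other] -= 1
        current, other = other, current

    design = BlockDesign(
        tr_s=float(tr_s),
        block_length_s=float(block_length_s),
        n_active_blocks=n_active,
        n_baseline_blocks=n_baseline,
        drop_initial=int(drop_initial),
        order=tuple(order),
    )
    if not 0 <= design.drop_initial < design.n_volumes:
        raise ValueError(
            f"drop_initial={drop_initial} must be in [0, {design.n_volumes})"
        )
    return design


def canonical_hrf(
    tr_s: float,
    duration_s: float = 32.0,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    peak_dispersion_s: float = 1.0,
    undershoot_dispersion_s: float = 1.0,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Difference of two gamma densities (response peaking near 5 s, undershoot
    near 15 s), normalized to unit peak. The kernel vanishes at t=0.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if duration_s < tr_s:
        raise ValueError("duration_s must be at least one TR")
    t = np.arange(0.0, duration_s + 1e-9, tr_s)
    peak = gamma.pdf(t, peak_delay_s / peak_dispersion_s, scale=peak_dispersion_s)
    under = gamma.pdf(
        t, undershoot_delay_s / undershoot_dispersion_s,
        scale=undershoot_dispersion_s,
    )
    h = peak - under / undershoot_ratio
    return h / np.max(np.abs(h))


def make_task_timecourse(
    design: BlockDesign, hrf: np.ndarray, apply_drop: bool = True
) -> np.ndarray:
    """HRF-convolved active-block boxcar; optionally drops initial volumes.

    With ``apply_drop=False`` the full ``n_volumes``-length response is
    returned (the form stored in :class:`GroundTruth`).
    """
    box = design.boxcar(ACTIVE)
    tc = np.convolve(box, np.asarray(hrf, dtype=float))[: design.n_volumes]
    if apply_drop:
        tc = tc[design.drop_initial:]
    return tc


def make_spatial_map(
    grid: GridSpec,
    centers: Sequence[tuple[int, int, int]],
    fwhm_mm: float,
    amplitudes: Sequence[float],
) -> np.ndarray:
    """Sum of isotropic Gaussian bumps, returned over masked voxels.

    ``fwhm_mm`` is converted per-axis to a voxel-space sigma through
    ``FWHM = 2 sqrt(2 ln 2) sigma``. Deterministic given its arguments.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if len(centers) != len(amplitudes):
        raise ValueError("centers and amplitudes must have equal length")
    sigma_vox = np.array(
        [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)) * v)
         for v in grid.voxel_size_mm]
    )
    axes = np.indices(grid.dims, dtype=float)
    vol = np.zeros(grid.dims)
    for center, amp in zip(centers, amplitudes):
        center = tuple(int(c) for c in center)
        if any(not 0 <= c < d for c, d in zip(center, grid.dims)):
            raise ValueError(f"center {center} outside grid {grid.dims}")
        if not grid.mask[center]:
            raise ValueError(f"center {center} lies outside the analysis mask")
        d2 = sum(
            ((axes[i] - center[i]) / sigma_vox[i]) ** 2 for i in range(3)
        )
        vol += amp * np.exp(-0.5 * d2)
    return grid.extract(vol)


@dataclass
class GroundTruth:
    """All planted components of one simulated cohort.

    ``task_timecourse`` and ``bg_timecourses`` cover the *full* volume count,
    before any initial-volume drop; ``baseline`` is a constant signal level
    added to every voxel (0 in the bare model; ~100 a.u. in realistic
    conditions, so the temporal-SNR statistic has a meaningful numerator).
    """

    task_map: np.ndarray
    task_timecourse: np.ndarray
    intensities: np.ndarray
    bg_maps: np.ndarray  # voxels x m
    noise_sigma: float
    noise_ar1: float = 0.3
    baseline: float = 0.0
    bg_timecourses: np.ndarray | None = None  # subjects x m x n_volumes
    bg_tc_smooth_s: float = 8.0

    def __post_init__(self) -> None:
        self.task_map = np.asarray(self.task_map, dtype=float)
        self.task_timecourse = np.asarray(self.task_timecourse, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.bg_maps = np.atleast_2d(np.asarray(self.bg_maps, dtype=float))
        if self.bg_maps.size == 0:
            self.bg_maps = self.bg_maps.reshape(self.task_map.size, 0)
        if not np.all(np.isfinite(self.task_map)):
            raise ValueError("task_map contains non-finite values")
        if np.any(self.intensities <= 0):
            raise ValueError("subject intensities must be strictly positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        m = self.bg_maps.shape[1]
        if m > 1 and np.linalg.matrix_rank(self.bg_maps) < m:
            raise ValueError("bg_maps columns must be linearly independent")

    @property
    def n_background(self) -> int:
        return self.bg_maps.shape[1]


def _ar1_noise(
    rng: np.random.Generator, n_voxels: int, n_volumes: int,
    sigma: float, rho: float,
) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal sd ``sigma``."""
    x = np.empty((n_voxels, n_volumes))
    x[:, 0] = sigma * rng.standard_normal(n_voxels)
    innov_sd = sigma * np.sqrt(1.0 - rho ** 2)
    for t in range(1, n_volumes):
        x[:, t] = rho * x[:, t - 1] + innov_sd * rng.standard_normal(n_voxels)
    return x


def _smooth_gp_timecourses(
    rng: np.random.Generator, m: int, n_volumes: int,
    tr_s: float, smooth_s: float,
) -> np.ndarray:
    """Unit-variance temporally smoothed Gaussian processes (m x T)."""
    raw = rng.standard_normal((m, n_volumes))
    if smooth_s > 0:
        raw = ndimage.gaussian_filter1d(raw, sigma=smooth_s / tr_s, axis=1)
    sd = raw.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (raw - raw.mean(axis=1, keepdims=True)) / sd


def simulate_cohort(
    grid: GridSpec,
    design: BlockDesign,
    truth: GroundTruth,
    n_subjects: int,
    seed: int,
) -> tuple[list[SubjectTimeseries], GroundTruth]:
    """Draw a cohort under the three-component superposition model.

    For subject k the full-length data are

    ``baseline + c_k * task_map task_tc' + bg_maps @ bg_tc_k + noise_k``

    after which the design's initial volumes are discarded. Background
    timecourses are drawn per subject as smoothed Gaussian processes unless
    already present in ``truth``; the returned :class:`GroundTruth` has them
    filled in. Bit-reproducible for a fixed seed.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    V = grid.n_voxels
    T = design.n_volumes
    if truth.task_map.size != V:
        raise ValueError(
            f"task_map has {truth.task_map.size} voxels, grid mask has {V}"
        )
    if truth.task_timecourse.size != T:
        raise ValueError(
            f"task_timecourse has {truth.task_timecourse.size} samples, "
            f"design has {T} volumes"
        )
    if truth.intensities.size != n_subjects:
        raise ValueError(
            f"{truth.intensities.size} intensities for {n_subjects} subjects"
        )
    m = truth.n_background
    if m and truth.bg_maps.shape[0] != V:
        raise ValueError(
            f"bg_maps have {truth.bg_maps.shape[0]} voxels, grid mask has {V}"
        )

    rng = np.random.default_rng(seed)
    if truth.bg_timecourses is not None:
        bg_tcs = np.asarray(truth.bg_timecourses, dtype=float)
        if bg_tcs.shape != (n_subjects, m, T):
            raise ValueError(
                f"bg_timecourses shape {bg_tcs.shape} != {(n_subjects, m, T)}"
            )
    else:
        bg_tcs = np.stack([
            _smooth_gp_timecourses(rng, m, T, design.tr_s, truth.bg_tc_smooth_s)
            for _ in range(n_subjects)
        ]) if m else np.zeros((n_subjects, 0, T))

    task_part = np.outer(truth.task_map, truth.task_timecourse)
    subjects: list[SubjectTimeseries] = []
    for k in range(n_subjects):
        data = truth.baseline + truth.intensities[k] * task_part
        if m:
            data = data + truth.bg_maps @ bg_tcs[k]
        if truth.noise_sigma > 0:
            data = data + _ar1_noise(rng, V, T, truth.noise_sigma,
                                     truth.noise_ar1)
        subjects.append(SubjectTimeseries(
            data=data[:, design.drop_initial:],
            grid=grid,
            tr_s=design.tr_s,
            subject_id=f"sub-{k:02d}",
        ))
    return subjects, replace(truth, bg_timecourses=bg_tcs)
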