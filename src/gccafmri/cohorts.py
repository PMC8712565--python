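"""Standard desk-scale study conditions used throughout the package.

One fixed cohort layout — an ellipsoidal "brain" mask on a 24 x 24 x 12 grid
of 3 mm voxels (~2800 masked voxels), 25 subjects, the 4+4 x 35 s block
paradigm at TR 3.5 s with 5 dropped volumes — mirroring the acquisition the
package models at reduced spatial dimension. Four task foci (analogues of
the EBA / SI / PMd / PMv regions of interest, the last one deliberately
weak), three background network maps, a signal-free noise-reference region
and a ventricle-like CSF region are planted at fixed locations.

Amplitudes are in arbitrary units relative to unit noise sigma: the three
strong foci have peak contrast-to-noise ratio 0.5, the weak focus 0.25, and
background networks unit amplitude; the baseline signal level is 100 a.u.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, SubjectTimeseries
from .synthetic import (
    BlockDesign,
    GroundTruth,
    canonical_hrf,
    make_block_design,
    make_spatial_map,
    make_task_timecourse,
    simulate_cohort,
)

__all__ = [
    "ROI_CENTERS",
    "StandardCohort",
    "standard_grid",
    "standard_design",
    "standard_masks",
    "standard_truth",
    "simulate_standard_cohort",
]

# Task focus centers (voxel coords) and peak amplitudes, noise-sigma units.
ROI_CENTERS: dict[str, tuple[int, int, int]] = {
    "EBA": (6, 18, 5),
    "SI": (17, 17, 7),
    "PMd": (7, 6, 7),
    "PMv": (17, 6, 4),  # weak-CNR focus
}
ROI_AMPLITUDES: dict[str, float] = {"EBA": 0.5, "SI": 0.5, "PMd": 0.5, "PMv": 0.25}
ROI_RADIUS_VOX = 2.5
TASK_FWHM_MM = 9.0

# Background network maps: two 9 mm bumps each, unit amplitude.
BG_CENTERS = [
    [(8, 13, 8), (15, 10, 8)],
    [(5, 11, 6), (18, 11, 6)],
    [(11, 5, 5), (11, 18, 5)],
]

NOISE_REGION = (slice(15, 18), slice(13, 16), slice(3, 6))
CSF_REGION = (slice(9, 15), slice(9, 15), slice(2, 6))
CSF_ARTIFACT_CENTER = (12, 11, 4)


def standard_grid() -> GridSpec:
    """24 x 24 x 12 grid of 3 mm voxels with an ellipsoidal mask."""
    dims = (24, 24, 12)
    x, y, z = np.indices(dims, dtype=float)
    mask = (
        ((x - 11.5) / 11.0) ** 2
        + ((y - 11.5) / 11.0) ** 2
        + ((z - 5.5) / 5.2) ** 2
    ) <= 1.0
    return GridSpec(dims=dims, voxel_size_mm=(3.0, 3.0, 3.0), mask=mask)


def standard_design() -> BlockDesign:
    """4 active + 4 static 35 s blocks, TR 3.5 s, 80 volumes, 5 dropped."""
    return make_block_design(
        n_active=4, n_baseline=4, block_length_s=35.0, tr_s=3.5, drop_initial=5
    )


def _sphere(grid: GridSpec, center: tuple[int, int, int],
            radius_vox: float) -> np.ndarray:
    x, y, z = np.indices(grid.dims, dtype=float)
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return (d2 <= radius_vox ** 2) & grid.mask


def standard_masks(grid: GridSpec | None = None) -> dict[str, np.ndarray]:
    """ROI spheres plus the noise-reference and CSF regions (boolean volumes)."""
    grid = grid or standard_grid()
    masks = {
        name: _sphere(grid, center, ROI_RADIUS_VOX)
        for name, center in ROI_CENTERS.items()
    }
    noise = np.zeros(grid.dims, dtype=bool)
    noise[NOISE_REGION] = True
    masks["noise_region"] = noise & grid.mask
    csf = np.zeros(grid.dims, dtype=bool)
    csf[CSF_REGION] = True
    masks["csf"] = csf & grid.mask
    for name in ROI_CENTERS:
        if (masks[name] & masks["noise_region"]).any():
            raise RuntimeError(f"noise region overlaps ROI {name}")
    return masks


def standard_truth(
    grid: GridSpec,
    design: BlockDesign,
    n_subjects: int = 25,
    seed: int = 0,
    noise_sigma: float = 1.0,
    noise_ar1: float = 0.3,
    baseline: float = 100.0,
    bg_amplitude: float = 1.0,
    with_csf_artifact: bool = False,
    csf_artifact_amplitude: float = 2.0,
) -> GroundTruth:
    """Planted ground truth for the standard cohort.

    Subject intensities are drawn Uniform(0.7, 1.3). With
    ``with_csf_artifact`` an extra *task-correlated* common component is
    planted inside the CSF region — the spurious ventricle signal the CSF
    overlap filter is designed to remove; it enters through the background
    slot with every subject's timecourse tied to the task response.
    """
    rng = np.random.default_rng(seed)
    hrf = canonical_hrf(design.tr_s)
    task_tc = make_task_timecourse(design, hrf, apply_drop=False)

    task_map = make_spatial_map(
        grid,
        centers=[ROI_CENTERS[n] for n in ROI_CENTERS],
        fwhm_mm=TASK_FWHM_MM,
        amplitudes=[ROI_AMPLITUDES[n] for n in ROI_CENTERS],
    )
    bg_maps = np.column_stack([
        make_spatial_map(grid, centers=pair, fwhm_mm=TASK_FWHM_MM,
                         amplitudes=[bg_amplitude] * len(pair))
        for pair in BG_CENTERS
    ])
    intensities = rng.uniform(0.7, 1.3, size=n_subjects)

    bg_timecourses = None
    if with_csf_artifact:
        artifact_map = make_spatial_map(
            grid, centers=[CSF_ARTIFACT_CENTER], fwhm_mm=TASK_FWHM_MM,
            amplitudes=[csf_artifact_amplitude],
        )
        bg_maps = np.column_stack([bg_maps, artifact_map])
        # Background timecourses are normally drawn inside simulate_cohort;
        # the artifact needs a task-locked one, so draw everything here.
        from .synthetic import _smooth_gp_timecourses

        m = bg_maps.shape[1]
        bg_timecourses = np.zeros((n_subjects, m, design.n_volumes))
        art_gain = rng.uniform(0.7, 1.3, size=n_subjects)
        task_unit = task_tc / task_tc.std(ddof=0)
        for k in range(n_subjects):
            bg_timecourses[k, : m - 1] = _smooth_gp_timecourses(
                rng, m - 1, design.n_volumes, design.tr_s, 8.0
            )
            # task-locked pulsation plus an ongoing subject-specific part;
            # the ongoing part is orthogonalized against the task response so
            # the artifact separates into its own spatial component
            ongoing = _smooth_gp_timecourses(
                rng, 1, design.n_volumes, design.tr_s, 8.0
            )[0]
            ongoing = ongoing - (
                ongoing @ task_unit / (task_unit @ task_unit)
            ) * task_unit
            sd = ongoing.std(ddof=0)
            if sd > 0:
                ongoing = ongoing / sd
            bg_timecourses[k, m - 1] = art_gain[k] * (
                0.4 * task_unit + np.sqrt(1.0 - 0.4 ** 2) * ongoing
            )

    return GroundTruth(
        task_map=task_map,
        task_timecourse=task_tc,
        intensities=intensities,
        bg_maps=bg_maps,
        noise_sigma=noise_sigma,
        noise_ar1=noise_ar1,
        baseline=baseline,
        bg_timecourses=bg_timecourses,
    )


@dataclass
class StandardCohort:
    """Bundle returned by :func:`simulate_standard_cohort`."""

    grid: GridSpec
    design: BlockDesign
    truth: GroundTruth
    masks: dict[str, np.ndarray]
    subjects: list[SubjectTimeseries] = field(default_factory=list)

    @property
    def roi_names(self) -> list[str]:
        return list(ROI_CENTERS)


def simulate_standard_cohort(
    seed: int,
    n_subjects: int = 25,
    with_csf_artifact: bool = False,
    **truth_kwargs,
) -> StandardCohort:
    """Simulate one cohort under the standard study conditions."""
    grid = standard_grid()
    design = standard_design()
    truth = standard_truth(
        grid, design, n_subjects=n_subjects, seed=seed,
        with_csf_artifact=with_csf_artifact, **truth_kwargs,
    )
    subjects, truth = simulate_cohort(
        grid, design, truth, n_subjects=n_subjects, seed=seed + 1
    )
    return StandardCohort(
        grid=grid, design=design, truth=truth,
        masks=standard_masks(grid), subjects=subjects,
    )
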