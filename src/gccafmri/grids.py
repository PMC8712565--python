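"""Voxel-grid containers shared by every stage of the pipeline.

Data live as ``voxels x time`` matrices restricted to an analysis mask;
:class:`GridSpec` carries the geometry needed to embed those vectors back
into 3-D volumes (for smoothing, clustering and NIfTI export).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "SubjectTimeseries"]


@dataclass(frozen=True)
class GridSpec:
    """A regular 3-D voxel grid with an analysis mask.

    Parameters
    ----------
    dims:
        Number of voxels along each axis, e.g. ``(24, 24, 12)``.
    voxel_size_mm:
        Physical voxel edge lengths in millimetres.
    mask:
        Boolean volume of shape ``dims``; ``True`` marks analyzed voxels.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size_mm", vs)
        if any(d < 1 for d in dims):
            raise ValueError(f"all grid dims must be >= 1, got {dims}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive, got {vs}")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != dims:
            raise ValueError(
                f"mask shape {mask.shape} does not match grid dims {dims}"
            )
        if not mask.any():
            raise ValueError("grid mask is empty")
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        """Number of masked (analyzed) voxels."""
        return int(self.mask.sum())

    @property
    def affine(self) -> np.ndarray:
        """Simple scaling affine (voxel indices -> mm), no rotation."""
        aff = np.diag((*self.voxel_size_mm, 1.0))
        return aff

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked-voxel vector (or ``V x T`` matrix) into volume(s).

        A vector returns a 3-D volume; a matrix returns a 4-D array with
        time as the last axis.
        """
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise ValueError(
                f"expected leading dimension {self.n_voxels} (masked voxels), "
                f"got {values.shape[0]}"
            )
        out_shape = self.dims + values.shape[1:]
        vol = np.full(out_shape, fill, dtype=values.dtype if
                      np.issubdtype(values.dtype, np.floating) else float)
        vol[self.mask] = values
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Gather masked voxels from a 3-D volume (or 4-D stack) into a vector/matrix."""
        volume = np.asarray(volume)
        if volume.shape[: 3] != self.dims:
            raise ValueError(
                f"volume shape {volume.shape[:3]} does not match grid dims {self.dims}"
            )
        return volume[self.mask]


@dataclass
class SubjectTimeseries:
    """One subject's masked ``voxels x time`` data matrix.

    Rows follow the ``True`` entries of ``grid.mask`` in C order; columns are
    the analyzed volumes (after any initial-volume drop).
    """

    data: np.ndarray
    grid: GridSpec
    tr_s: float
    subject_id: str = "sub-00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D voxels x time matrix")
        if self.data.shape[0] != self.grid.n_voxels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but the grid mask has "
                f"{self.grid.n_voxels} voxels"
            )
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in data for {self.subject_id}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "SubjectTimeseries":
        """Same subject/grid metadata with a new data matrix."""
        return SubjectTimeseries(
            data=data, grid=self.grid, tr_s=self.tr_s, subject_id=self.subject_id
        )
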