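"""NIfTI import/export for timeseries, masks and component maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import GridSpec, SubjectTimeseries

__all__ = [
    "write_mask",
    "read_grid",
    "write_subject",
    "read_subject",
    "write_volume",
    "read_volume",
]


def write_mask(grid: GridSpec, path: str | Path) -> None:
    """Write the analysis mask as a uint8 NIfTI."""
    img = nib.Nifti1Image(grid.mask.astype(np.uint8), grid.affine)
    nib.save(img, str(path))


def read_grid(path: str | Path) -> GridSpec:
    """Rebuild a GridSpec from a mask NIfTI (scaling affine assumed)."""
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    zooms = img.header.get_zooms()[:3]
    return GridSpec(dims=mask.shape, voxel_size_mm=tuple(float(z) for z in zooms),
                    mask=mask)


def write_subject(ts: SubjectTimeseries, path: str | Path) -> None:
    """Write a subject's masked timeseries as a 4-D float32 NIfTI."""
    vols = ts.grid.embed(ts.data.astype(np.float32))
    img = nib.Nifti1Image(vols, ts.grid.affine)
    img.header.set_zooms((*ts.grid.voxel_size_mm, ts.tr_s))
    nib.save(img, str(path))


def read_subject(
    path: str | Path, grid: GridSpec, tr_s: float | None = None,
    subject_id: str | None = None,
) -> SubjectTimeseries:
    """Read a 4-D NIfTI back into a masked timeseries on ``grid``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D timeseries, got {data.ndim}-D")
    if data.shape[:3] != grid.dims:
        raise ValueError(
            f"{path}: volume shape {data.shape[:3]} does not match grid "
            f"{grid.dims}"
        )
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3])
    return SubjectTimeseries(
        data=grid.extract(data).astype(float),
        grid=grid,
        tr_s=tr_s,
        subject_id=subject_id or Path(path).stem.split(".")[0],
    )


def write_volume(values: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    """Embed a masked-voxel vector (or voxels x k matrix) and write it."""
    img = nib.Nifti1Image(grid.embed(np.asarray(values, dtype=np.float32)),
                          grid.affine)
    nib.save(img, str(path))


def read_volume(path: str | Path, grid: GridSpec) -> np.ndarray:
    """Read a 3-D (or 4-D component) NIfTI into masked-voxel form."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.shape[:3] != grid.dims:
        raise ValueError(
            f"{path}: volume shape {data.shape[:3]} does not match grid "
            f"{grid.dims}"
        )
    return grid.extract(data.astype(float))
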