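"""NIfTI input/output and ROI timecourse extraction.

Voxel linearization convention
------------------------------
Everywhere in this package a 3D mask is flattened to a 1D voxel list by
ascending linear index with the FIRST spatial axis varying fastest
(Fortran/column-major order, matching the on-disk NIfTI data layout). The
single source of truth is :func:`mask_linear_indices`; every extraction and
every map written back to a volume uses it, so row ``j`` of a timecourse
matrix and element ``j`` of a voxel map always refer to the same voxel.

Masks are expected to live on the functional grid already: no resampling is
performed and affines are passed through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "RoiMask",
    "RunTimecourse",
    "RegionTimecourses",
    "mask_linear_indices",
    "load_mask",
    "load_region_timecourses",
    "write_voxel_map",
]


@dataclass
class RoiMask:
    """Binary region-of-interest mask on a 3D voxel grid.

    Parameters
    ----------
    grid : ndarray of bool, shape (i, j, k)
        True where the voxel belongs to the region.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform, passed through from the source image.
    label : str
        Free-text name used in logs.
    """

    grid: np.ndarray
    affine: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError(f"mask grid must be 3D, got {self.grid.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.n_voxels < 1:
            raise ValueError(f"empty mask: no nonzero voxels ({self.label or 'unnamed'})")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class RunTimecourse:
    """Voxels x timepoints matrix for one fMRI run."""

    values: np.ndarray
    run_id: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("run timecourse must be 2D (voxels x time)")
        if self.T < 1:
            raise ValueError("run must have at least one timepoint")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass
class RegionTimecourses:
    """Multi-run timecourses for a single region, rows in mask order."""

    runs: list[RunTimecourse]
    mask: RoiMask | None = None

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("need at least one run")
        n = self.runs[0].n_voxels
        for r in self.runs:
            if r.n_voxels != n:
                raise ValueError("all runs must share the same voxel count")
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate run ids: {ids}")
        if sorted(ids) != ids:
            raise ValueError(f"run ids must be in ascending order: {ids}")

    @property
    def n_voxels(self) -> int:
        return self.runs[0].n_voxels

    @property
    def run_ids(self) -> list[int]:
        return [r.run_id for r in self.runs]


def mask_linear_indices(grid: np.ndarray) -> np.ndarray:
    """Flat (Fortran-order) indices of the True voxels, ascending.

    This is the package-wide voxel linearization: the first spatial axis
    varies fastest, matching NIfTI's on-disk layout.
    """
    return np.flatnonzero(np.asarray(grid, dtype=bool).ravel(order="F"))


def load_mask(path: str | Path, label: str | None = None) -> RoiMask:
    """Load a 3D binary mask volume; any nonzero value counts as in-mask.

    Raises on a missing file, a 4D input, or a mask with zero voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"mask must be a 3D volume, got {data.ndim}D: {path}")
    grid = np.nan_to_num(data, nan=0.0) != 0
    if not grid.any():
        raise ValueError(f"empty mask (no nonzero voxels): {path}")
    return RoiMask(grid=grid, affine=img.affine, label=label or path.name)


def load_region_timecourses(
    func_paths: Sequence[str | Path], mask: RoiMask
) -> RegionTimecourses:
    """Extract per-run voxel x time matrices from 4D functional images.

    Row ``j`` of each matrix is the timecourse of the ``j``-th mask voxel in
    the package linearization order; runs keep the input order and are
    numbered 0..m-1.
    """
    if len(func_paths) == 0:
        raise ValueError("need at least one functional image")
    idx = mask_linear_indices(mask.grid)
    runs: list[RunTimecourse] = []
    for run_id, p in enumerate(func_paths):
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"functional image not found: {p}")
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError(f"functional image must be 4D, got {data.ndim}D: {p}")
        if data.shape[:3] != mask.shape:
            raise ValueError(
                f"run {run_id} ({p}): spatial shape {data.shape[:3]} does not "
                f"match mask shape {mask.shape}"
            )
        T = data.shape[3]
        flat = data.reshape(-1, T, order="F")
        values = np.asarray(flat[idx], dtype=float)
        if not np.isfinite(values).all():
            raise ValueError(f"non-finite values inside the mask in run {run_id}: {p}")
        runs.append(RunTimecourse(values=values, run_id=run_id))
    return RegionTimecourses(runs=runs, mask=mask)


def write_voxel_map(
    values: np.ndarray, mask: RoiMask, path: str | Path, dtype=np.float32
) -> Path:
    """Write a per-voxel vector back into a 3D volume (background 0).

    Values are placed at the mask voxels in linearization order; the output
    keeps the mask's shape and affine and is stored as 32-bit float by
    default. Note an all-zero map is indistinguishable from background
    outside the header.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size != mask.n_voxels:
        raise ValueError(
            f"value count {values.size} does not match mask voxel count {mask.n_voxels}"
        )
    flat = np.zeros(int(np.prod(mask.shape)), dtype=dtype)
    flat[mask_linear_indices(mask.grid)] = values.astype(dtype)
    vol = flat.reshape(mask.shape, order="F")
    img = nib.Nifti1Image(vol, mask.affine)
    img.header.set_data_dtype(dtype)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path
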