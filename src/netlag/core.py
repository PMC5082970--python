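"""Core containers shared across the pipeline.

A :class:`VoxelGrid` describes the common voxel grid all subjects live on
(the pipeline assumes spatial registration has already happened), and a
:class:`BoldRun` is one subject's 4D BOLD time series on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "BoldRun"]

MIN_GRID_DIM = 8


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel grid with its voxel-to-mm affine.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis; each must be >= 8.
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm.
    affine : (4, 4) ndarray
        Voxel-index -> mm coordinate mapping (NIfTI convention).
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size_mm", vs)
        aff = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "affine", aff)
        if len(dims) != 3 or any(d < MIN_GRID_DIM for d in dims):
            raise ValueError(f"grid dims must be 3 integers >= {MIN_GRID_DIM}, got {dims}")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive, got {vs}")
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        scales = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
        if not np.allclose(scales, vs, rtol=1e-6):
            raise ValueError(
                f"voxel_size_mm {vs} inconsistent with affine scales {tuple(scales)}"
            )

    @classmethod
    def isotropic(cls, dims: tuple[int, int, int], voxel_mm: float = 3.0) -> "VoxelGrid":
        """Axis-aligned grid with isotropic voxels, origin at the grid centre."""
        dims = tuple(int(d) for d in dims)
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        aff[:3, 3] = -voxel_mm * (np.asarray(dims) - 1) / 2.0
        return cls(dims=dims, voxel_size_mm=(voxel_mm,) * 3, affine=aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to mm coordinates through the affine."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class BoldRun:
    """One subject's 4D BOLD run on a :class:`VoxelGrid`.

    ``data`` has shape ``grid.dims + (T,)`` (time last, NIfTI convention);
    ``mask`` is a 3D boolean array marking in-brain voxels.
    """

    data: np.ndarray
    tr_s: float
    grid: VoxelGrid
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.data.shape[:3] != self.grid.dims:
            raise ValueError(
                f"data spatial shape {self.data.shape[:3]} != grid dims {self.grid.dims}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("a BOLD run needs at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError(f"TR must be positive, got {self.tr_s}")
        if self.mask is None:
            self.mask = np.ones(self.grid.dims, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.dims:
                raise ValueError("mask shape must match grid dims")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[3])

    def masked_matrix(self) -> np.ndarray:
        """Return the (T, V_mask) voxels-in-mask time series matrix."""
        return self.data[self.mask].T

    def with_data(self, data: np.ndarray) -> "BoldRun":
        """Copy of this run carrying new data (same grid, TR, mask)."""
        return BoldRun(data=data, tr_s=self.tr_s, grid=self.grid, mask=self.mask.copy())
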