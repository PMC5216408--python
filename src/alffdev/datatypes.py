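"""Core in-memory containers shared across the pipeline.

A :class:`Volume4D` is a subject's voxel time-series grid together with its
geometry (voxel size, repetition time, grid-to-world affine).  A
:class:`MotionTrace` holds the six rigid-body realignment parameters, one row
per volume, in the units conventional for resting-state pipelines
(translations in mm, rotations in radians).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume4D", "MotionTrace"]


def _default_affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    """RAS+ affine with the origin at the grid corner."""
    aff = np.diag(list(voxel_size_mm) + [1.0]).astype(float)
    return aff


@dataclass
class Volume4D:
    """A 4D (x, y, z, t) voxel time-series grid.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz, nt)``.  A 3D array is promoted to a
        single-frame 4D array (documented promotion used when reading masks).
    voxel_size_mm
        Edge lengths of a voxel along x, y, z.
    tr_s
        Repetition time (sampling interval) in seconds.
    affine
        4x4 grid-to-world map; defaults to ``diag(voxel_size)`` with the
        origin at the grid corner.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D expects 3D or 4D data, got ndim={self.data.ndim}")
        if self.data.shape[-1] < 1:
            raise ValueError("Volume4D needs at least one timepoint")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    def with_data(self, data: np.ndarray) -> "Volume4D":
        """Copy of this volume's geometry wrapped around new data."""
        return Volume4D(data, self.voxel_size_mm, self.tr_s, self.affine.copy())


@dataclass
class MotionTrace:
    """Rigid-body motion parameters, one row per volume.

    Columns 0-2 are translations (mm), columns 3-5 rotations (radians).
    """

    params: np.ndarray
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError(f"motion trace needs 6 columns, got {self.params.shape[1]}")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]
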