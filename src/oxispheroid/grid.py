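"""Uniform cell-centered Cartesian grids (2D and 3D), coordinates in μm."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Uniform grid of cubic cells.

    ``origin`` is the minimum corner of the grid (not a cell center); cell
    centers sit at ``origin + (index + 0.5) * spacing`` along each axis.
    """

    origin: tuple[float, ...]
    spacing: float
    dims: tuple[int, ...]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if len(self.origin) != len(self.dims):
            raise ValueError("origin and dims must have the same length")
        if len(self.dims) not in (2, 3):
            raise ValueError("only 2D and 3D grids are supported")
        if any(int(n) < 2 for n in self.dims):
            raise ValueError("need at least 2 cells per axis")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "dims", tuple(int(n) for n in self.dims))

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(min corner, max corner) of the gridded region."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + self.spacing * np.asarray(self.dims, dtype=float)
        return lo, hi

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.dims[axis]) + 0.5) * self.spacing

    def cell_centers(self) -> np.ndarray:
        """All cell centers, shape ``dims + (ndim,)``."""
        axes = [self.axis_centers(k) for k in range(self.ndim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    @property
    def cell_volume(self) -> float:
        return float(self.spacing ** self.ndim)

    @classmethod
    def covering(cls, bounding_box, spacing: float, pad_cells: int = 2) -> "GridSpec":
        """Grid of the given spacing covering an axis-aligned box, with
        ``pad_cells`` whole cells of margin on every side."""
        lo = np.asarray(bounding_box[0], dtype=float)
        hi = np.asarray(bounding_box[1], dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounding box must be a (2, ndim) array")
        n = np.ceil((hi - lo) / spacing).astype(int) + 2 * pad_cells
        center = (lo + hi) / 2.0
        origin = center - n * spacing / 2.0
        return cls(origin=tuple(origin), spacing=float(spacing), dims=tuple(n))

    @classmethod
    def for_model(cls, model, spacing: float, pad_cells: int = 2) -> "GridSpec":
        """3D grid covering a model's bounding box."""
        return cls.covering(model.bounding_box, spacing, pad_cells=pad_cells)

    def plane_xy(self) -> "GridSpec":
        """The 2D (x, y) footprint of this 3D grid."""
        if self.ndim != 3:
            raise ValueError("plane_xy() requires a 3D grid")
        return GridSpec(origin=self.origin[:2], spacing=self.spacing, dims=self.dims[:2])
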