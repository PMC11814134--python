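"""Contour slicing and triangle-surface extraction from implicit models.

Planar slices use marching squares with connected-component labelling of the
interior; full surfaces use marching cubes.  In both cases the crossing
vertices produced by linear interpolation are refined by bisection of the
defining function along their grid edge, so vertex accuracy is controlled by
``root_tol`` rather than by the grid alone.  Surfaces round-trip through STL
(ascii or binary); STL coordinates are micrometres by package convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure

from .geometry import ImplicitModel, evaluate_grid
from .grid import GridSpec

__all__ = [
    "SliceContour",
    "TriangleSurface",
    "EmptyGeometryError",
    "slice_model",
    "extract_surface",
    "write_stl",
    "read_stl",
    "surface_edge_counts",
    "is_watertight",
]


class EmptyGeometryError(ValueError):
    """The implicit model has no interior on the given grid."""


@dataclass
class SliceContour:
    """Closed contour loops of ``f(·,·,z) = 0`` in one z-plane (μm)."""

    z: float
    polylines: list[np.ndarray] = field(default_factory=list)  # each (M, 2), closed
    component_labels: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(set(self.component_labels))

    def total_length(self) -> float:
        total = 0.0
        for loop in self.polylines:
            seg = np.diff(loop, axis=0)
            total += float(np.sum(np.linalg.norm(seg, axis=1)))
        return total

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for k, (loop, lab) in enumerate(zip(self.polylines, self.component_labels)):
            for i, (x, y) in enumerate(loop):
                rows.append((k, lab, i, x, y, self.z))
        return pd.DataFrame(
            rows, columns=["loop_id", "component", "vertex_index", "x_um", "y_um", "z_um"]
        )


@dataclass
class TriangleSurface:
    """Indexed triangle mesh with outward-oriented faces, coordinates in μm."""

    vertices: np.ndarray  # (N, 3) float
    triangles: np.ndarray  # (M, 3) int

    @property
    def n_triangles(self) -> int:
        return int(len(self.triangles))

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    def area(self) -> float:
        return float(self.as_trimesh().area)

    def volume(self) -> float:
        return float(self.as_trimesh().volume)

    def euler_characteristic(self) -> int:
        edges = surface_edge_counts(self)
        return int(len(self.vertices) - len(edges) + len(self.triangles))


def surface_edge_counts(surface: TriangleSurface) -> dict[tuple[int, int], int]:
    """Occurrences of each undirected edge across all triangles."""
    tri = np.asarray(surface.triangles)
    edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return {tuple(int(v) for v in e): int(c) for e, c in zip(uniq, counts)}


def is_watertight(surface: TriangleSurface) -> bool:
    """True iff every undirected edge belongs to exactly two triangles."""
    if surface.n_triangles == 0:
        return False
    return all(c == 2 for c in surface_edge_counts(surface).values())


def _bisect_on_segments(model: ImplicitModel, a: np.ndarray, b: np.ndarray,
                        tol: float) -> np.ndarray:
    """Roots of f along segments a→b with f(a) and f(b) of opposite sign.

    Vectorized bisection; segments whose endpoints do not bracket a sign
    change fall back to their midpoint-interpolated input (a+b)/2.
    """
    a = a.copy()
    b = b.copy()
    fa = model(a)
    fb = model(b)
    ok = (fa * fb) <= 0
    # orient so that f(a) >= 0 on bracketed segments
    flip = ok & (fa < 0)
    a[flip], b[flip] = b[flip].copy(), a[flip].copy()
    span = np.linalg.norm(b - a, axis=1)
    n_iter = int(np.ceil(np.log2(max(span.max(initial=0.0), tol) / tol))) + 1 if len(a) else 0
    for _ in range(max(n_iter, 0)):
        mid = 0.5 * (a + b)
        fm = model(mid)
        pos = fm >= 0
        a[ok & pos] = mid[ok & pos]
        b[ok & ~pos] = mid[ok & ~pos]
    out = 0.5 * (a + b)
    return out


def slice_model(model: ImplicitModel, z: float, grid2d: GridSpec,
                root_tol: float | None = None) -> SliceContour:
    """Marching-squares contours of the model in the plane at height ``z``.

    Loops are labelled by the connected component of the interior region they
    bound.  Crossing vertices are refined along their grid edge by bisection
    to ``root_tol`` (default: spacing / 100).
    """
    if grid2d.ndim != 2:
        raise ValueError("slice_model requires a 2D grid")
    if root_tol is None:
        root_tol = grid2d.spacing / 100.0
    if root_tol <= 0:
        raise ValueError("root_tol must be positive")
    lo, hi = model.bounding_box[0], model.bounding_box[1]
    if not (lo[2] <= z <= hi[2]):
        warnings.warn(f"slice plane z={z} is outside the model bounding box")
        return SliceContour(z=z)

    xs = grid2d.axis_centers(0)
    ys = grid2d.axis_centers(1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, float(z))])
    values = model(pts).reshape(X.shape)
    if np.all(values <= 0):
        return SliceContour(z=z)
    # nudge exact surface hits off zero (degenerate marching-squares cases)
    eps = 1e-12 * max(float(np.abs(values).max()), h := grid2d.spacing)
    values = np.where(values == 0.0, eps, values)

    labels = measure.label(values > 0, connectivity=1)
    contours = measure.find_contours(values, 0.0)

    h = grid2d.spacing
    origin = np.asarray(grid2d.origin, dtype=float)

    def to_xy(idx_pts: np.ndarray) -> np.ndarray:
        return origin + (idx_pts + 0.5) * h

    polylines: list[np.ndarray] = []
    comp_labels: list[int] = []
    for cont in contours:
        xy = to_xy(cont)
        # refine each vertex along its (single) fractional axis
        frac = cont - np.floor(cont)
        on_edge = ~np.isclose(frac, 0.0)
        lo_idx = np.floor(cont).astype(int)
        hi_idx = np.ceil(cont).astype(int)
        a_idx = cont.copy()
        b_idx = cont.copy()
        for ax in (0, 1):
            sel = on_edge[:, ax]
            a_idx[sel, ax] = lo_idx[sel, ax]
            b_idx[sel, ax] = hi_idx[sel, ax]
        a3 = np.column_stack([to_xy(a_idx), np.full(len(cont), float(z))])
        b3 = np.column_stack([to_xy(b_idx), np.full(len(cont), float(z))])
        refined = _bisect_on_segments(model, a3, b3, root_tol)[:, :2]
        # vertices exactly on lattice nodes are already roots; keep them
        node = ~on_edge.any(axis=1)
        refined[node] = xy[node]
        if not np.allclose(refined[0], refined[-1]):
            refined = np.vstack([refined, refined[0]])
        polylines.append(refined)

        # component label: probe the 4 pixels around the first edge point
        i0, j0 = cont[0]
        label = 0
        for ii in {int(np.floor(i0)), int(np.ceil(i0))}:
            for jj in {int(np.floor(j0)), int(np.ceil(j0))}:
                if 0 <= ii < labels.shape[0] and 0 <= jj < labels.shape[1]:
                    if labels[ii, jj] > 0:
                        label = int(labels[ii, jj])
        comp_labels.append(label)

    return SliceContour(z=float(z), polylines=polylines, component_labels=comp_labels)


def extract_surface(model: ImplicitModel, grid: GridSpec,
                    root_tol: float | None = None) -> TriangleSurface:
    """Marching-cubes triangle surface of ``{f = 0}``, vertices refined by
    bisection along their grid edges to ``root_tol`` (default spacing/100).

    The sampled field must be negative on the entire grid border (at least
    one cell of exterior padding) so the extracted surface closes up; the
    result is watertight and consistently oriented with outward normals.
    """
    if grid.ndim != 3:
        raise ValueError("extract_surface requires a 3D grid")
    if root_tol is None:
        root_tol = grid.spacing / 100.0
    values = evaluate_grid(model, grid)
    if np.all(values <= 0):
        raise EmptyGeometryError("model has no interior on this grid")
    border = np.concatenate([
        values[[0, -1], :, :].ravel(),
        values[:, [0, -1], :].ravel(),
        values[:, :, [0, -1]].ravel(),
    ])
    if np.any(border > 0):
        raise ValueError("interior reaches the grid border; enlarge the grid padding")

    h = grid.spacing
    # lattice nodes that land exactly on the surface (f = 0) produce
    # degenerate marching-cubes cases; count them as interior by an
    # infinitesimal nudge, consistent with the f >= 0 solid convention
    eps = 1e-12 * max(float(np.abs(values).max()), h)
    values = np.where(values == 0.0, eps, values)
    verts, faces, _, _ = measure.marching_cubes(values, level=0.0, spacing=(1.0, 1.0, 1.0))

    origin = np.asarray(grid.origin, dtype=float) + 0.5 * h  # first lattice node

    frac = verts - np.floor(verts)
    on_edge = ~np.isclose(frac, 0.0, atol=1e-9)
    a_idx = verts.copy()
    b_idx = verts.copy()
    for ax in range(3):
        sel = on_edge[:, ax]
        a_idx[sel, ax] = np.floor(verts[sel, ax])
        b_idx[sel, ax] = np.ceil(verts[sel, ax])
    a3 = origin + a_idx * h
    b3 = origin + b_idx * h
    refined = _bisect_on_segments(model, a3, b3, root_tol)
    node = ~on_edge.any(axis=1)
    refined[node] = origin + verts[node] * h

    mesh = trimesh.Trimesh(vertices=refined, faces=faces, process=False)
    if mesh.volume < 0:  # enforce outward orientation
        faces = faces[:, ::-1]
    return TriangleSurface(vertices=refined, triangles=np.ascontiguousarray(faces))


def write_stl(surface: TriangleSurface, path, mode: str = "binary") -> None:
    """Write the surface as STL (coordinates are μm).  ``mode`` is
    ``"binary"`` (default) or ``"ascii"``."""
    if surface.n_triangles == 0:
        raise EmptyGeometryError("refusing to write an empty surface")
    if mode not in ("binary", "ascii"):
        raise ValueError("mode must be 'binary' or 'ascii'")
    mesh = surface.as_trimesh()
    file_type = "stl" if mode == "binary" else "stl_ascii"
    data = trimesh.exchange.stl.export_stl(mesh) if mode == "binary" else \
        trimesh.exchange.stl.export_stl_ascii(mesh)
    with open(path, "wb" if isinstance(data, bytes) else "w") as fh:
        fh.write(data)


def read_stl(path, merge_vertices: bool = True) -> TriangleSurface:
    """Read an ascii or binary STL file (autodetected).

    With ``merge_vertices`` bitwise-identical duplicate vertices are welded
    so watertightness is checkable on the indexed mesh (STL stores each
    triangle's corners separately, but corners shared between triangles are
    written from the same coordinates and so compare equal); without it the
    raw triangle soup is returned.  Coordinates are never rounded.
    """
    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - surface the parse location
        raise ValueError(f"failed to parse STL file {path!s}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"failed to parse STL file {path!s}: no triangles found")
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    if merge_vertices:
        corner = verts[faces.ravel()]
        uniq, inverse = np.unique(corner, axis=0, return_inverse=True)
        verts = uniq
        faces = inverse.reshape(-1, 3)
        # distinct surface points closer than the STL float32 resolution
        # collapse on welding; the zero-area triangles they leave behind are
        # edge collapses and must be dropped to keep the 2-per-edge property
        deg = (
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        )
        faces = faces[~deg]
    return TriangleSurface(vertices=verts, triangles=faces)
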