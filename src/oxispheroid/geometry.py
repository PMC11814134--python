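"""Implicit (function-representation) geometry of tissue spheroids.

A shape is a continuous scalar field ``f(x, y, z)`` that is positive inside
the object, zero on its surface and negative outside.  Smooth spheroids are
signed-distance spheres; surface irregularities are added with Gardner solid
noise; the fusion of two spheroids is modeled with an R-function union plus
a Gaussian-type blending displacement that adds material at the neck.

All coordinates and field values are in micrometres (μm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "GardnerNoiseParams",
    "BlendParams",
    "SpheroidSpec",
    "FusionSpec",
    "ImplicitModel",
    "sphere",
    "gardner_noise",
    "noisy_spheroid",
    "r_union",
    "displacement",
    "blend_union",
    "fused_spheroids",
    "evaluate_grid",
    "GARDNER_FACTOR_BOUND",
]

#: Bound on one Gardner factor: |a sin| + |a/1.17 sin| <= a (1 + 1/1.17).
GARDNER_FACTOR_BOUND = 1.0 + 1.0 / 1.17  # ≈ 1.8547


def _as_points(points) -> np.ndarray:
    """Coerce input to an (N, 3) float array; accepts a single (3,) point."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected points of shape (N, 3), got {pts.shape}")
    return pts


@dataclass(frozen=True)
class GardnerNoiseParams:
    """Amplitude ``a`` (per-factor; the product scales as ~a³), frequency
    ``q`` (rad/μm) and phase ``p`` (dimensionless) of Gardner solid noise."""

    a: float = 0.0
    q: float = 0.0
    p: float = 0.0

    def __post_init__(self):
        if self.a < 0 or self.q < 0:
            raise ValueError("Gardner noise requires a >= 0 and q >= 0")

    @property
    def max_displacement(self) -> float:
        """Upper bound on |GN| anywhere: (a·(1 + 1/1.17))³."""
        return (GARDNER_FACTOR_BOUND * self.a) ** 3


@dataclass(frozen=True)
class BlendParams:
    """Blending-union shape parameters: displacement magnitude ``a0`` (μm)
    and the scales ``a1``, ``a2`` (μm) controlling how far from each surface
    the added material extends."""

    a0: float = 0.0
    a1: float = 1.0
    a2: float = 1.0

    def __post_init__(self):
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("blend scales a1, a2 must be positive")
        if self.a0 < 0:
            raise ValueError("blend displacement a0 must be non-negative")

    @classmethod
    def for_radius(cls, radius: float, a0_fraction: float = 0.2) -> "BlendParams":
        """Default blend for spheroids of a given radius: a0 = 0.2·R, a1 = a2 = R."""
        return cls(a0=a0_fraction * radius, a1=radius, a2=radius)


@dataclass(frozen=True)
class SpheroidSpec:
    """A (possibly noisy) spheroid: center (μm), radius (μm), noise parameters."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 100.0
    noise: GardnerNoiseParams = field(default_factory=GardnerNoiseParams)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("spheroid radius must be positive")


@dataclass(frozen=True)
class FusionSpec:
    """Two spheroids joined by a blending union."""

    spheroid_1: SpheroidSpec
    spheroid_2: SpheroidSpec
    blend: BlendParams = field(default_factory=BlendParams)

    def __post_init__(self):
        if np.allclose(self.spheroid_1.center, self.spheroid_2.center) and \
                self.spheroid_1.radius != self.spheroid_2.radius:
            pass  # coincident centers with equal radii are allowed (degenerate fusion)

    @classmethod
    def symmetric(cls, radius: float, separation: float | None = None,
                  noise: GardnerNoiseParams | None = None,
                  blend: BlendParams | None = None) -> "FusionSpec":
        """Two equal spheroids on the x axis.  Default separation 1.5·R
        (a moderate fusion stage) and default blend a0 = 0.2·R, a1 = a2 = R."""
        if separation is None:
            separation = 1.5 * radius
        noise = noise or GardnerNoiseParams()
        blend = blend or BlendParams.for_radius(radius)
        half = separation / 2.0
        return cls(
            spheroid_1=SpheroidSpec(center=(-half, 0.0, 0.0), radius=radius, noise=noise),
            spheroid_2=SpheroidSpec(center=(+half, 0.0, 0.0), radius=radius, noise=noise),
            blend=blend,
        )


@dataclass(frozen=True)
class ImplicitModel:
    """A defining function plus an axis-aligned box guaranteed to contain
    the ``f >= 0`` set.  ``f`` is vectorized over an (N, 3) point array."""

    f: Callable[[np.ndarray], np.ndarray]
    bounding_box: np.ndarray  # (2, 3): [min corner, max corner], μm

    def __call__(self, points) -> np.ndarray:
        return np.asarray(self.f(_as_points(points)), dtype=float)


def sphere(center, radius: float) -> ImplicitModel:
    """Signed-distance sphere: f = radius − ‖x − center‖ (μm).

    f equals the radius at the center, zero on the surface and is negative
    outside, decreasing at unit rate with distance.
    """
    if radius <= 0:
        raise ValueError("sphere radius must be positive")
    c = np.asarray(center, dtype=float).reshape(3)

    def f(points: np.ndarray) -> np.ndarray:
        return radius - np.linalg.norm(points - c, axis=1)

    pad = 1e-6 * max(radius, 1.0)
    bbox = np.array([c - radius - pad, c + radius + pad])
    return ImplicitModel(f=f, bounding_box=bbox)


def gardner_noise(points, params: GardnerNoiseParams) -> np.ndarray:
    """Gardner solid noise: the product of three nested-sinusoid factors.

    Each factor is ``a·sin(q u) + (a/1.17)·sin(q u/1.35 + p·sin(q v))`` where
    (u, v) cycles through (x, z), (y, x), (z, y).  Deterministic, zero at the
    origin, and identically zero when a = 0 or q = 0.
    """
    pts = _as_points(points)
    a, q, p = params.a, params.q, params.p
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]

    def factor(u, v):
        return a * np.sin(q * u) + (a / 1.17) * np.sin(q * u / 1.35 + p * np.sin(q * v))

    return factor(x, z) * factor(y, x) * factor(z, y)


def noisy_spheroid(spec: SpheroidSpec) -> ImplicitModel:
    """Sphere with Gardner noise added to its defining function.

    The noise is evaluated in coordinates relative to the spheroid center, so
    a spheroid's surface texture travels with it.  With a = 0 the model is
    pointwise identical to the smooth sphere.  The bounding box is padded by
    the maximum possible noise magnitude so the ``f >= 0`` set stays inside.
    """
    base = sphere(spec.center, spec.radius)
    if spec.noise.a == 0.0:
        return base
    c = np.asarray(spec.center, dtype=float).reshape(3)
    noise = spec.noise

    def f(points: np.ndarray) -> np.ndarray:
        return base.f(points) + gardner_noise(points - c, noise)

    pad = noise.max_displacement
    bbox = np.array([base.bounding_box[0] - pad, base.bounding_box[1] + pad])
    return ImplicitModel(f=f, bounding_box=bbox)


def r_union(f1, f2):
    """Rvachev union: f1 + f2 + sqrt(f1² + f2²).

    Sign-equivalent to max(f1, f2): positive iff either argument is positive.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    return f1 + f2 + np.sqrt(f1 * f1 + f2 * f2)


def displacement(f1, f2, blend: BlendParams):
    """Gaussian-type blend displacement d = a0 / (1 + (f1/a1)² + (f2/a2)²).

    Peaks at a0 exactly where both surfaces meet (f1 = f2 = 0) and decays
    with distance from either surface.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    return blend.a0 / (1.0 + (f1 / blend.a1) ** 2 + (f2 / blend.a2) ** 2)


def blend_union(f1, f2, blend: BlendParams):
    """Blending union: R-union plus the displacement, adding material at the
    junction of the two shapes.  Reduces exactly to ``r_union`` at a0 = 0."""
    return r_union(f1, f2) + displacement(f1, f2, blend)


def fused_spheroids(spec: FusionSpec) -> ImplicitModel:
    """Blending union of two (possibly noisy) spheroids."""
    m1 = noisy_spheroid(spec.spheroid_1)
    m2 = noisy_spheroid(spec.spheroid_2)
    blend = spec.blend

    def f(points: np.ndarray) -> np.ndarray:
        return blend_union(m1.f(points), m2.f(points), blend)

    # The blend adds at most a0 of field value; with signed-distance-like
    # fields that moves the surface outward by at most ~a0.
    pad = blend.a0
    lo = np.minimum(m1.bounding_box[0], m2.bounding_box[0]) - pad
    hi = np.maximum(m1.bounding_box[1], m2.bounding_box[1]) + pad
    return ImplicitModel(f=f, bounding_box=np.array([lo, hi]))


def evaluate_grid(model: ImplicitModel, grid) -> np.ndarray:
    """Evaluate the defining function at every cell center of a 3D grid.

    The grid must cover the model's bounding box.  Returns an array of shape
    ``grid.dims``.
    """
    if grid.ndim != 3:
        raise ValueError("evaluate_grid requires a 3D grid")
    lo, hi = grid.extent
    blo, bhi = model.bounding_box
    tol = 1e-9 * float(grid.spacing)
    if np.any(lo > blo + tol) or np.any(hi < bhi - tol):
        raise ValueError(
            f"grid extent [{lo}, {hi}] does not cover model bounding box [{blo}, {bhi}]"
        )
    centers = grid.cell_centers()
    values = model(centers.reshape(-1, 3))
    return values.reshape(grid.dims)
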