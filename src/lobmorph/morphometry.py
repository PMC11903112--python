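"""The four nuclear size parameters: area, perimeter, min/max Feret diameter.

Area is the absolute shoelace sum, perimeter the closed ring's edge-length
sum. The Feret (caliper) diameters are computed exactly on the convex hull:
the maximum Feret diameter is the hull diameter (attained at a hull vertex
pair), and the minimum Feret diameter is the minimum caliper width, attained
perpendicular to some hull edge — so scanning hull edges and hull vertex
pairs is exact, with no angular discretization.

All functions take an (n, 2) vertex array in μm (closing edge implied) and
are invariant to translation, rotation and reflection; scaling coordinates
by k scales area by k² and the three length measures by k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .io import NucleusShape

__all__ = [
    "MorphometricRecord",
    "polygon_area",
    "polygon_perimeter",
    "convex_hull",
    "max_feret",
    "min_feret",
    "measure_nucleus",
    "measure_all",
]


@dataclass(frozen=True)
class MorphometricRecord:
    """The four size parameters for one nucleus, in μm/μm²."""

    nucleus_id: str
    case_id: str
    cell_class: str
    area: float
    perimeter: float
    min_feret: float
    max_feret: float

    def __post_init__(self) -> None:
        vals = (self.area, self.perimeter, self.min_feret, self.max_feret)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError("all four size parameters must be positive and finite")
        if self.min_feret > self.max_feret * (1 + 1e-12):
            raise ValueError("min_feret exceeds max_feret")
        if self.perimeter**2 < 4 * np.pi * self.area * (1 - 1e-9):
            raise ValueError("isoperimetric inequality violated")
        if self.area > self.min_feret * self.max_feret * (1 + 1e-12):
            raise ValueError("area exceeds min_feret * max_feret bound")

    def value(self, parameter: str) -> float:
        return {
            "area": self.area,
            "perimeter": self.perimeter,
            "min_feret": self.min_feret,
            "max_feret": self.max_feret,
        }[parameter]


def _as_ring(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("need an (n>=3, 2) vertex array")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite vertex coordinates")
    return v


def polygon_area(vertices) -> float:
    """Absolute shoelace area of a simple ring, μm²."""
    v = _as_ring(vertices)
    x, y = v[:, 0], v[:, 1]
    a = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if a == 0:
        raise ValueError("zero-area polygon")
    return float(a)


def polygon_perimeter(vertices) -> float:
    """Sum of Euclidean edge lengths including the closing edge, μm."""
    v = _as_ring(vertices)
    d = np.roll(v, -1, axis=0) - v
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def convex_hull(vertices) -> np.ndarray:
    """Convex hull vertices in counter-clockwise order.

    Collinear points interior to hull edges are dropped. All-collinear
    input raises ``ValueError``.
    """
    v = _as_ring(np.asarray(vertices, dtype=float))
    try:
        hull = ConvexHull(v)
    except QhullError as exc:
        raise ValueError("degenerate point set: no 2-D convex hull") from exc
    return v[hull.vertices]  # Qhull reports 2-D hull vertices in CCW order


def max_feret(vertices) -> float:
    """Maximum Feret diameter: largest pairwise distance, μm.

    Equals the diameter of the convex hull, so only hull vertex pairs are
    scanned.
    """
    h = convex_hull(vertices)
    if len(h) == 2:
        return float(np.hypot(*(h[1] - h[0])))
    return float(pdist(h).max())


def min_feret(vertices) -> float:
    """Minimum Feret diameter (minimum caliper width), μm.

    For each hull edge, the caliper width is the farthest hull-vertex
    distance to the edge's supporting line; the minimum over edges is the
    minimum width of the hull (and of the polygon).
    """
    h = convex_hull(vertices)
    edges = np.roll(h, -1, axis=0) - h
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    # unit normals to each edge
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / lengths[:, None]
    # widths[i] = max_j |(h[j] - h[i]) . n_i|
    rel = h[None, :, :] - h[:, None, :]
    widths = np.abs(np.einsum("ijk,ik->ij", rel, normals)).max(axis=1)
    return float(widths.min())


def measure_nucleus(shape: NucleusShape) -> MorphometricRecord:
    """Assemble the four size parameters for one nucleus boundary."""
    v = shape.vertices
    return MorphometricRecord(
        nucleus_id=shape.nucleus_id,
        case_id=shape.case_id,
        cell_class=shape.cell_class,
        area=polygon_area(v),
        perimeter=polygon_perimeter(v),
        min_feret=min_feret(v),
        max_feret=max_feret(v),
    )


def measure_all(shapes) -> list[MorphometricRecord]:
    """Measure a list of shapes, preserving order."""
    return [measure_nucleus(s) for s in shapes]
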