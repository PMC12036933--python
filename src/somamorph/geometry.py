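"""Shape descriptors for traced soma contours.

A traced soma is a closed planar polygon (vertex coordinates in µm).
From the polygon we compute two size measures (area, perimeter), the two
Feret diameters (caliper diameter and minimum width), and five
dimensionless descriptors used to characterise soma flatness and
boundary complexity:

====================  =========================================  =========
descriptor            formula                                    circle
====================  =========================================  =========
aspect ratio          feret_min / feret_max                      1
compactness           sqrt(4·A/π) / feret_max                    1
roundness             4·A / (π·feret_max²) = compactness²        1
shape factor          P / sqrt(A)                                2√π ≈ 3.54
form factor           4π·A / P²                                  1
====================  =========================================  =========

Aspect ratio, compactness and roundness fall below 1 as a soma
flattens; shape factor grows above 2√π with large-scale boundary
convolutions, and form factor falls below 1 with fine-scale boundary
roughness (by the isoperimetric inequality a circle attains both
bounds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import shapely
from scipy.spatial import ConvexHull

__all__ = [
    "Contour",
    "SomaMetrics",
    "InvalidContourError",
    "normalize_contour",
    "area",
    "perimeter",
    "feret_max",
    "feret_min",
    "descriptors",
    "regular_polygon",
]

#: coordinates closer than this (µm) are treated as the same vertex
_DUP_TOL = 1e-9


class InvalidContourError(ValueError):
    """Raised for contours that cannot represent a simple closed soma outline."""


@dataclass(frozen=True)
class Contour:
    """A simple closed polygon, stored open (closing edge implicit).

    Vertices are an ``(n, 2)`` float array in µm, ordered
    counter-clockwise (positive signed area).  Use
    :func:`normalize_contour` to build a validated instance from raw
    traced coordinates; code that constructs `Contour` directly (e.g.
    the synthetic generator) is responsible for the invariants.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidContourError(f"vertices must be (n, 2), got {v.shape}")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the vertex set, µm."""
        v = self.vertices
        return (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.vertices + np.array([dx, dy]))

    def to_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


@dataclass(frozen=True)
class SomaMetrics:
    """The nine per-cell measurements (µm, µm² and dimensionless)."""

    area: float
    perimeter: float
    feret_max: float
    feret_min: float
    aspect_ratio: float
    compactness: float
    roundness: float
    shape_factor: float
    form_factor: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: field order of SomaMetrics, for tabular output
METRIC_FIELDS: tuple[str, ...] = tuple(f.name for f in fields(SomaMetrics))


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def normalize_contour(raw_vertices) -> Contour:
    """Validate and canonicalise raw traced vertices.

    Drops a duplicated closing vertex and consecutive duplicates,
    requires at least 3 distinct vertices, rejects self-intersecting or
    zero-area input, and orients the result counter-clockwise.

    Raises
    ------
    InvalidContourError
        If fewer than 3 distinct vertices remain, or the polygon is
        self-intersecting or degenerate (zero area).
    """
    v = np.asarray(raw_vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or not np.all(np.isfinite(v)):
        raise InvalidContourError("vertices must be a finite (n, 2) coordinate array")
    if len(v) > 1 and np.linalg.norm(v[0] - v[-1]) <= _DUP_TOL:
        v = v[:-1]
    if len(v) > 1:
        step = np.linalg.norm(v - np.roll(v, 1, axis=0), axis=1)
        v = v[step > _DUP_TOL]
    if len(v) < 3:
        raise InvalidContourError("contour needs at least 3 distinct vertices")

    poly = shapely.Polygon(v)
    if not poly.is_valid:
        raise InvalidContourError("contour is self-intersecting or otherwise invalid")
    if poly.area <= 0.0:
        raise InvalidContourError("contour has zero area (degenerate/collinear)")

    if _signed_area(v) < 0:
        v = v[::-1]
    return Contour(v)


def area(c: Contour) -> float:
    """Polygon area (shoelace), µm²."""
    return abs(_signed_area(c.vertices))


def perimeter(c: Contour) -> float:
    """Polygon perimeter including the implicit closing edge, µm."""
    v = c.vertices
    return float(np.sum(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)))


def _hull_points(c: Contour) -> np.ndarray:
    """Convex hull vertices, counter-clockwise (Qhull drops interior and
    collinear points)."""
    v = c.vertices
    hull = ConvexHull(v)
    return v[hull.vertices]


def _calipers(p: np.ndarray) -> tuple[float, float]:
    """Rotating-calipers sweep over a convex CCW polygon.

    Returns ``(diameter, width)``: for each hull edge the antipodal
    pointer advances to the vertex farthest from the edge line; the
    diameter is the largest distance among the antipodal vertex pairs
    visited, the width the smallest farthest-vertex edge distance.
    O(h) for h hull vertices.
    """
    h = len(p)
    if h == 1:
        return 0.0, 0.0
    if h == 2:
        d = float(np.linalg.norm(p[0] - p[1]))
        return d, 0.0

    # plain-float lists: the tight pointer loop is much faster than
    # numpy scalar arithmetic for the small arrays seen here
    xs = p[:, 0].tolist()
    ys = p[:, 1].tolist()

    diam2 = 0.0
    width = math.inf
    j = 1
    for i in range(h):
        ni = i + 1 if i + 1 < h else 0
        ex = xs[ni] - xs[i]
        ey = ys[ni] - ys[i]
        # advance j while the next vertex is farther from edge i's line
        while True:
            nj = j + 1 if j + 1 < h else 0
            if ex * (ys[nj] - ys[j]) - ey * (xs[nj] - xs[j]) > 0.0:
                j = nj
            else:
                break
        nj = j + 1 if j + 1 < h else 0
        for k in (j, nj):  # nj guards exact ties (parallel edges)
            for m in (i, ni):
                dx = xs[m] - xs[k]
                dy = ys[m] - ys[k]
                d2 = dx * dx + dy * dy
                if d2 > diam2:
                    diam2 = d2
        # perpendicular distance of the farthest vertex from edge i
        w = abs(ex * (ys[j] - ys[i]) - ey * (xs[j] - xs[i])) / math.hypot(ex, ey)
        if w < width:
            width = w
    return math.sqrt(diam2), width


def feret_max(c: Contour) -> float:
    """Maximum Feret (caliper) diameter: the largest distance between
    any two contour points, µm.

    Attained at convex-hull vertices; computed by rotating calipers
    over the hull (equals the brute-force all-pairs maximum).
    """
    return _calipers(_hull_points(c))[0]


def feret_min(c: Contour) -> float:
    """Minimum Feret diameter: the smallest distance between two
    parallel supporting lines enclosing the contour, µm.

    The width of a polygon equals the width of its convex hull and is
    attained with one supporting line flush against a hull edge;
    computed by rotating calipers over the hull.
    """
    return _calipers(_hull_points(c))[1]


def descriptors(c: Contour) -> SomaMetrics:
    """All nine soma measurements for one contour.

    Raises
    ------
    InvalidContourError
        If the contour area is not strictly positive.
    """
    a = area(c)
    if a <= 0.0:
        raise InvalidContourError("degenerate contour: zero area")
    p = perimeter(c)
    fmax, fmin = _calipers(_hull_points(c))  # one hull, one sweep
    return SomaMetrics(
        area=a,
        perimeter=p,
        feret_max=fmax,
        feret_min=fmin,
        aspect_ratio=fmin / fmax,
        compactness=np.sqrt(4.0 * a / np.pi) / fmax,
        roundness=4.0 * a / (np.pi * fmax**2),
        shape_factor=p / np.sqrt(a),
        form_factor=4.0 * np.pi * a / p**2,
    )


def regular_polygon(n: int, radius: float = 1.0, center=(0.0, 0.0)) -> Contour:
    """A regular ``n``-gon inscribed in a circle: the discrete circle limit."""
    if n < 3:
        raise InvalidContourError("need at least 3 vertices")
    theta = 2.0 * np.pi * np.arange(n) / n
    v = np.column_stack([np.cos(theta), np.sin(theta)]) * radius + np.asarray(center)
    return Contour(v)
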