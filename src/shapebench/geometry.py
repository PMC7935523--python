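"""Parametric construction of the stimulus shape families.

All shapes are built in a local frame centered on the shape's centroid, in
continuous canvas units with the raster convention: origin at the top-left,
x rightward, y downward, rotation positive clockwise in that frame.  A
:class:`ShapeSpec` couples the local geometry with a similarity transform
(translation, rotation, scale) that places it on the canvas; the transform
acts on vertices only, so every category-defining predicate — parallel
pairs, side equality, hole count, component count, containment — is
preserved by construction.

Circles are represented as dense regular polygons (``CIRCLE_VERTICES``
vertices), which keeps a single polygonal pipeline from construction
through rasterization; the area deficit of a 90-gon relative to the true
disk is below 0.1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
from shapely.geometry import LineString, Point as _ShPoint, Polygon as _ShPolygon

from .errors import ShapeGenerationError

__all__ = [
    "Point2",
    "Polygon",
    "Segment",
    "AnnularShape",
    "CompositeShape",
    "Transform",
    "ShapeSpec",
    "make_quadrilateral",
    "make_triangle",
    "make_regular",
    "make_annulus",
    "make_irregular",
    "disassemble",
    "place_dot",
    "apply_transform",
    "side_lengths",
    "interior_angles",
    "polygon_area",
    "polygon_centroid",
    "parallel_pairs",
    "RETRY_LIMIT",
    "CIRCLE_VERTICES",
    "TAU_ANG_DEG",
    "DEFAULT_STROKE_WIDTH",
]

RETRY_LIMIT = 1000
CIRCLE_VERTICES = 90
#: angular tolerance for parallelism / right-angle predicates, degrees
TAU_ANG_DEG = 0.5
DEFAULT_STROKE_WIDTH = 3.0
#: minimum clearance (canvas units) between annulus boundaries for the
#: stroke-safe containment check
MIN_CLEARANCE = 4.0

Style = Literal["filled", "outline"]


@dataclass(frozen=True)
class Point2:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("Point2 coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class Polygon:
    """Simple closed polygon; ``style`` selects filled vs. stroked rendering."""

    vertices: np.ndarray  # (N, 2) float, implicitly closed
    style: Style = "filled"
    stroke_width: float = DEFAULT_STROKE_WIDTH

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        sh = self.shapely
        if not sh.is_valid or sh.area <= 0:
            raise ValueError("polygon must be simple with positive area")

    @property
    def shapely(self) -> _ShPolygon:
        return _ShPolygon(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        c = self.shapely.centroid
        return np.array([c.x, c.y])


@dataclass
class Segment:
    """A stroked straight line segment (one side of a disassembled figure)."""

    p0: np.ndarray
    p1: np.ndarray
    stroke_width: float = DEFAULT_STROKE_WIDTH

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if np.allclose(self.p0, self.p1):
            raise ValueError("degenerate segment")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def shapely(self) -> LineString:
        return LineString([self.p0, self.p1])


@dataclass
class AnnularShape:
    """A filled outer boundary with a strictly contained hole."""

    outer: Polygon
    inner: Polygon

    def __post_init__(self) -> None:
        if not self.outer.shapely.contains(self.inner.shapely):
            raise ValueError("inner boundary must lie strictly inside outer")
        if self.clearance() <= 0:
            raise ValueError("annulus boundaries must not touch")

    def clearance(self) -> float:
        return float(
            self.outer.shapely.exterior.distance(self.inner.shapely.exterior)
        )


Part = Union[Polygon, Segment]


@dataclass
class CompositeShape:
    """Disjoint rendered elements: separated segments, or figure plus dot."""

    parts: list[Part]
    part_roles: list[str]  # "segment" | "figure" | "dot"

    def __post_init__(self) -> None:
        if len(self.parts) != len(self.part_roles):
            raise ValueError("parts and part_roles must align")
        if self.part_roles.count("dot") > 1:
            raise ValueError("at most one dot part")


Geometry = Union[Polygon, AnnularShape, CompositeShape]


@dataclass(frozen=True)
class Transform:
    translation: Point2
    rotation_deg: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class ShapeSpec:
    """One stimulus: a category name, local geometry, placement, and seed."""

    category: str
    geometry: Geometry
    transform: Transform
    seed: int


# ---------------------------------------------------------------------------
# vertex-level oracles (shoelace / dot products) used by constructors
# ---------------------------------------------------------------------------


def _edges(vertices: np.ndarray) -> np.ndarray:
    return np.roll(vertices, -1, axis=0) - vertices


def side_lengths(poly: Polygon | np.ndarray) -> np.ndarray:
    v = poly.vertices if isinstance(poly, Polygon) else np.asarray(poly, float)
    return np.linalg.norm(_edges(v), axis=1)


def interior_angles(poly: Polygon | np.ndarray) -> np.ndarray:
    """Interior angles in degrees, one per vertex, via dot products."""
    v = poly.vertices if isinstance(poly, Polygon) else np.asarray(poly, float)
    prev = v - np.roll(v, 1, axis=0)
    nxt = np.roll(v, -1, axis=0) - v
    a = -prev
    cosang = np.einsum("ij,ij->i", a, nxt) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(nxt, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area (positive for counter-clockwise in math axes)."""
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + np.roll(x, -1)) * cross) / (6 * a)
    cy = np.sum((y + np.roll(y, -1)) * cross) / (6 * a)
    return np.array([cx, cy])


def parallel_pairs(poly: Polygon | np.ndarray, tol_deg: float = TAU_ANG_DEG) -> int:
    """Count of opposite-side pairs that are parallel within ``tol_deg``.

    Defined for quadrilaterals: pairs (0,2) and (1,3).
    """
    v = poly.vertices if isinstance(poly, Polygon) else np.asarray(poly, float)
    if len(v) != 4:
        raise ValueError("parallel_pairs is defined for quadrilaterals")
    e = _edges(v)
    count = 0
    for i, j in ((0, 2), (1, 3)):
        a, b = e[i], e[j]
        cross = abs(a[0] * b[1] - a[1] * b[0])
        sin_ang = cross / (np.linalg.norm(a) * np.linalg.norm(b))
        if math.degrees(math.asin(min(1.0, sin_ang))) < tol_deg:
            count += 1
    return count


def _center(vertices: np.ndarray) -> np.ndarray:
    return vertices - polygon_centroid(vertices)


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------


def make_quadrilateral(
    family: str,
    rng: np.random.Generator,
    *,
    style: Style = "filled",
    stroke_width: float = DEFAULT_STROKE_WIDTH,
) -> Polygon:
    """Sample one quadrilateral of the given family, centered at the origin.

    Families and their defining invariants (exact by construction):

    - ``square``: four equal sides, four right angles;
    - ``rectangle``: four right angles, aspect ratio in [1.3, 2.5] so no
      rectangle is within tolerance of a square;
    - ``trapezoid``: exactly one pair of parallel opposite sides (the legs
      cannot be parallel because the parallel sides have distinct lengths);
    - ``parallelogram``: two pairs of parallel sides, interior angles in
      [50°, 80°] (and supplements), at least 10° away from right angles.
    """
    if family == "square":
        s = rng.uniform(100.0, 140.0)
        h = s / 2.0
        v = np.array([[-h, -h], [h, -h], [h, h], [-h, h]])
    elif family == "rectangle":
        s = rng.uniform(90.0, 120.0)
        aspect = rng.uniform(1.3, 2.5)
        w, h = s * math.sqrt(aspect) / 2.0, s / math.sqrt(aspect) / 2.0
        v = np.array([[-w, -h], [w, -h], [w, h], [-w, h]])
    elif family == "trapezoid":
        b = rng.uniform(110.0, 160.0)
        t = b * rng.uniform(0.45, 0.75)
        h = rng.uniform(80.0, 130.0)
        off = rng.uniform(-0.15, 0.15) * b
        v = np.array(
            [
                [-t / 2 + off, -h / 2],
                [t / 2 + off, -h / 2],
                [b / 2, h / 2],
                [-b / 2, h / 2],
            ]
        )
    elif family == "parallelogram":
        a = rng.uniform(100.0, 150.0)
        b = rng.uniform(60.0, 100.0)
        theta = math.radians(rng.uniform(50.0, 80.0))
        u = np.array([a, 0.0])
        w = np.array([b * math.cos(theta), -b * math.sin(theta)])
        p0 = -(u + w) / 2.0
        v = np.array([p0, p0 + u, p0 + u + w, p0 + w])
    else:
        raise ValueError(f"unknown quadrilateral family: {family!r}")
    return Polygon(_center(v), style=style, stroke_width=stroke_width)


def make_triangle(
    kind: str,
    style: Style,
    rng: np.random.Generator,
    *,
    stroke_width: float = DEFAULT_STROKE_WIDTH,
    min_angle_deg: float = 18.0,
) -> Polygon:
    """Sample a triangle: ``isosceles`` (two sides exactly equal) or
    ``irregular`` (all sides pairwise distinct by a margin).

    Irregular triangles are rejection-sampled from three points on a circle
    until the minimum interior angle is at least ``min_angle_deg`` and the
    smallest pairwise side-length difference exceeds 6% of the mean side.
    """
    if kind == "isosceles":
        leg = rng.uniform(90.0, 140.0)
        apex = math.radians(rng.uniform(35.0, 90.0))
        half_base = leg * math.sin(apex / 2.0)
        height = leg * math.cos(apex / 2.0)
        v = np.array([[0.0, -height], [half_base, 0.0], [-half_base, 0.0]])
        return Polygon(_center(v), style=style, stroke_width=stroke_width)
    if kind != "irregular":
        raise ValueError(f"unknown triangle kind: {kind!r}")
    radius = rng.uniform(70.0, 100.0)
    for _ in range(RETRY_LIMIT):
        ang = np.sort(rng.uniform(0.0, 2 * math.pi, size=3))
        v = radius * np.column_stack([np.cos(ang), np.sin(ang)])
        sides = side_lengths(v)
        margin = 0.06 * float(sides.mean())
        diffs = [abs(sides[i] - sides[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        if min(diffs) > margin and interior_angles(v).min() >= min_angle_deg:
            return Polygon(_center(v), style=style, stroke_width=stroke_width)
    raise ShapeGenerationError("could not sample an irregular triangle")


def _regular_vertices(kind: str, radius: float) -> np.ndarray:
    """Vertices of a circle (dense polygon), equilateral triangle, or square
    of the given circumradius, centered at the origin."""
    if kind == "circle":
        n = CIRCLE_VERTICES
        ang = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    elif kind == "triangle":
        ang = np.array([-math.pi / 2, math.pi / 6, 5 * math.pi / 6])
    elif kind == "square":
        ang = np.array([1, 3, 5, 7]) * math.pi / 4
    else:
        raise ValueError(f"unknown regular shape kind: {kind!r}")
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


def make_regular(
    kind: str,
    rng: np.random.Generator,
    *,
    style: Style = "filled",
    stroke_width: float = DEFAULT_STROKE_WIDTH,
    radius_range: tuple[float, float] = (60.0, 90.0),
) -> Polygon:
    """A solid disk, equilateral triangle, or square with sampled circumradius."""
    radius = rng.uniform(*radius_range)
    return Polygon(
        _regular_vertices(kind, radius), style=style, stroke_width=stroke_width
    )


def make_annulus(
    kind: str,
    hole_ratio: float,
    rng: np.random.Generator,
    *,
    min_clearance: float = MIN_CLEARANCE,
) -> AnnularShape:
    """An outer figure with a concentric hole scaled by ``hole_ratio``.

    The inner boundary is the outer boundary scaled about its centroid by
    ``hole_ratio``, so the hole ratio is exact by definition.  Outer size is
    re-sampled until the boundary clearance is stroke-safe; an infeasible
    ``hole_ratio`` (clearance below ``min_clearance`` for every sampled
    size) raises :class:`ShapeGenerationError`.
    """
    if not 0.0 < hole_ratio < 1.0:
        raise ValueError("hole_ratio must lie strictly inside (0, 1)")
    for _ in range(RETRY_LIMIT):
        outer = make_regular(kind, rng, radius_range=(65.0, 90.0))
        inner_v = outer.vertices * hole_ratio  # centroid is at the origin
        ann = AnnularShape(outer=outer, inner=Polygon(inner_v))
        if ann.clearance() >= min_clearance:
            return ann
    raise ShapeGenerationError(
        f"annulus with hole_ratio={hole_ratio} cannot satisfy the "
        f"minimum clearance of {min_clearance}"
    )


def _densify(vertices: np.ndarray, step: float = 4.0) -> np.ndarray:
    """Insert points along each edge so no segment exceeds ``step`` units."""
    out: list[np.ndarray] = []
    n = len(vertices)
    for i in range(n):
        a, b = vertices[i], vertices[(i + 1) % n]
        k = max(1, int(math.ceil(np.linalg.norm(b - a) / step)))
        t = np.arange(k, dtype=float)[:, None] / k
        out.append(a + t * (b - a))
    return np.vstack(out)


def _harmonic_factor(
    theta: np.ndarray,
    amplitude: float,
    n_harmonics: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radial modulation 1 + sum_k a_k cos(k θ + φ_k) over low harmonics.

    Harmonics start at k = 2: the k = 1 term mostly shifts the shape, which
    the translation transform already covers.  Coefficients are scaled so
    the total modulation is bounded by ``amplitude``.
    """
    ks = np.arange(2, 2 + n_harmonics)
    a = rng.uniform(0.4, 1.0, size=n_harmonics) * rng.choice([-1.0, 1.0], n_harmonics)
    a *= amplitude / np.sum(np.abs(a))
    phi = rng.uniform(0.0, 2 * math.pi, size=n_harmonics)
    f = 1.0 + np.sum(
        a[None, :] * np.cos(ks[None, :] * theta[:, None] + phi[None, :]), axis=1
    )
    return f, a, phi


def make_irregular(
    base: Polygon | AnnularShape,
    amplitude: float,
    n_harmonics: int,
    rng: np.random.Generator,
) -> Polygon | AnnularShape:
    """Perturb a shape's boundary radially by a random low-order harmonic sum.

    The boundary is densified and every point is moved along the ray from
    the centroid by a factor ``1 + Σ a_k cos(kθ + φ_k)``.  Because the
    modulated radius stays positive, the perturbed boundary is a radial
    graph about the centroid and therefore remains simple; for an annulus
    the same angular field is applied to both boundaries (the inner being a
    scaled copy of the outer), so the hole survives with its clearance
    scaled but positive.  Topology — component count and hole count — is
    unchanged.
    """
    if not 0.0 <= amplitude <= 0.3:
        raise ValueError("amplitude must lie in [0, 0.3]")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")

    def perturb(vertices: np.ndarray) -> np.ndarray:
        if amplitude == 0.0:
            return vertices.copy()
        c = polygon_centroid(vertices)
        dense = _densify(vertices)
        rel = dense - c
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        f, _, _ = _harmonic_factor(theta, amplitude, n_harmonics, local_rng)
        return c + rel * f[:, None]

    for _ in range(RETRY_LIMIT):
        local_rng = np.random.default_rng(rng.integers(0, 2**31))
        if isinstance(base, Polygon):
            v = perturb(base.vertices)
            cand = Polygon(v, style=base.style, stroke_width=base.stroke_width)
            if cand.shapely.is_valid:
                return cand
        else:
            c = polygon_centroid(base.outer.vertices)
            dense = _densify(base.outer.vertices)
            rel = dense - c
            theta = np.arctan2(rel[:, 1], rel[:, 0])
            f, _, _ = _harmonic_factor(theta, amplitude, n_harmonics, local_rng)
            outer_v = c + rel * f[:, None]
            ratio = _annulus_ratio(base)
            inner_v = c + rel * f[:, None] * ratio
            cand = AnnularShape(outer=Polygon(outer_v), inner=Polygon(inner_v))
            if cand.clearance() > 0:
                return cand
    raise ShapeGenerationError("irregular perturbation kept self-intersecting")


def _annulus_ratio(ann: AnnularShape) -> float:
    """Hole ratio recovered from boundary extents (exact for scaled copies)."""
    c = polygon_centroid(ann.outer.vertices)
    r_out = np.linalg.norm(ann.outer.vertices - c, axis=1).max()
    r_in = np.linalg.norm(ann.inner.vertices - c, axis=1).max()
    return float(r_in / r_out)


def disassemble(
    triangle_outline: Polygon,
    displacement: float | None,
    rng: np.random.Generator,
    *,
    gap: float | None = None,
    max_part_rotation_deg: float = 30.0,
) -> CompositeShape:
    """Break an outline triangle into its three sides, rigidly displaced.

    Each side is translated outward from the triangle centroid by
    ``displacement`` (default 0.25 × circumradius) and rotated about its own
    midpoint by a uniform angle in ±``max_part_rotation_deg``.  Placement is
    rejection-sampled until every pair of segments is separated by at least
    ``gap`` (default 2 × stroke width).  Rigid motions preserve length, so
    total ink equals the source perimeter.
    """
    if len(triangle_outline.vertices) != 3 or triangle_outline.style != "outline":
        raise ValueError("input must be an outline triangle")
    v = triangle_outline.vertices
    c = polygon_centroid(v)
    circumradius = float(np.linalg.norm(v - c, axis=1).max())
    if gap is None:
        gap = 2.0 * triangle_outline.stroke_width
    if displacement is None:
        # large gaps (e.g. demanded by a small placement scale) need the
        # parts pushed proportionally further out to stay satisfiable
        displacement = max(0.25 * circumradius, 1.2 * gap)

    sides = [(v[i], v[(i + 1) % 3]) for i in range(3)]
    for _ in range(RETRY_LIMIT):
        parts: list[Segment] = []
        for p0, p1 in sides:
            mid = (p0 + p1) / 2.0
            out_dir = mid - c
            nrm = np.linalg.norm(out_dir)
            out_dir = out_dir / nrm if nrm > 0 else np.array([1.0, 0.0])
            jitter = math.radians(rng.uniform(-20.0, 20.0))
            rot_j = np.array(
                [
                    [math.cos(jitter), -math.sin(jitter)],
                    [math.sin(jitter), math.cos(jitter)],
                ]
            )
            new_mid = mid + displacement * (rot_j @ out_dir)
            ang = math.radians(rng.uniform(-max_part_rotation_deg, max_part_rotation_deg))
            rot = np.array(
                [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
            )
            half = (p1 - p0) / 2.0
            half_r = rot @ half
            parts.append(
                Segment(
                    new_mid - half_r,
                    new_mid + half_r,
                    stroke_width=triangle_outline.stroke_width,
                )
            )
        dists = [
            parts[i].shapely.distance(parts[j].shapely)
            for i, j in ((0, 1), (0, 2), (1, 2))
        ]
        if min(dists) >= gap:
            return CompositeShape(parts=list(parts), part_roles=["segment"] * 3)
    raise ShapeGenerationError(
        "could not separate the triangle sides by the required gap"
    )


def place_dot(
    figure: Polygon,
    inside: bool,
    dot_radius: float,
    rng: np.random.Generator,
    *,
    margin: float | None = None,
    outside_reach: float = 0.6,
) -> CompositeShape:
    """Add a filled dot strictly inside or strictly outside a closed outline.

    The dot center is rejection-sampled; a placement is accepted when the
    point-in-polygon test matches ``inside`` and the dot boundary keeps at
    least ``margin`` (default 2 × stroke width) clear of the stroked
    outline.  Outside dots land within ``outside_reach`` × circumradius of
    the outline so that the composite still fits the canvas after the
    placement transform.
    """
    if figure.style != "outline":
        raise ValueError("dot figures require a closed outline polygon")
    sh = figure.shapely
    c = polygon_centroid(figure.vertices)
    circumradius = float(np.linalg.norm(figure.vertices - c, axis=1).max())
    if margin is None:
        margin = 2.0 * figure.stroke_width
    # clearance from dot boundary to the *stroked* outline
    clear = dot_radius + margin + figure.stroke_width / 2.0
    reach = circumradius * (1.0 + outside_reach)
    for _ in range(RETRY_LIMIT):
        center = c + rng.uniform(-reach, reach, size=2)
        p = _ShPoint(center)
        if sh.contains(p) != inside:
            continue
        if sh.exterior.distance(p) < clear:
            continue
        if not inside and np.linalg.norm(center - c) > reach:
            continue
        ang = np.linspace(0.0, 2 * math.pi, 24, endpoint=False)
        dot_v = center + dot_radius * np.column_stack([np.cos(ang), np.sin(ang)])
        return CompositeShape(
            parts=[figure, Polygon(dot_v, style="filled")],
            part_roles=["figure", "dot"],
        )
    raise ShapeGenerationError("no valid dot placement found")


# ---------------------------------------------------------------------------
# similarity transform
# ---------------------------------------------------------------------------


def _transform_points(pts: np.ndarray, t: Transform) -> np.ndarray:
    th = math.radians(t.rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return (t.scale * (pts @ rot.T)) + np.array([t.translation.x, t.translation.y])


def _transform_part(part: Part, t: Transform) -> Part:
    if isinstance(part, Polygon):
        return Polygon(
            _transform_points(part.vertices, t),
            style=part.style,
            stroke_width=part.stroke_width,
        )
    return Segment(
        _transform_points(part.p0[None, :], t)[0],
        _transform_points(part.p1[None, :], t)[0],
        stroke_width=part.stroke_width,
    )


def apply_transform(spec: ShapeSpec) -> Geometry:
    """Place the spec's local geometry on the canvas.

    Rotation and scaling act about the local origin (the shape centroid),
    then the translation moves the shape to its canvas position.  Stroke
    widths are rendering attributes and are left in canvas pixels — scaling
    them with the shape would let thin outlines drop below the raster
    resolution and change the rendered topology.
    """
    g = spec.geometry
    t = spec.transform
    if isinstance(g, Polygon):
        return _transform_part(g, t)
    if isinstance(g, AnnularShape):
        return AnnularShape(
            outer=_transform_part(g.outer, t), inner=_transform_part(g.inner, t)
        )
    return CompositeShape(
        parts=[_transform_part(p, t) for p in g.parts],
        part_roles=list(g.part_roles),
    )


def geometry_bounds(g: Geometry) -> tuple[float, float, float, float]:
    """(xmin, ymin, xmax, ymax) over all vertices, padded by stroke radii."""

    def part_bounds(part: Part) -> tuple[np.ndarray, float]:
        if isinstance(part, Polygon):
            pad = part.stroke_width / 2.0 if part.style == "outline" else 0.0
            return part.vertices, pad
        return np.vstack([part.p0, part.p1]), part.stroke_width / 2.0

    parts: list[Part]
    if isinstance(g, Polygon):
        parts = [g]
    elif isinstance(g, AnnularShape):
        parts = [g.outer]
    else:
        parts = list(g.parts)
    lo = np.array([np.inf, np.inf])
    hi = np.array([-np.inf, -np.inf])
    for part in parts:
        pts, pad = part_bounds(part)
        lo = np.minimum(lo, pts.min(axis=0) - pad)
        hi = np.maximum(hi, pts.max(axis=0) + pad)
    return float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1])
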