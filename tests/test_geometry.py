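"""Vector-level checks of the shape constructors.

Every geometric predicate asserted here is computed by independent oracles
(dot-product angles, cross-product parallelism, shoelace area) on the
emitted vertices — never by the constructor's own bookkeeping.
"""

import math

import numpy as np
import pytest

from shapebench import geometry as geo
from shapebench.errors import ShapeGenerationError

TAU = geo.TAU_ANG_DEG


# -- independent oracles ----------------------------------------------------


def oracle_angles_deg(v):
    """Interior angles via explicit dot products, one vertex at a time."""
    v = np.asarray(v, float)
    n = len(v)
    out = []
    for i in range(n):
        a = v[(i - 1) % n] - v[i]
        b = v[(i + 1) % n] - v[i]
        cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        out.append(math.degrees(math.acos(np.clip(cosang, -1, 1))))
    return np.array(out)


def oracle_parallel(p, q, r, s, tol_deg=TAU):
    """Whether segment pq is parallel to rs, by normalized cross product."""
    d1 = np.asarray(q) - np.asarray(p)
    d2 = np.asarray(s) - np.asarray(r)
    cross = abs(d1[0] * d2[1] - d1[1] * d2[0])
    sin_ang = cross / (np.linalg.norm(d1) * np.linalg.norm(d2))
    return math.degrees(math.asin(min(1.0, sin_ang))) < tol_deg


def oracle_shoelace(v):
    v = np.asarray(v, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def seg_dist(a0, a1, b0, b1):
    """Minimum distance between two segments by dense sampling."""
    t = np.linspace(0, 1, 200)[:, None]
    pa = a0 + t * (np.asarray(a1) - a0)
    pb = b0 + t * (np.asarray(b1) - b0)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return d.min()


# -- quadrilaterals ---------------------------------------------------------


@pytest.mark.parametrize("seed", range(25))
def test_square_sides_equal_and_right_angled(seed):
    poly = geo.make_quadrilateral("square", np.random.default_rng(seed))
    sides = geo.side_lengths(poly)
    assert np.ptp(sides) == pytest.approx(0.0, abs=1e-9)
    assert oracle_angles_deg(poly.vertices) == pytest.approx(90.0, abs=TAU)


@pytest.mark.parametrize("seed", range(25))
def test_rectangle_right_angles_and_nonsquare_aspect(seed):
    poly = geo.make_quadrilateral("rectangle", np.random.default_rng(seed))
    assert oracle_angles_deg(poly.vertices) == pytest.approx(90.0, abs=TAU)
    sides = geo.side_lengths(poly)
    aspect = max(sides) / min(sides)
    assert 1.3 - 1e-9 <= aspect <= 2.5 + 1e-9


@pytest.mark.parametrize("seed", range(25))
def test_trapezoid_has_exactly_one_parallel_pair(seed):
    v = geo.make_quadrilateral("trapezoid", np.random.default_rng(seed)).vertices
    pairs = [
        oracle_parallel(v[0], v[1], v[3], v[2]),
        oracle_parallel(v[1], v[2], v[0], v[3]),
    ]
    assert sum(pairs) == 1


@pytest.mark.parametrize("seed", [3, *range(10)])
def test_parallelogram_two_parallel_pairs_no_right_angle(seed):
    v = geo.make_quadrilateral("parallelogram", np.random.default_rng(seed)).vertices
    assert oracle_parallel(v[0], v[1], v[3], v[2])
    assert oracle_parallel(v[1], v[2], v[0], v[3])
    angles = oracle_angles_deg(v)
    assert np.all(np.abs(angles - 90.0) > TAU)


def test_unknown_quadrilateral_family_rejected(rng):
    with pytest.raises(ValueError, match="family"):
        geo.make_quadrilateral("rhombus", rng)


# -- triangles --------------------------------------------------------------


@pytest.mark.parametrize("kind,style", [("isosceles", "outline"), ("irregular", "filled")])
@pytest.mark.parametrize("seed", [1, 2, 17])
def test_triangle_construction(kind, style, seed):
    poly = geo.make_triangle(kind, style, np.random.default_rng(seed))
    sides = np.sort(geo.side_lengths(poly))
    angles = oracle_angles_deg(poly.vertices)
    assert angles.sum() == pytest.approx(180.0, abs=1e-6)
    assert angles.min() >= 15.0
    if kind == "isosceles":
        assert min(sides[1] - sides[0], sides[2] - sides[1]) == pytest.approx(0, abs=1e-9)
    else:
        margin = 0.06 * sides.mean()
        assert np.diff(sides).min() > margin


# -- annuli -----------------------------------------------------------------


@pytest.mark.parametrize("kind,ratio", [("circle", 0.5), ("square", 0.4), ("triangle", 0.35)])
def test_annulus_inner_is_scaled_copy(kind, ratio):
    ann = geo.make_annulus(kind, ratio, np.random.default_rng(0))
    c_out = geo.polygon_centroid(ann.outer.vertices)
    c_in = geo.polygon_centroid(ann.inner.vertices)
    assert c_in == pytest.approx(c_out, abs=1e-8)
    r_out = np.linalg.norm(ann.outer.vertices - c_out, axis=1)
    r_in = np.linalg.norm(ann.inner.vertices - c_in, axis=1)
    assert r_in / r_out == pytest.approx(ratio, abs=1e-9)
    assert oracle_shoelace(ann.inner.vertices) == pytest.approx(
        ratio**2 * oracle_shoelace(ann.outer.vertices), rel=1e-9
    )


def test_annulus_rejects_bad_hole_ratio(rng):
    for ratio in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(ValueError, match="hole_ratio"):
            geo.make_annulus("circle", ratio, rng)


def test_annulus_near_unit_ratio_fails_clearance(rng):
    # clearance can never reach the stroke-safe minimum at ratio 0.99
    with pytest.raises(ShapeGenerationError, match="clearance"):
        geo.make_annulus("triangle", 0.99, rng)


def test_annulus_clearance_matches_point_to_segment_oracle(rng):
    ann = geo.make_annulus("square", 0.4, rng)
    # oracle: min over inner vertices of distance to each outer edge
    outer, inner = ann.outer.vertices, ann.inner.vertices
    best = np.inf
    for p in inner:
        for i in range(len(outer)):
            a, b = outer[i], outer[(i + 1) % len(outer)]
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            best = min(best, np.linalg.norm(p - (a + t * ab)))
    assert ann.clearance() == pytest.approx(best, rel=1e-6)


# -- irregular perturbation -------------------------------------------------


def test_irregular_amplitude_zero_is_identity(rng):
    base = geo.make_regular("circle", rng)
    out = geo.make_irregular(base, 0.0, 5, rng)
    assert np.array_equal(out.vertices, base.vertices)


@pytest.mark.parametrize("seed", range(5))
def test_irregular_bounds_radial_excursion(seed):
    rng = np.random.default_rng(seed)
    base = geo.make_regular("circle", rng)
    r0 = np.linalg.norm(base.vertices, axis=1).mean()
    out = geo.make_irregular(base, 0.15, 5, rng)
    c = geo.polygon_centroid(out.vertices)
    r = np.linalg.norm(out.vertices - c, axis=1)
    assert r.max() <= r0 * 1.20 and r.min() >= r0 * 0.80
    assert out.shapely.is_valid


def test_irregular_rejects_bad_params(rng):
    base = geo.make_regular("circle", rng)
    with pytest.raises(ValueError):
        geo.make_irregular(base, 0.5, 5, rng)
    with pytest.raises(ValueError):
        geo.make_irregular(base, 0.1, 0, rng)


# -- disassembly ------------------------------------------------------------


def test_disassemble_conserves_total_ink_length(rng):
    tri = geo.make_triangle("isosceles", "outline", rng)
    comp = geo.disassemble(tri, None, rng)
    total = sum(p.length for p in comp.parts)
    assert total == pytest.approx(geo.side_lengths(tri).sum(), rel=1e-9)


def test_disassemble_respects_gap_by_sampled_distance_oracle(rng):
    tri = geo.make_triangle("irregular", "outline", rng)
    comp = geo.disassemble(tri, None, rng, gap=10.0)
    segs = comp.parts
    for i in range(3):
        for j in range(i + 1, 3):
            d = seg_dist(segs[i].p0, segs[i].p1, segs[j].p0, segs[j].p1)
            assert d >= 10.0 - 0.05  # dense-sampling resolution slack


def test_disassemble_zero_displacement_fails_gap_check(rng):
    # undisplaced, unrotated sides still touch at the vertices
    tri = geo.make_triangle("isosceles", "outline", rng)
    with pytest.raises(ShapeGenerationError):
        geo.disassemble(tri, 0.0, rng, max_part_rotation_deg=0.0)


def test_disassemble_requires_outline_triangle(rng):
    solid = geo.make_triangle("isosceles", "filled", rng)
    with pytest.raises(ValueError, match="outline"):
        geo.disassemble(solid, None, rng)


# -- dot placement ----------------------------------------------------------


def ray_cast_inside(point, vertices):
    """Independent point-in-polygon oracle (even-odd ray casting)."""
    x, y = point
    inside = False
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        if (y0 > y) != (y1 > y):
            xt = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
            if xt > x:
                inside = not inside
    return inside


@pytest.mark.parametrize("inside", [True, False])
@pytest.mark.parametrize("figure_kind", ["circle", "square"])
def test_dot_placement_matches_ray_casting_oracle(inside, figure_kind, rng):
    if figure_kind == "circle":
        fig = geo.make_regular("circle", rng, style="outline")
    else:
        fig = geo.make_quadrilateral("square", rng, style="outline")
    comp = geo.place_dot(fig, inside, 8.0, rng)
    assert comp.part_roles == ["figure", "dot"]
    dot_center = geo.polygon_centroid(comp.parts[1].vertices)
    assert ray_cast_inside(dot_center, fig.vertices) == inside


def test_dot_requires_outline_figure(rng):
    solid = geo.make_regular("circle", rng, style="filled")
    with pytest.raises(ValueError, match="outline"):
        geo.place_dot(solid, True, 8.0, rng)


# -- similarity transform ---------------------------------------------------


def test_identity_transform_preserves_geometry(rng):
    poly = geo.make_quadrilateral("trapezoid", rng)
    spec = geo.ShapeSpec(
        "trapezoid", poly, geo.Transform(geo.Point2(0, 0), 0.0, 1.0), 0
    )
    out = geo.apply_transform(spec)
    assert out.vertices == pytest.approx(poly.vertices, abs=1e-12)


@pytest.mark.parametrize("rotation", [90.0, 45.0, 210.0])
def test_rotated_square_remains_square(rotation, rng):
    poly = geo.make_quadrilateral("square", rng)
    spec = geo.ShapeSpec(
        "square", poly, geo.Transform(geo.Point2(128, 128), rotation, 1.0), 0
    )
    out = geo.apply_transform(spec)
    assert np.ptp(geo.side_lengths(out)) == pytest.approx(0.0, abs=1e-9)
    assert oracle_angles_deg(out.vertices) == pytest.approx(90.0, abs=1e-9)


def test_scaling_preserves_hole_ratio(rng):
    ann = geo.make_annulus("circle", 0.5, rng)
    spec = geo.ShapeSpec(
        "ring", ann, geo.Transform(geo.Point2(128, 128), 30.0, 0.5), 0
    )
    out = geo.apply_transform(spec)
    c = geo.polygon_centroid(out.outer.vertices)
    r_out = np.linalg.norm(out.outer.vertices - c, axis=1)
    r_in = np.linalg.norm(out.inner.vertices - c, axis=1)
    assert r_in / r_out == pytest.approx(0.5, abs=1e-9)


def test_transform_rejects_nonpositive_scale():
    with pytest.raises(ValueError, match="scale"):
        geo.Transform(geo.Point2(0, 0), 0.0, 0.0)
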