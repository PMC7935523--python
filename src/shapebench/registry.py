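"""The 24-category stimulus registry and per-category sampling.

Each category couples a geometry builder with its sampling ranges and a
transform policy.  The defaults reproduce the study conditions: every image
varies by translation, rotation, and scaling, with the category-defining
predicate (parallel pairs, equal sides, holes, connectivity, containment)
held invariant.

Category names follow the learning/transfer task table, with the solid
shapes used in the hole tasks suffixed ``-solid`` to keep them distinct
from the quadrilateral categories of the local-feature tasks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import yaml

from . import geometry as geo
from .errors import ShapeGenerationError
from .geometry import (
    Geometry,
    Point2,
    ShapeSpec,
    Transform,
    apply_transform,
    geometry_bounds,
)

__all__ = ["CategoryDef", "ShapeRegistry", "default_registry", "CATEGORY_NAMES"]

CATEGORY_NAMES: tuple[str, ...] = (
    "square",
    "rectangle",
    "trapezoid",
    "parallelogram",
    "disk",
    "ring",
    "triangle-solid",
    "triangle-ring",
    "square-solid",
    "square-ring",
    "irregular-disk",
    "irregular-ring",
    "irregular-triangle-solid",
    "irregular-triangle-ring",
    "irregular-square",
    "irregular-square-ring",
    "isosceles-triangle-outline",
    "disassembled-isosceles-triangle",
    "irregular-triangle-outline",
    "disassembled-irregular-triangle",
    "dot-inside-circle",
    "dot-outside-circle",
    "dot-inside-square",
    "dot-outside-square",
)


@dataclass(frozen=True)
class CategoryDef:
    """Declarative description of one category's construction."""

    name: str
    family: str  # builder key
    style: str = "filled"
    params: dict[str, Any] = field(default_factory=dict)
    #: expected rendered topology, used as ground truth in validation:
    #: (n_components, n_holes, enclosed_dot or None)
    topology: tuple[int, int, bool | None] = (1, 0, None)


def _quad(family: str):
    def build(rng: np.random.Generator, params: dict) -> Geometry:
        return geo.make_quadrilateral(family, rng, style=params.get("style", "filled"))

    return build


def _solid(kind: str):
    def build(rng: np.random.Generator, params: dict) -> Geometry:
        return geo.make_regular(kind, rng)

    return build


def _annulus(kind: str):
    def build(rng: np.random.Generator, params: dict) -> Geometry:
        lo, hi = params.get("hole_ratio_range", (0.3, 0.6))
        return geo.make_annulus(kind, rng.uniform(lo, hi), rng)

    return build


def _irregular(base_builder):
    def build(rng: np.random.Generator, params: dict) -> Geometry:
        base = base_builder(rng, params)
        return geo.make_irregular(
            base,
            params.get("amplitude", 0.15),
            params.get("n_harmonics", 5),
            rng,
        )

    return build


def _triangle_outline(kind: str):
    def build(rng: np.random.Generator, params: dict) -> Geometry:
        return geo.make_triangle(kind, "outline", rng)

    return build


def _disassembled(kind: str):
    def build(rng: np.random.Generator, params: dict) -> Geometry:
        tri = geo.make_triangle(kind, "outline", rng)
        # The placement transform scales vertex geometry but not stroke
        # widths, so the separation that survives rendering is
        # scale * centerline_gap - stroke.  Demand a centerline gap large
        # enough that the rendered gap stays >= 2 strokes at this scale.
        scale = params.get("_scale_hint", 1.0)
        gap = (2.0 * tri.stroke_width + tri.stroke_width) / scale
        return geo.disassemble(tri, None, rng, gap=gap)

    return build


def _irregular_triangle_solid(rng: np.random.Generator, params: dict) -> Geometry:
    tri = geo.make_triangle("irregular", "filled", rng)
    return geo.make_irregular(
        tri, params.get("amplitude", 0.15), params.get("n_harmonics", 5), rng
    )


def _dot_figure(figure_kind: str, inside: bool):
    def build(rng: np.random.Generator, params: dict) -> Geometry:
        if figure_kind == "circle":
            fig = geo.make_regular("circle", rng, style="outline",
                                   radius_range=(55.0, 80.0))
        else:
            fig = geo.make_quadrilateral("square", rng, style="outline")
        dot_radius = rng.uniform(*params.get("dot_radius_range", (6.0, 10.0)))
        return geo.place_dot(fig, inside, dot_radius, rng)

    return build


_BUILDERS: dict[str, Callable[[np.random.Generator, dict], Geometry]] = {
    "square": _quad("square"),
    "rectangle": _quad("rectangle"),
    "trapezoid": _quad("trapezoid"),
    "parallelogram": _quad("parallelogram"),
    "disk": _solid("circle"),
    "ring": _annulus("circle"),
    "triangle-solid": _solid("triangle"),
    "triangle-ring": _annulus("triangle"),
    "square-solid": _solid("square"),
    "square-ring": _annulus("square"),
    "irregular-disk": _irregular(_solid("circle")),
    "irregular-ring": _irregular(_annulus("circle")),
    "irregular-triangle-solid": _irregular_triangle_solid,
    "irregular-triangle-ring": _irregular(_annulus("triangle")),
    "irregular-square": _irregular(_solid("square")),
    "irregular-square-ring": _irregular(_annulus("square")),
    "isosceles-triangle-outline": _triangle_outline("isosceles"),
    "disassembled-isosceles-triangle": _disassembled("isosceles"),
    "irregular-triangle-outline": _triangle_outline("irregular"),
    "disassembled-irregular-triangle": _disassembled("irregular"),
    "dot-inside-circle": _dot_figure("circle", True),
    "dot-outside-circle": _dot_figure("circle", False),
    "dot-inside-square": _dot_figure("square", True),
    "dot-outside-square": _dot_figure("square", False),
}


def _expected_topology(name: str) -> tuple[int, int, bool | None]:
    if name.startswith("disassembled"):
        return (3, 0, None)
    if name.endswith("-ring") or name == "ring":
        return (1, 1, None)
    if name.endswith("-outline") or name == "isosceles-triangle-outline":
        return (1, 1, None)  # a closed stroked outline encloses one hole
    if name.startswith("dot-inside"):
        return (2, 1, True)
    if name.startswith("dot-outside"):
        return (2, 1, False)
    return (1, 0, None)


@dataclass
class ShapeRegistry:
    """All category definitions plus canvas and transform policy."""

    canvas_size: int = 256
    canvas_margin: float = 4.0
    rotation_range: tuple[float, float] = (0.0, 360.0)
    scale_range: tuple[float, float] = (0.5, 1.0)
    categories: dict[str, CategoryDef] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.categories:
            self.categories = {
                name: CategoryDef(
                    name=name, family=name, topology=_expected_topology(name)
                )
                for name in CATEGORY_NAMES
            }

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.categories)

    def build_geometry(
        self,
        category: str,
        rng: np.random.Generator,
        scale_hint: float = 1.0,
    ) -> Geometry:
        """Build one geometry sample; ``scale_hint`` is the placement scale
        the geometry will be rendered at, which gap-sensitive builders use
        to keep separations stroke-safe."""
        if category not in self.categories:
            raise ValueError(f"unknown category: {category!r}")
        cdef = self.categories[category]
        params = dict(cdef.params)
        params["_scale_hint"] = scale_hint
        return _BUILDERS[cdef.family](rng, params)

    def sample_spec(self, category: str, seed: int) -> ShapeSpec:
        """Sample a full stimulus: geometry plus an in-canvas placement.

        The translation is sampled uniformly over the positions that keep
        the rotated, scaled shape fully on the canvas with the configured
        margin; the rotation is uniform over the configured range and the
        scale uniform over the configured fraction of base size.
        """
        rng = np.random.default_rng(seed)
        for _ in range(geo.RETRY_LIMIT):
            rot = rng.uniform(*self.rotation_range)
            scale = rng.uniform(*self.scale_range)
            try:
                g = self.build_geometry(category, rng, scale_hint=scale)
            except ShapeGenerationError:
                continue  # gap infeasible at this scale; draw a fresh one
            probe = ShapeSpec(
                category=category,
                geometry=g,
                transform=Transform(Point2(0.0, 0.0), rot, scale),
                seed=seed,
            )
            xmin, ymin, xmax, ymax = geometry_bounds(apply_transform(probe))
            m = self.canvas_margin
            lo_x, hi_x = m - xmin, self.canvas_size - m - xmax
            lo_y, hi_y = m - ymin, self.canvas_size - m - ymax
            if lo_x > hi_x or lo_y > hi_y:
                continue  # shape too large at this rotation; resample
            tx = rng.uniform(lo_x, hi_x)
            ty = rng.uniform(lo_y, hi_y)
            return ShapeSpec(
                category=category,
                geometry=g,
                transform=Transform(Point2(tx, ty), rot, scale),
                seed=seed,
            )
        raise ShapeGenerationError(
            f"no in-canvas placement for category {category!r}, seed {seed}"
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "canvas_size": self.canvas_size,
            "canvas_margin": self.canvas_margin,
            "rotation_range": list(self.rotation_range),
            "scale_range": list(self.scale_range),
            "categories": {
                name: {
                    "family": c.family,
                    "style": c.style,
                    "params": c.params,
                    "topology": list(c.topology),
                }
                for name, c in self.categories.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ShapeRegistry":
        cats = {
            name: CategoryDef(
                name=name,
                family=c.get("family", name),
                style=c.get("style", "filled"),
                params=dict(c.get("params", {})),
                topology=tuple(c.get("topology", _expected_topology(name))),
            )
            for name, c in d.get("categories", {}).items()
        }
        return cls(
            canvas_size=int(d.get("canvas_size", 256)),
            canvas_margin=float(d.get("canvas_margin", 4.0)),
            rotation_range=tuple(d.get("rotation_range", (0.0, 360.0))),
            scale_range=tuple(d.get("scale_range", (0.5, 1.0))),
            categories=cats,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ShapeRegistry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_registry() -> ShapeRegistry:
    return ShapeRegistry()


def derive_seed(master_seed: int, category: str, index: int) -> int:
    """Stable per-image seed from (master seed, category, index).

    Hash-based so the seed of any image is independent of generation order
    and of which other categories are generated.
    """
    digest = hashlib.sha256(
        f"{master_seed}:{category}:{index}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
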