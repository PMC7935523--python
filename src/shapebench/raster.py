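"""Rasterization of shape specs and pixel-level topological measurement.

Rendering draws dark shapes on a light background.  Antialiasing is done by
supersampling: the geometry is drawn at ``SUPERSAMPLE`` times the target
resolution and area-downsampled, which gives smooth edges without the seam
artifacts of per-primitive antialiasing.  Topology is measured on the
binarized image with the standard complementary connectivity pair —
8-connected foreground, 4-connected background — so hole counting is
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from scipy.ndimage import binary_dilation
from skimage.measure import label

from .geometry import AnnularShape, Geometry, Polygon, ShapeSpec, apply_transform

__all__ = [
    "TopologySummary",
    "render",
    "render_part_mask",
    "to_model_input",
    "topology",
    "containment",
    "MODEL_INPUT_SIZES",
    "FOREGROUND_THRESHOLD",
]

SUPERSAMPLE = 4
FOREGROUND_THRESHOLD = 128
BACKGROUND = 255
INK = 0

#: per-model square input sizes (pixels); all presets expect 3 channels
MODEL_INPUT_SIZES: dict[str, int] = {
    "alexnet": 227,
    "vgg19": 224,
    "resnet101": 224,
    "inception-resnet-v2": 299,
    "reference": 64,
}


@dataclass(frozen=True)
class TopologySummary:
    """Counts of the global invariants readable from a binary image."""

    n_components: int
    n_holes: int
    enclosed_dot: bool | None = None


#: opening radius (canvas px) applied to light interior regions before
#: drawing; truncates tips thinner than the raster resolution that would
#: otherwise discretize into isolated background specks (spurious holes)
_LIGHT_OPENING_RADIUS = 1.25


def _open_region(region):
    r = _LIGHT_OPENING_RADIUS
    return region.buffer(-r, quad_segs=4).buffer(r, quad_segs=4)


def _fill_shapely(draw: ImageDraw.ImageDraw, region, ss: int, color: int) -> None:
    geoms = getattr(region, "geoms", [region])
    for g in geoms:
        if g.is_empty:
            continue
        draw.polygon([(ss * x, ss * y) for x, y in g.exterior.coords], fill=color)


def _draw_part(draw: ImageDraw.ImageDraw, part, ss: int, ink: int) -> None:
    if isinstance(part, Polygon):
        if part.style == "filled":
            _fill_shapely(draw, _open_region(part.shapely), ss, ink)
        else:
            # Stroke the boundary as a polygon difference: dilate the region
            # by half the stroke (round joins) and fill, then restore the
            # eroded interior.  Unlike per-segment stroking this cannot
            # pinch off background pockets at sharp vertices.
            half = part.stroke_width / 2.0
            sh = part.shapely
            _fill_shapely(draw, sh.buffer(half, quad_segs=8), ss, ink)
            inner = _open_region(sh.buffer(-half, quad_segs=8))
            _fill_shapely(draw, inner, ss, BACKGROUND)
    else:
        w = max(1, round(part.stroke_width * ss))
        p0 = tuple(ss * part.p0)
        p1 = tuple(ss * part.p1)
        draw.line([p0, p1], fill=ink, width=w)
        r = w / 2.0
        for x, y in (p0, p1):
            draw.ellipse([x - r, y - r, x + r, y + r], fill=ink)


def _render_geometry(
    g: Geometry,
    canvas_size: int,
    antialias: bool,
    *,
    only_role: str | None = None,
    ink: int = INK,
    background: int = BACKGROUND,
) -> np.ndarray:
    ss = SUPERSAMPLE if antialias else 1
    im = Image.new("L", (canvas_size * ss, canvas_size * ss), color=background)
    draw = ImageDraw.Draw(im)
    if isinstance(g, Polygon):
        parts, roles = [g], ["figure"]
    elif isinstance(g, AnnularShape):
        _fill_shapely(draw, _open_region(g.outer.shapely), ss, ink)
        _fill_shapely(draw, _open_region(g.inner.shapely), ss, background)
        parts, roles = [], []
    else:
        parts, roles = list(g.parts), list(g.part_roles)
    for part, role in zip(parts, roles):
        if only_role is not None and role != only_role:
            continue
        _draw_part(draw, part, ss, ink)
    if ss > 1:
        im = im.resize((canvas_size, canvas_size), Image.BOX)
    return np.asarray(im, dtype=np.uint8)


def render(spec: ShapeSpec, canvas_size: int = 256, antialias: bool = True) -> np.ndarray:
    """Rasterize a spec (with its transform applied) to a grayscale array.

    Returns a ``(canvas_size, canvas_size)`` uint8 array, dark shape on a
    light background.  Deterministic for fixed inputs.
    """
    return _render_geometry(apply_transform(spec), canvas_size, antialias)


def render_part_mask(
    spec: ShapeSpec, role: str, canvas_size: int = 256
) -> np.ndarray:
    """Boolean mask of the pixels covered by parts with the given role.

    Rendered without antialiasing so the mask is crisp; used e.g. to
    isolate the dot of a dot-figure for the containment test.
    """
    img = _render_geometry(
        apply_transform(spec), canvas_size, antialias=False, only_role=role
    )
    return img < FOREGROUND_THRESHOLD


def to_model_input(img: np.ndarray, preset: str) -> np.ndarray:
    """Resize to a model's square input size and replicate to 3 channels."""
    if preset not in MODEL_INPUT_SIZES:
        raise ValueError(f"unknown model preset: {preset!r}")
    size = MODEL_INPUT_SIZES[preset]
    if img.ndim == 3:
        img = img[..., 0]
    if img.shape != (size, size):
        pil = Image.fromarray(img, mode="L").resize((size, size), Image.LANCZOS)
        img = np.asarray(pil, dtype=np.uint8)
    return np.repeat(img[..., None], 3, axis=2)


def _binarize(img: np.ndarray, threshold: int) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., 0]
    return img < threshold


def topology(img: np.ndarray, threshold: int = FOREGROUND_THRESHOLD) -> TopologySummary:
    """Count foreground components and enclosed holes of a rendered image.

    Foreground (dark) components use 8-connectivity; holes are background
    components under 4-connectivity that do not touch the image border.
    """
    fg = _binarize(img, threshold)
    if not fg.any():
        return TopologySummary(0, 0)
    n_components = int(label(fg, connectivity=2).max())
    bg_labels = label(~fg, connectivity=1)
    border = np.unique(
        np.concatenate(
            [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]
        )
    )
    border = set(border[border > 0].tolist())
    all_bg = set(np.unique(bg_labels[bg_labels > 0]).tolist())
    return TopologySummary(n_components, len(all_bg - border))


def containment(
    img: np.ndarray,
    dot_mask: np.ndarray,
    threshold: int = FOREGROUND_THRESHOLD,
) -> bool:
    """Whether the dot lies in a region enclosed by the rest of the figure.

    The dot's pixels are removed from the foreground; the background region
    containing the dot centroid is then flood-labeled, and the dot counts
    as enclosed iff that region does not reach the image border.
    """
    if not dot_mask.any():
        raise ValueError("dot_mask is empty")
    fg = _binarize(img, threshold)
    # The dot must be its own foreground component, not merged with the
    # figure.  A small halo is allowed around the supplied mask so the
    # antialiased boundary of the dot does not count as overlap.
    fg_labels = label(fg, connectivity=2)
    dot_ids = np.unique(fg_labels[dot_mask & fg])
    dot_ids = dot_ids[dot_ids > 0]
    if dot_ids.size == 0:
        raise ValueError("dot_mask covers no foreground pixels")
    halo = binary_dilation(dot_mask, iterations=2)
    dot_component = np.isin(fg_labels, dot_ids)
    if (dot_component & ~halo).any():
        raise ValueError("dot overlaps or touches the figure")
    figure = fg & ~dot_component
    bg = ~figure
    bg_labels = label(bg, connectivity=1)
    ys, xs = np.nonzero(dot_component)
    cy, cx = int(round(ys.mean())), int(round(xs.mean()))
    region = bg_labels[cy, cx]
    if region == 0:
        raise ValueError("dot centroid is not in the background after removal")
    border_regions = set(
        np.unique(
            np.concatenate(
                [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]
            )
        ).tolist()
    )
    return region not in border_regions
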