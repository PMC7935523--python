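"""Dataset assembly: generation, manifests, splits, and image loading.

The on-disk layout is the common image-folder convention —
``<root>/<category>/<index>.png`` — with a CSV manifest listing every image
(path, category, seed, JSON-encoded placement parameters) and a JSON
sidecar capturing the registry configuration that produced it.

Default study conditions: 24 categories, 540 images per category, with an
85%/15% per-category train/validation split for the learning tasks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .raster import render, to_model_input
from .registry import ShapeRegistry, default_registry, derive_seed

__all__ = [
    "IMAGES_PER_CATEGORY",
    "TRAIN_FRACTION",
    "generate_dataset",
    "generate_arrays",
    "make_splits",
    "load_manifest",
    "load_images",
]

IMAGES_PER_CATEGORY = 540
TRAIN_FRACTION = 0.85


def _spec_params(spec) -> str:
    t = spec.transform
    return json.dumps(
        {
            "translation": [t.translation.x, t.translation.y],
            "rotation_deg": t.rotation_deg,
            "scale": t.scale,
        }
    )


def generate_dataset(
    out_dir: str | Path,
    master_seed: int,
    *,
    registry: ShapeRegistry | None = None,
    images_per_category: int = IMAGES_PER_CATEGORY,
    categories: Sequence[str] | None = None,
    antialias: bool = True,
) -> pd.DataFrame:
    """Render the full shape dataset to disk and return its manifest.

    Per-image seeds are derived by hashing (master seed, category, index),
    so any category's images are reproducible independently of generation
    order.  The manifest is written as ``manifest.csv`` next to the images
    with the registry configuration as ``registry.json``.
    """
    registry = registry or default_registry()
    names = tuple(categories) if categories is not None else registry.names
    unknown = set(names) - set(registry.names)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for category in names:
        cat_dir = out / category
        cat_dir.mkdir(exist_ok=True)
        for index in range(images_per_category):
            seed = derive_seed(master_seed, category, index)
            spec = registry.sample_spec(category, seed)
            img = render(spec, registry.canvas_size, antialias=antialias)
            rel = f"{category}/{index:04d}.png"
            Image.fromarray(img, mode="L").save(out / rel)
            rows.append(
                {
                    "path": rel,
                    "category": category,
                    "split": "",
                    "seed": seed,
                    "params_json": _spec_params(spec),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    with open(out / "registry.json", "w") as fh:
        json.dump(
            {"master_seed": master_seed, "registry": registry.to_dict()}, fh, indent=1
        )
    return manifest


def generate_arrays(
    categories: Sequence[str],
    master_seed: int,
    *,
    registry: ShapeRegistry | None = None,
    images_per_category: int = IMAGES_PER_CATEGORY,
    preset: str | None = None,
    antialias: bool = True,
) -> dict[str, np.ndarray]:
    """In-memory variant of :func:`generate_dataset`.

    Returns ``{category: stacked uint8 images}``; when ``preset`` is given
    each image is resized to that model's input size with 3 channels.
    Seeds match :func:`generate_dataset`, so the pixels are identical to
    the on-disk pipeline.
    """
    registry = registry or default_registry()
    out: dict[str, np.ndarray] = {}
    for category in categories:
        imgs = []
        for index in range(images_per_category):
            seed = derive_seed(master_seed, category, index)
            spec = registry.sample_spec(category, seed)
            img = render(spec, registry.canvas_size, antialias=antialias)
            if preset is not None:
                img = to_model_input(img, preset)
            imgs.append(img)
        out[category] = np.stack(imgs)
    return out


def make_splits(
    manifest: pd.DataFrame,
    categories: Sequence[str],
    train_frac: float = TRAIN_FRACTION,
    seed: int = 0,
) -> pd.DataFrame:
    """Tag a stratified train/validation split for the given categories.

    Per category, ``round(train_frac * n)`` images are tagged ``train`` and
    the rest ``validation`` (459/81 under the default 540 images and 85%
    fraction); rows of other categories keep their existing tag.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly inside (0, 1)")
    present = set(manifest["category"])
    missing = [c for c in categories if c not in present]
    if missing:
        raise ValueError(f"categories absent from manifest: {missing}")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    for category in categories:
        idx = out.index[out["category"] == category].to_numpy()
        n_train = round(train_frac * len(idx))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(
                f"train_frac={train_frac} leaves an empty split for {category!r}"
            )
        perm = rng.permutation(len(idx))
        out.loc[idx[perm[:n_train]], "split"] = "train"
        out.loc[idx[perm[n_train:]], "split"] = "validation"
    return out


def load_manifest(root: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(root) / "manifest.csv", keep_default_na=False)


def load_images(
    root: str | Path,
    manifest: pd.DataFrame,
    preset: str | None = None,
) -> np.ndarray:
    """Load the manifest's images in row order, optionally model-sized."""
    root = Path(root)
    imgs = []
    for rel in manifest["path"]:
        img = np.asarray(Image.open(root / rel).convert("L"), dtype=np.uint8)
        if preset is not None:
            img = to_model_input(img, preset)
        imgs.append(img)
    return np.stack(imgs)
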