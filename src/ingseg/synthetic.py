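"""Seeded synthetic ingredient imagery with exact ground truth.

Single-"ingredient" images are full-frame procedural textures; each class is
a (texture family, base hue) pair and owns a handful of visual variants that
perturb hue, scale and orientation — standing in for the appearance changes
that cutting and cooking introduce.  Multi-ingredient scenes composite K
textured regions (Voronoi cells inside an elliptical plate, or packed
blobs) over a uniform background, with a pixel-aligned label map and a
blue-background rendering for evaluation.
"""

from __future__ import annotations

import colorsys
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ingseg.segmentation import blue_background_composite
from ingseg.taxonomy import IngredientTaxonomy, lift_label

logger = logging.getLogger(__name__)

TEXTURE_FAMILIES = ("stripes", "spots", "checker", "gradient", "speckle")


@dataclass(frozen=True)
class VariantSpec:
    """One visual variant of a class: a hue/scale/orientation perturbation."""

    hue_shift: float = 0.0
    scale: float = 1.0
    orientation: float = 0.0  # radians


@dataclass(frozen=True)
class SyntheticClassSpec:
    class_id: int
    texture: str
    base_hue: float
    variants: tuple[VariantSpec, ...] = (VariantSpec(),)
    images_per_variant: int = 6
    name: str = ""

    def __post_init__(self):
        if self.texture not in TEXTURE_FAMILIES:
            raise ValueError(f"unknown texture family {self.texture!r}")
        if not self.variants:
            raise ValueError("a class needs at least one variant")
        if not 5 <= self.images_per_variant <= 10:
            raise ValueError("images_per_variant must lie in [5, 10]")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one multi-ingredient composite with known label map."""

    k: int
    class_ids: tuple[int, ...]
    size: int = 64
    layout: str = "voronoi"  # or "blobs"
    background_color: tuple[int, int, int] = (0, 0, 255)
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if len(self.class_ids) != self.k:
            raise ValueError("need exactly K class ids")
        if self.layout not in ("voronoi", "blobs"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclass
class SceneSample:
    image: np.ndarray        # H x W x 3 uint8, natural background
    label_map: np.ndarray    # H x W uint8, 0 = background, 1..K = regions
    blue_image: np.ndarray   # image with background replaced by pure blue
    spec: SceneSpec


def _two_tone(base_hue: float) -> tuple[np.ndarray, np.ndarray]:
    c1 = np.array(colorsys.hsv_to_rgb(base_hue % 1.0, 0.75, 0.9))
    c2 = np.array(colorsys.hsv_to_rgb(base_hue % 1.0, 0.45, 0.45))
    return c1, c2


def _rotated_coords(size: int, orientation: float) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    c, s = np.cos(orientation), np.sin(orientation)
    return c * xx + s * yy, -s * xx + c * yy


def render_texture(
    texture: str,
    base_hue: float,
    size: int,
    variant: VariantSpec = VariantSpec(),
    rng: np.random.Generator | None = None,
    noise_level: float = 0.02,
) -> np.ndarray:
    """Render one full-frame texture as an H x W x 3 uint8 image."""
    rng = rng or np.random.default_rng(0)
    hue = (base_hue + variant.hue_shift) % 1.0
    c1, c2 = _two_tone(hue)
    period = 8.0 * variant.scale
    u, v = _rotated_coords(size, variant.orientation)
    phase = rng.uniform(0, period, size=2)
    u = u + phase[0]
    v = v + phase[1]
    if texture == "stripes":
        field01 = (np.sin(2 * np.pi * u / period) > 0).astype(np.float64)
    elif texture == "checker":
        field01 = ((np.floor(u / period) + np.floor(v / period)) % 2).astype(
            np.float64
        )
    elif texture == "spots":
        du = u % period - period / 2
        dv = v % period - period / 2
        field01 = (du**2 + dv**2 < (0.3 * period) ** 2).astype(np.float64)
    elif texture == "gradient":
        span = np.ptp(u)
        field01 = (u - u.min()) / span if span > 0 else np.zeros_like(u)
    elif texture == "speckle":
        noise = gaussian_filter(rng.standard_normal((size, size)),
                                sigma=1.2 * variant.scale)
        field01 = (noise > np.median(noise)).astype(np.float64)
    else:  # pragma: no cover - guarded by SyntheticClassSpec
        raise ValueError(f"unknown texture family {texture!r}")
    img = field01[:, :, None] * c1[None, None, :]
    img += (1.0 - field01[:, :, None]) * c2[None, None, :]
    if noise_level > 0:
        img = img + rng.normal(0, noise_level, size=img.shape)
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def generate_single_ingredient_image(
    spec: SyntheticClassSpec,
    variant: int,
    seed: int,
    size: int = 64,
    noise_level: float = 0.02,
) -> tuple[np.ndarray, int]:
    """One full-frame single-class image plus its leaf label; seed-exact."""
    if not 0 <= variant < len(spec.variants):
        raise ValueError(
            f"class {spec.class_id} has {len(spec.variants)} variants; "
            f"asked for {variant}"
        )
    rng = np.random.default_rng([seed, spec.class_id, variant])
    img = render_texture(spec.texture, spec.base_hue, size, spec.variants[variant],
                         rng, noise_level)
    return img, spec.class_id


def default_class_specs(
    n_classes: int,
    variants_per_class: int = 2,
    images_per_variant: int = 6,
    seed: int = 0,
) -> list[SyntheticClassSpec]:
    """Separable-but-related class set: hues are shared pairwise across
    texture families, so classes differ by colour *or* pattern, not always
    both."""
    rng = np.random.default_rng(seed)
    specs = []
    for cid in range(n_classes):
        texture = TEXTURE_FAMILIES[cid % len(TEXTURE_FAMILIES)]
        base_hue = (cid // len(TEXTURE_FAMILIES) * 0.37 + cid * 0.193) % 1.0
        variants = tuple(
            VariantSpec(
                hue_shift=float(rng.uniform(-0.04, 0.04)) if v else 0.0,
                scale=float(rng.uniform(0.8, 1.4)) if v else 1.0,
                orientation=float(rng.uniform(0, np.pi)) if v else 0.0,
            )
            for v in range(variants_per_class)
        )
        specs.append(
            SyntheticClassSpec(
                class_id=cid,
                texture=texture,
                base_hue=float(base_hue),
                variants=variants,
                images_per_variant=images_per_variant,
                name=f"class{cid:03d}",
            )
        )
    return specs


@dataclass
class SyntheticDataset:
    images: np.ndarray           # (N, H, W, 3) uint8
    leaf_labels: np.ndarray      # (N,)
    hierarchical_labels: np.ndarray  # (N, 4) columns y1..y4
    manifest: pd.DataFrame
    train_idx: np.ndarray
    test_idx: np.ndarray


def generate_dataset(
    class_specs: list[SyntheticClassSpec],
    tax: IngredientTaxonomy,
    split_seed: int = 0,
    image_seed: int = 0,
    size: int = 64,
) -> SyntheticDataset:
    """Render every class/variant/image combination and 80/20-split it.

    Class ids index the taxonomy's level-4 leaves; leaf labels are lifted to
    all four levels for the manifest.
    """
    from ingseg.training import split_80_20

    for spec in class_specs:
        if not 0 <= spec.class_id < tax.num_leaves:
            raise ValueError(
                f"class id {spec.class_id} is not a level-4 leaf of the taxonomy"
            )
    images, leaves, rows = [], [], []
    for spec in class_specs:
        for v in range(len(spec.variants)):
            for i in range(spec.images_per_variant):
                img, leaf = generate_single_ingredient_image(
                    spec, v, seed=image_seed * 100003 + i, size=size
                )
                hl = lift_label(tax, leaf)
                images.append(img)
                leaves.append(leaf)
                rows.append(
                    {
                        "image_id": f"c{spec.class_id:03d}_v{v}_{i:02d}",
                        "class_id": leaf,
                        "variant": v,
                        "y1": hl.y1,
                        "y2": hl.y2,
                        "y3": hl.y3,
                        "y4": hl.y4,
                    }
                )
    images_arr = np.stack(images)
    leaves_arr = np.array(leaves)
    manifest = pd.DataFrame(rows)
    hier = manifest[["y1", "y2", "y3", "y4"]].to_numpy()
    train_idx, test_idx = split_80_20(leaves_arr, seed=split_seed)
    manifest["split"] = "train"
    manifest.loc[test_idx, "split"] = "test"
    return SyntheticDataset(
        images=images_arr,
        leaf_labels=leaves_arr,
        hierarchical_labels=hier,
        manifest=manifest,
        train_idx=train_idx,
        test_idx=test_idx,
    )


def _voronoi_label_map(size: int, k: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2
    ry = rx = 0.46 * size
    plate = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    seeds = rng.uniform(0.15 * size, 0.85 * size, size=(k, 2))
    d2 = (yy[None] - seeds[:, 0, None, None]) ** 2
    d2 += (xx[None] - seeds[:, 1, None, None]) ** 2
    nearest = np.argmin(d2, axis=0)
    label_map = np.where(plate, nearest + 1, 0).astype(np.uint8)
    return label_map


def _blob_label_map(size: int, k: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    label_map = np.zeros((size, size), dtype=np.uint8)
    radius = 0.28 * size / np.sqrt(k)
    centers: list[np.ndarray] = []
    for region in range(1, k + 1):
        for _ in range(200):
            c = rng.uniform(radius, size - radius, size=2)
            if all(np.hypot(*(c - o)) > 1.9 * radius for o in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError("blob placement failed")
        disk = (yy - centers[-1][0]) ** 2 + (xx - centers[-1][1]) ** 2 <= radius**2
        label_map[disk] = region
    return label_map


def compose_multi_ingredient_scene(
    spec: SceneSpec, class_specs: list[SyntheticClassSpec]
) -> SceneSample:
    """Composite K textured regions over a uniform background.

    Retries layout generation (with a logged internal reseed) until every
    region holds at least 1% of the pixels.
    """
    by_id = {c.class_id: c for c in class_specs}
    missing = [cid for cid in spec.class_ids if cid not in by_id]
    if missing:
        raise ValueError(f"no class spec for ids {missing}")
    size = spec.size
    min_pixels = max(1, int(0.01 * size * size))
    label_map = None
    for attempt in range(50):
        rng = np.random.default_rng([spec.seed, attempt])
        try:
            candidate = (
                _voronoi_label_map(size, spec.k, rng)
                if spec.layout == "voronoi"
                else _blob_label_map(size, spec.k, rng)
            )
        except RuntimeError:
            continue
        sizes = [np.count_nonzero(candidate == r) for r in range(1, spec.k + 1)]
        if min(sizes) >= min_pixels:
            label_map = candidate
            if attempt:
                logger.info("scene %d: layout accepted on retry %d",
                            spec.seed, attempt)
            break
    if label_map is None:
        raise RuntimeError(
            f"could not place {spec.k} regions of >= {min_pixels} px in "
            f"{size} x {size} after 50 attempts"
        )
    rng = np.random.default_rng([spec.seed, 9999])
    image = np.zeros((size, size, 3), dtype=np.uint8)
    image[label_map == 0] = (90, 80, 70)  # neutral tabletop backdrop
    for region, cid in enumerate(spec.class_ids, start=1):
        cspec = by_id[cid]
        variant = int(rng.integers(len(cspec.variants)))
        tex = render_texture(
            cspec.texture, cspec.base_hue, size, cspec.variants[variant],
            rng, spec.noise_level,
        )
        image[label_map == region] = tex[label_map == region]
    blue = blue_background_composite(image, label_map)
    if spec.background_color != (0, 0, 255):
        blue = np.array(image, copy=True)
        blue[label_map == 0] = spec.background_color
    return SceneSample(image=image, label_map=label_map, blue_image=blue, spec=spec)
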