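"""Ingredient segmentation from classification feature maps.

Two mask-generation routes operate on the H x W x C4 grid of the last
convolutional stage:

* **Method 1** — keep channels whose sigmoid-normalized global mean exceeds
  0.5, merge transitively every pair of kept channels with positive Pearson
  correlation, then binarize each merged map.
* **Method 2** — treat each pixel as a C4-dimensional vector and k-means it
  into K clusters (K + 1 when a uniform background is present; the cluster
  that best overlaps the known background region is dropped).

Masks are produced at feature resolution, upscaled to image size with
nearest-neighbour interpolation, and multiplied element-wise into the image
to cut out per-ingredient segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.cluster import KMeans

from ingseg.attnet import FeatureMaps, forward_feature_maps
from ingseg.nn import sigmoid

logger = logging.getLogger(__name__)

BACKGROUND_BLUE = (0, 0, 255)


class DegenerateInputError(ValueError):
    """Raised when clustering is requested on featureless input."""


@dataclass(frozen=True)
class Method1Params:
    score_threshold: float = 0.5
    correlation_threshold: float = 0.0
    binarization: str = "minmax"  # or "otsu"


@dataclass(frozen=True)
class Method2Params:
    k: int
    background_present: bool = False
    restarts: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class MaskSet:
    """Binary masks plus provenance of how each was produced."""

    masks: list[np.ndarray]
    method: str
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        for i, m in enumerate(self.masks):
            if m.dtype != bool:
                raise ValueError(f"mask {i} is not binary (dtype {m.dtype})")
            if m.shape != self.masks[0].shape:
                raise ValueError("masks must share one shape")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def shape(self) -> tuple[int, int] | None:
        return self.masks[0].shape if self.masks else None


def channel_scores(f: FeatureMaps) -> np.ndarray:
    """Sigmoid of each channel's global mean activation."""
    return sigmoid(f.values.reshape(-1, f.num_channels).mean(axis=0))


def filter_channels(f: FeatureMaps, threshold: float = 0.5) -> np.ndarray:
    """Indices of channels whose score strictly exceeds the threshold."""
    return np.flatnonzero(channel_scores(f) > threshold)


def pairwise_channel_correlation(channels: np.ndarray) -> np.ndarray:
    """Pearson correlation between flattened channels (rows).

    Zero-variance channels correlate 0 with everything (including
    themselves) rather than producing NaNs.
    """
    x = channels.reshape(channels.shape[0], -1).astype(np.float64)
    centered = x - x.mean(axis=1, keepdims=True)
    std = centered.std(axis=1)
    n = x.shape[1]
    cov = centered @ centered.T / n
    denom = np.outer(std, std)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return r


def correlation_groups(r: np.ndarray, threshold: float = 0.0) -> list[list[int]]:
    """Transitive closure of 'correlation > threshold' edges."""
    n = r.shape[0]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if r[i, j] > threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def binarize_map(m: np.ndarray, policy: str = "minmax") -> np.ndarray:
    """Scale-invariant binarization of a real-valued map to a boolean mask."""
    mn, mx = float(m.min()), float(m.max())
    if mx <= mn:
        return np.zeros(m.shape, dtype=bool)
    if policy == "minmax":
        return (m - mn) / (mx - mn) >= 0.5
    if policy == "otsu":
        from skimage.filters import threshold_otsu

        return m > threshold_otsu(m)
    raise ValueError(f"unknown binarization policy {policy!r}")


def method1_generate_masks(f: FeatureMaps, p: Method1Params = Method1Params()) -> MaskSet:
    """Filter channels by score, merge positively correlated ones, binarize."""
    keep = filter_channels(f, p.score_threshold)
    if keep.size == 0:
        return MaskSet(masks=[], method="method1", provenance=[])
    stack = f.values[:, :, keep].transpose(2, 0, 1)  # (n_keep, H, W)
    r = pairwise_channel_correlation(stack)
    groups = correlation_groups(r, p.correlation_threshold)
    masks: list[np.ndarray] = []
    provenance: list[dict] = []
    for group in groups:
        merged = stack[group].mean(axis=0)
        mask = binarize_map(merged, p.binarization)
        src = [int(keep[g]) for g in group]
        if not mask.any():
            logger.info("method1: discarding empty mask from channels %s", src)
            continue
        masks.append(mask)
        provenance.append({"channels": src})
    return MaskSet(masks=masks, method="method1", provenance=provenance)


def downsample_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Area-style downsample of a binary mask; cell is set if >= half covered."""
    frac = _sk_resize(mask.astype(np.float64), shape, order=1,
                      anti_aliasing=False, preserve_range=True)
    return frac >= 0.5


def method2_generate_masks(
    f: FeatureMaps,
    p: Method2Params,
    background_region: np.ndarray | None = None,
) -> MaskSet:
    """K-means the per-pixel feature vectors into K (+1) clusters.

    ``background_region`` is a binary mask at source-image resolution marking
    the known background; required when ``p.background_present``.  The cluster
    overlapping it most is dropped so exactly K ingredient masks remain.
    """
    h, w, _ = f.values.shape
    vectors = f.values.reshape(h * w, -1).astype(np.float64)
    n_clusters = p.k + (1 if p.background_present else 0)
    if n_clusters > h * w:
        raise ValueError(f"{n_clusters} clusters exceed {h * w} pixels")
    if n_clusters > 1 and np.ptp(vectors, axis=0).max() == 0:
        raise DegenerateInputError(
            "all pixel feature vectors are identical; cannot form "
            f"{n_clusters} clusters"
        )
    if n_clusters == 1:
        labels = np.zeros(h * w, dtype=int)
    else:
        km = KMeans(n_clusters=n_clusters, n_init=p.restarts,
                    random_state=p.seed)
        labels = km.fit_predict(vectors)
    labels = labels.reshape(h, w)
    cluster_ids = list(range(n_clusters))
    if p.background_present:
        if background_region is None:
            raise ValueError("background_present requires a background_region mask")
        bg = downsample_mask(background_region.astype(bool), (h, w))
        overlaps = [int(np.sum((labels == c) & bg)) for c in cluster_ids]
        dropped = int(np.argmax(overlaps))
        logger.debug("method2: dropping background cluster %d (overlap %d px)",
                     dropped, overlaps[dropped])
        cluster_ids.remove(dropped)
    masks = [labels == c for c in cluster_ids]
    provenance = [{"cluster": int(c)} for c in cluster_ids]
    return MaskSet(masks=masks, method="method2", provenance=provenance)


def upscale_masks(m: MaskSet, target: tuple[int, int]) -> MaskSet:
    """Nearest-neighbour resize of every mask to image resolution."""
    if len(target) != 2 or min(target) < 1:
        raise ValueError(f"bad target size {target}")
    resized = [
        _sk_resize(mask.astype(np.uint8), target, order=0, anti_aliasing=False,
                   preserve_range=True).astype(bool)
        for mask in m.masks
    ]
    return MaskSet(masks=resized, method=m.method, provenance=list(m.provenance))


def extract_segments(image: np.ndarray, m: MaskSet) -> list[np.ndarray]:
    """Element-wise product of the image with each mask (per RGB channel)."""
    segments = []
    for mask in m.masks:
        if mask.shape != image.shape[:2]:
            raise ValueError(
                f"mask shape {mask.shape} does not match image {image.shape[:2]}"
            )
        segments.append((image * mask[:, :, None]).astype(image.dtype))
    return segments


def blue_background_composite(
    image: np.ndarray, label_map: np.ndarray, background_label: int = 0
) -> np.ndarray:
    """Replace background pixels (label 0 in the map) with pure blue."""
    if label_map.shape != image.shape[:2]:
        raise ValueError(
            f"label map shape {label_map.shape} does not match image "
            f"{image.shape[:2]}"
        )
    out = np.array(image, copy=True)
    out[label_map == background_label] = BACKGROUND_BLUE
    return out


def blue_region(image: np.ndarray, tolerance: int = 40) -> np.ndarray:
    """Pixels within ``tolerance`` of the pure-blue background colour."""
    diff = np.abs(image.astype(np.int32) - np.array(BACKGROUND_BLUE))
    return (diff <= tolerance).all(axis=2)


def segment_image(
    model,
    image: np.ndarray,
    method: str | int,
    params: Method1Params | Method2Params,
) -> tuple[MaskSet, list[np.ndarray]]:
    """Full pipeline: feature maps -> masks -> upscale -> segments.

    The image must match the model's input size (use the synthetic scene
    size or resize upstream).  For Method 2 with a background, the blue
    region of the input image identifies the cluster to drop.
    """
    method = str(method)
    size = model.input_size
    if image.shape[0] != size or image.shape[1] != size:
        from PIL import Image as PILImage

        image = np.asarray(
            PILImage.fromarray(np.asarray(image, dtype=np.uint8)).resize(
                (size, size), PILImage.BILINEAR
            )
        )
    f = forward_feature_maps(model, image)
    if method == "1":
        if not isinstance(params, Method1Params):
            raise TypeError("method 1 requires Method1Params")
        masks = method1_generate_masks(f, params)
    elif method == "2":
        if not isinstance(params, Method2Params):
            raise TypeError("method 2 requires Method2Params")
        bg = blue_region(image) if params.background_present else None
        masks = method2_generate_masks(f, params, background_region=bg)
    else:
        raise ValueError(f"unknown method {method!r}; expected '1' or '2'")
    upscaled = upscale_masks(masks, image.shape[:2])
    segments = extract_segments(image, upscaled)
    return upscaled, segments
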