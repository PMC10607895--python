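"""Gated-CNN classifier family and feature-map extraction.

The network is a stack of eight gated blocks (conv -> batch-norm -> sigmoid
score -> element-wise product).  Blocks 1-7 carry the widening channel
schedule and the three stride-2 reductions; block 8 maps to one channel per
class with its own kernel size.  Classification logits are the global
average pool of the final grid, so the last block's activations double as
per-class spatial evidence maps — the raw material for segmentation.

Four variants differ only in kernel sizes: "1" (all 1x1), "3" (all 3x3),
"1+3" (1x1 blocks, 3x3 final) and "3+1" (3x3 blocks, 1x1 final).

The multi-level flavour shares blocks 1-7 and stacks one gated block per
taxonomy level bottom-up (level 4 first, one output channel per category of
that level), each with its own pooled softmax head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ingseg.nn import (
    GatedBlock,
    Parameter,
    global_avg_pool,
    global_avg_pool_backward,
)
from ingseg.taxonomy import IngredientTaxonomy

#: variant tag -> (block kernel k, final kernel j)
VARIANT_KERNELS = {"1": (1, 1), "3": (3, 3), "1+3": (1, 3), "3+1": (3, 1)}

DEFAULT_CHANNELS = (64, 128, 128, 256, 256, 512, 512)
STRIDES = (2, 2, 2, 1, 1, 1, 1)


@dataclass(frozen=True)
class AttNetConfig:
    variant: str = "1"
    num_classes: int = 110
    input_size: int = 224
    channels: tuple[int, ...] = DEFAULT_CHANNELS
    strides: tuple[int, ...] = STRIDES
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANT_KERNELS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of "
                f"{sorted(VARIANT_KERNELS)}"
            )
        if len(self.channels) != 7 or len(self.strides) != 7:
            raise ValueError("channels and strides schedules must have length 7")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    @property
    def block_kernel(self) -> int:
        return VARIANT_KERNELS[self.variant][0]

    @property
    def final_kernel(self) -> int:
        return VARIANT_KERNELS[self.variant][1]

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "num_classes": self.num_classes,
            "input_size": self.input_size,
            "channels": list(self.channels),
            "strides": list(self.strides),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttNetConfig":
        return cls(
            variant=d["variant"],
            num_classes=d["num_classes"],
            input_size=d["input_size"],
            channels=tuple(d["channels"]),
            strides=tuple(d["strides"]),
            seed=d.get("seed", 0),
        )


@dataclass
class FeatureMaps:
    """H x W x C activations of the last convolutional stage of a model."""

    values: np.ndarray
    source_image_size: tuple[int, int]

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError(f"feature maps must be H x W x C, got {self.values.shape}")
        h, w, _ = self.values.shape
        if h < 1 or w < 1:
            raise ValueError("feature maps must be non-empty")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def num_channels(self) -> int:
        return self.values.shape[2]


def normalize_image(image: np.ndarray) -> np.ndarray:
    """8-bit H x W x 3 RGB -> (3, H, W) float32 in [0, 1]."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {image.shape}")
    arr = np.asarray(image, dtype=np.float32)
    if image.dtype == np.uint8:
        arr = arr / 255.0
    return arr.transpose(2, 0, 1)


class AttNet:
    """Single-level gated-CNN classifier (eight blocks + pooled softmax)."""

    def __init__(self, config: AttNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, j = config.block_kernel, config.final_kernel
        self.blocks: list[GatedBlock] = []
        in_ch = 3
        for i, (out_ch, stride) in enumerate(zip(config.channels, config.strides)):
            self.blocks.append(
                GatedBlock(in_ch, out_ch, k, stride, rng, name=f"block{i + 1}")
            )
            in_ch = out_ch
        self.blocks.append(
            GatedBlock(in_ch, config.num_classes, j, 1, rng, name="block8")
        )
        self._last_grid_shape: tuple[int, int] | None = None

    @property
    def num_classes(self) -> int:
        return self.config.num_classes

    @property
    def input_size(self) -> int:
        return self.config.input_size

    @property
    def params(self) -> list[Parameter]:
        return [p for b in self.blocks for p in b.params]

    def forward_grid(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Final-stage feature grid (N, C#, H', W')."""
        h = x
        for block in self.blocks:
            h = block.forward(h, train)
        self._last_grid_shape = h.shape[2:]
        return h

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return global_avg_pool(self.forward_grid(x, train))

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        g = global_avg_pool_backward(dlogits, self._last_grid_shape)
        for block in reversed(self.blocks):
            g = block.backward(g)

    def stage_shapes(self, x: np.ndarray) -> list[tuple[int, int, int]]:
        """(channels, H, W) of every block output for one forward pass."""
        shapes = []
        h = x
        for block in self.blocks:
            h = block.forward(h, train=False)
            shapes.append((h.shape[1], h.shape[2], h.shape[3]))
        return shapes


class MultiLevelAttNet:
    """Shared 7-block trunk plus per-level gated blocks stacked bottom-up.

    ``level_blocks`` is ordered level 4 -> level 1; each block emits one
    channel per category of its level and feeds the block of the level above.
    """

    def __init__(self, config: AttNetConfig, taxonomy: IngredientTaxonomy):
        counts = taxonomy.counts
        if config.num_classes != counts[3]:
            config = AttNetConfig(**{**config.to_dict(), "num_classes": counts[3]})
        self.config = config
        self.level_counts = counts
        rng = np.random.default_rng(config.seed)
        k, j = config.block_kernel, config.final_kernel
        self.trunk: list[GatedBlock] = []
        in_ch = 3
        for i, (out_ch, stride) in enumerate(zip(config.channels, config.strides)):
            self.trunk.append(
                GatedBlock(in_ch, out_ch, k, stride, rng, name=f"block{i + 1}")
            )
            in_ch = out_ch
        self.level_blocks: list[GatedBlock] = []
        for level, c_l in zip((4, 3, 2, 1), reversed(counts)):
            self.level_blocks.append(
                GatedBlock(in_ch, c_l, j, 1, rng, name=f"level{level}")
            )
            in_ch = c_l
        self._grid_shapes: list[tuple[int, int]] = []

    @property
    def input_size(self) -> int:
        return self.config.input_size

    @property
    def params(self) -> list[Parameter]:
        blocks = self.trunk + self.level_blocks
        return [p for b in blocks for p in b.params]

    def forward_logits(self, x: np.ndarray, train: bool = False) -> dict[int, np.ndarray]:
        """Per-level pooled logits keyed by level (4 is the leaf level)."""
        h = x
        for block in self.trunk:
            h = block.forward(h, train)
        logits: dict[int, np.ndarray] = {}
        self._grid_shapes = []
        for level, block in zip((4, 3, 2, 1), self.level_blocks):
            h = block.forward(h, train)
            self._grid_shapes.append(h.shape[2:])
            logits[level] = global_avg_pool(h)
        return logits

    def backward_from_logits(self, dlogits: dict[int, np.ndarray]) -> None:
        g = None
        for idx in reversed(range(4)):  # level-1 block first
            level = 4 - idx
            block = self.level_blocks[idx]
            head = global_avg_pool_backward(dlogits[level], self._grid_shapes[idx])
            g = head if g is None else head + g
            g = block.backward(g)
        for block in reversed(self.trunk):
            g = block.backward(g)

    def level4_grid(self, x: np.ndarray) -> np.ndarray:
        """Feature grid of the level-4 block (C4 channels), inference mode."""
        h = x
        for block in self.trunk:
            h = block.forward(h, train=False)
        return self.level_blocks[0].forward(h, train=False)


def build_attnet(config: AttNetConfig) -> AttNet:
    """Construct a single-level gated-CNN classifier from its config."""
    return AttNet(config)


def build_multilevel_attnet(
    config: AttNetConfig, taxonomy: IngredientTaxonomy
) -> MultiLevelAttNet:
    """Construct the multi-level model (shared trunk, four stacked heads)."""
    return MultiLevelAttNet(config, taxonomy)


def forward_feature_maps(model, image: np.ndarray) -> FeatureMaps:
    """Run one image through a model and return the last-stage feature grid.

    For a single-level model this is the final block's gated output
    (one channel per leaf class); for the multi-level model it is the
    level-4 block's output, which has the same channel count.
    """
    size = model.input_size
    if image.shape[0] != size or image.shape[1] != size:
        raise ValueError(
            f"expected {size} x {size} input, got {image.shape[0]} x {image.shape[1]}"
        )
    x = normalize_image(image)[None]
    if isinstance(model, MultiLevelAttNet):
        grid = model.level4_grid(x)
    elif isinstance(model, AttNet):
        grid = model.forward_grid(x, train=False)
    elif isinstance(model, BackboneWithHead):
        grid = model.forward_grid(x, train=False)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    values = grid[0].transpose(1, 2, 0).astype(np.float32)
    return FeatureMaps(values=values, source_image_size=image.shape[:2])


class BackboneWithHead:
    """Any spatial feature extractor + 1x1 conv head to C# channels.

    Lets third-party trunks reuse the same segmentation machinery: the head
    replaces their classifier with a 1x1 conv to one channel per class,
    global average pooling and a softmax classification layer.
    """

    def __init__(self, backbone_blocks: list[GatedBlock], num_classes: int,
                 input_size: int = 224, seed: int = 0):
        if not backbone_blocks:
            raise ValueError("backbone must contain at least one block")
        from ingseg.nn.layers import Conv2d

        self.backbone = backbone_blocks
        rng = np.random.default_rng(seed)
        in_ch = backbone_blocks[-1].out_channels
        self.head = Conv2d(in_ch, num_classes, 1, 1, rng, name="head")
        self.num_classes = num_classes
        self.input_size = input_size
        self._last_grid_shape: tuple[int, int] | None = None

    @property
    def params(self) -> list[Parameter]:
        return [p for b in self.backbone for p in b.params] + self.head.params

    def forward_grid(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for block in self.backbone:
            h = block.forward(h, train)
        if h.ndim != 4:
            raise ValueError("backbone output is not a spatial grid")
        h = self.head.forward(h)
        self._last_grid_shape = h.shape[2:]
        return h

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return global_avg_pool(self.forward_grid(x, train))

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        g = global_avg_pool_backward(dlogits, self._last_grid_shape)
        g = self.head.backward(g)
        for block in reversed(self.backbone):
            g = block.backward(g)


def build_backbone_head(
    backbone_blocks: list[GatedBlock], num_classes: int, input_size: int = 224,
    seed: int = 0,
) -> BackboneWithHead:
    return BackboneWithHead(backbone_blocks, num_classes, input_size, seed)


# ---------------------------------------------------------------------------
# checkpoints


def _state_arrays(model) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    blocks = (
        model.trunk + model.level_blocks
        if isinstance(model, MultiLevelAttNet)
        else model.blocks
    )
    for block in blocks:
        for p in block.params:
            state[p.name] = p.value
        state[f"{block.name}.bn.running_mean"] = block.bn.running_mean
        state[f"{block.name}.bn.running_var"] = block.bn.running_var
    return state


def save_checkpoint(model, path: str | Path) -> None:
    """Self-describing checkpoint: config JSON + all weights and BN stats."""
    meta = {
        "kind": "mlm" if isinstance(model, MultiLevelAttNet) else "slm",
        "config": model.config.to_dict(),
    }
    if isinstance(model, MultiLevelAttNet):
        meta["level_counts"] = list(model.level_counts)
    np.savez(
        Path(path),
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **_state_arrays(model),
    )


def load_checkpoint(path: str | Path):
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = AttNetConfig.from_dict(meta["config"])
        if meta["kind"] == "mlm":
            from ingseg.taxonomy import balanced_taxonomy

            model = MultiLevelAttNet(config, balanced_taxonomy(meta["level_counts"]))
            blocks = model.trunk + model.level_blocks
        else:
            model = AttNet(config)
            blocks = model.blocks
        for block in blocks:
            for p in block.params:
                p.value = data[p.name].copy()
            block.bn.running_mean = data[f"{block.name}.bn.running_mean"].copy()
            block.bn.running_var = data[f"{block.name}.bn.running_var"].copy()
    return model
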