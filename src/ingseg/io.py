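"""File formats and the end-to-end pipeline runner.

Conventions: row-major, 0-based pixel coordinates everywhere; label maps are
indexed PNGs with background id 0; masks are 8-bit PNGs with foreground 255.
Every pipeline artifact carries the run's config hash and seed so a run is
reproducible from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from ingseg import taxonomy as taxmod
from ingseg.segmentation import MaskSet

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid or incomplete run configurations."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


# ---------------------------------------------------------------------------
# images, label maps, masks


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def _label_palette(n: int = 256) -> list[int]:
    rng = np.random.default_rng(12345)
    colors = rng.integers(40, 255, size=(n, 3))
    colors[0] = (0, 0, 0)
    return [int(v) for v in colors.ravel()]


def write_label_map(label_map: np.ndarray, path: str | Path) -> None:
    """Write an indexed (palette) PNG whose pixel values are the label ids."""
    arr = np.asarray(label_map)
    if arr.ndim != 2:
        raise ValueError("label map must be 2-D")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("label ids must fit in uint8")
    img = Image.fromarray(arr.astype(np.uint8), mode="P")
    img.putpalette(_label_palette())
    img.save(path)


def read_label_map(path: str | Path) -> tuple[list[np.ndarray], list[int]]:
    """Read an indexed PNG into one binary mask per non-background label.

    Background is label 0 and gets no mask.  RGB images are rejected: label
    maps must be palette ('P') or single-channel ('L') images.
    """
    img = Image.open(path)
    if img.mode not in ("P", "L"):
        raise ValueError(
            f"{path}: not an indexed label map (mode {img.mode!r})"
        )
    arr = np.asarray(img)
    labels = sorted(int(v) for v in np.unique(arr) if v != 0)
    if not labels:
        warnings.warn(f"{path}: label map has no foreground labels", stacklevel=2)
    return [arr == lab for lab in labels], labels


def write_masks(maskset: MaskSet, out_dir: str | Path, prefix: str = "mask",
                extra_meta: dict | None = None) -> list[Path]:
    """Write masks as 0/255 PNGs plus a JSON sidecar with provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mask in enumerate(maskset.masks):
        p = out / f"{prefix}_{i:03d}.png"
        Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(p)
        paths.append(p)
    sidecar = {
        "method": maskset.method,
        "num_masks": len(maskset.masks),
        "provenance": maskset.provenance,
        "files": [p.name for p in paths],
    }
    if extra_meta:
        sidecar.update(extra_meta)
    (out / f"{prefix}s.json").write_text(json.dumps(sidecar, indent=2))
    return paths


def read_masks(mask_dir: str | Path, prefix: str = "mask") -> MaskSet:
    """Read back a directory of 0/255 mask PNGs written by :func:`write_masks`."""
    mask_dir = Path(mask_dir)
    files = sorted(mask_dir.glob(f"{prefix}_*.png"))
    masks = [np.asarray(Image.open(p).convert("L")) >= 128 for p in files]
    method = "unknown"
    sidecar = mask_dir / f"{prefix}s.json"
    if sidecar.exists():
        method = json.loads(sidecar.read_text()).get("method", "unknown")
    return MaskSet(masks=masks, method=method, provenance=[{} for _ in masks])


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    taxonomy_path: str
    out_dir: str
    variant: str = "1"
    input_size: int = 64
    channels: tuple[int, ...] = (8, 16, 16, 32, 32, 64, 64)
    n_classes: int = 8
    variants_per_class: int = 2
    images_per_variant: int = 6
    epochs: int = 30
    batch_size: int = 32
    initial_lr: float = 3e-2
    n_scenes: int = 10
    scene_ks: tuple[int, ...] = (2, 3)
    method: str = "2"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        missing = {"taxonomy_path", "out_dir"} - set(kwargs)
        if missing:
            raise ConfigError(f"config missing required keys: {sorted(missing)}")
        cfg = cls(**kwargs, extra=extra)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not Path(self.taxonomy_path).exists():
            raise ConfigError(f"taxonomy path does not exist: {self.taxonomy_path}")
        for name in ("channels", "scene_ks"):
            setattr(self, name, tuple(getattr(self, name)))

    def config_hash(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """synth -> train (SLM) -> segment -> evaluate, writing every artifact.

    Returns a summary dict with the classification report and the dataset
    segmentation metrics.
    """
    from ingseg.attnet import AttNetConfig, build_attnet, save_checkpoint
    from ingseg.seg_metrics import (
        EvaluationInstance,
        dataset_metrics,
        image_metrics,
    )
    from ingseg.segmentation import Method1Params, Method2Params, segment_image
    from ingseg.synthetic import (
        SceneSpec,
        compose_multi_ingredient_scene,
        default_class_specs,
        generate_dataset,
    )
    from ingseg.training import TrainConfig, evaluate_classification, train_slm

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    (out / "run_config.json").write_text(
        json.dumps({"config": asdict(cfg), "config_hash": chash}, indent=2,
                   default=str)
    )

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    tax = stage("taxonomy")(taxmod.load_taxonomy, cfg.taxonomy_path)
    if tax.num_leaves < cfg.n_classes:
        raise ConfigError(
            f"taxonomy has {tax.num_leaves} leaves but config asks for "
            f"{cfg.n_classes} classes"
        )

    # synth
    specs = default_class_specs(
        cfg.n_classes, cfg.variants_per_class, cfg.images_per_variant,
        seed=cfg.seed,
    )
    ds = stage("synth")(generate_dataset, specs, tax, split_seed=cfg.seed,
                        image_seed=cfg.seed, size=cfg.input_size)
    ds.manifest.to_csv(out / "manifest.csv", index=False)

    # train
    model = build_attnet(
        AttNetConfig(variant=cfg.variant, num_classes=cfg.n_classes,
                     input_size=cfg.input_size, channels=cfg.channels,
                     seed=cfg.seed)
    )
    tcfg = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                       initial_lr=cfg.initial_lr, seed=cfg.seed)
    result = stage("train")(
        train_slm, model, ds.images[ds.train_idx], ds.leaf_labels[ds.train_idx],
        tcfg,
    )
    pd.DataFrame(
        {"epoch": range(1, len(result.loss_history) + 1),
         "loss": result.loss_history, "lr": result.lr_history}
    ).to_csv(out / "loss_history.csv", index=False)
    save_checkpoint(model, out / "model.npz")
    report = stage("evaluate-classification")(
        evaluate_classification, model, ds.images[ds.test_idx],
        ds.leaf_labels[ds.test_idx],
    )

    # segment + evaluate scenes
    rng = np.random.default_rng(cfg.seed)
    records = []
    scene_dir = out / "scenes"
    scene_dir.mkdir(exist_ok=True)
    for s in range(cfg.n_scenes):
        k = int(cfg.scene_ks[s % len(cfg.scene_ks)])
        class_ids = tuple(int(c) for c in rng.choice(cfg.n_classes, size=k,
                                                     replace=False))
        scene = stage("synth-scene")(
            compose_multi_ingredient_scene,
            SceneSpec(k=k, class_ids=class_ids, size=cfg.input_size,
                      seed=cfg.seed * 1000 + s),
            specs,
        )
        write_image(scene.blue_image, scene_dir / f"scene_{s:03d}.png")
        write_label_map(scene.label_map, scene_dir / f"scene_{s:03d}_gt.png")
        if cfg.method == "2":
            params = Method2Params(k=k, background_present=True,
                                   seed=cfg.seed)
        else:
            params = Method1Params()
        masks, _segments = stage("segment")(
            segment_image, model, scene.blue_image, cfg.method, params
        )
        write_masks(masks, scene_dir / f"scene_{s:03d}_masks",
                    extra_meta={"config_hash": chash, "seed": cfg.seed})
        gts = [scene.label_map == r for r in range(1, k + 1)]
        nonempty = [m for m in masks.masks if m.any()]
        records.append(image_metrics(EvaluationInstance(gts=gts,
                                                        segments=nonempty)))
    seg_report = dataset_metrics(records)
    rows = [
        {"image": f"scene_{i:03d}", "mPurity": r.m_purity,
         "mEntirety": r.m_entirety, "mLoGTs": r.logts, "mIoU": r.m_iou,
         "mDice": r.m_dice}
        for i, r in enumerate(records)
    ]
    rows.append({"image": "DATASET", **seg_report.as_dict()})
    pd.DataFrame(rows).to_csv(out / "segmentation_report.csv", index=False)

    summary = {
        "config_hash": chash,
        "seed": cfg.seed,
        "classification": {
            "accuracy": report.accuracy,
            "macro_precision": report.macro_precision,
            "macro_recall": report.macro_recall,
            "macro_f1": report.macro_f1,
        },
        "segmentation": seg_report.as_dict(),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
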