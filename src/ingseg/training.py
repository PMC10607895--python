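"""Single-level (SLM) and multi-level (MLM) training plus classification scoring.

SLM optimizes plain cross-entropy on leaf (level-4) labels.  MLM optimizes a
weighted sum of per-level cross-entropies; weights descend from the leaf
level upward (default 1.0, 0.5, 0.3, 0.1 for levels 4..1) so the many-class
bottom task dominates.  Both use an Adam-type optimizer with squared-gradient
decay 0.9 and a piecewise learning-rate schedule (factor 0.2 drops).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ingseg.attnet import AttNet, MultiLevelAttNet, normalize_image
from ingseg.nn import Adam, softmax_cross_entropy
from ingseg.taxonomy import HierarchicalLabel


class TrainingDivergedError(RuntimeError):
    """Raised when a batch loss becomes non-finite."""


@dataclass(frozen=True)
class LevelWeights:
    """Per-level loss weights; index 1..4 by taxonomy level."""

    l4: float = 1.0
    l3: float = 0.5
    l2: float = 0.3
    l1: float = 0.1

    def __post_init__(self):
        vals = (self.l4, self.l3, self.l2, self.l1)
        if any(v < 0 for v in vals):
            raise ValueError("level weights must be non-negative")
        if self.l4 <= 0:
            raise ValueError("the leaf-level weight must be positive")
        if not (self.l4 >= self.l3 >= self.l2 >= self.l1):
            raise ValueError("weights must descend from level 4 to level 1")

    def at_level(self, level: int) -> float:
        return {4: self.l4, 3: self.l3, 2: self.l2, 1: self.l1}[level]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    initial_lr: float = 3e-2
    lr_drop_factor: float = 0.2
    lr_drop_period: int = 10  # schedule period unstated upstream; overridable
    grad_decay: float = 0.9
    squared_grad_decay: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.lr_drop_period) <= 0:
            raise ValueError("epochs, batch_size and lr_drop_period must be positive")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0 < self.lr_drop_factor < 1:
            raise ValueError("lr_drop_factor must lie in (0, 1)")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate used during 0-based epoch ``epoch``."""
        return self.initial_lr * self.lr_drop_factor ** (epoch // self.lr_drop_period)


@dataclass
class TrainResult:
    model: object
    loss_history: list[float]
    per_level_history: dict[int, list[float]] | None = None
    lr_history: list[float] = field(default_factory=list)


@dataclass
class ClassificationReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict[int, dict[str, float]]


def multilevel_loss(
    per_level_outputs: dict[int, np.ndarray] | list[np.ndarray],
    label: HierarchicalLabel,
    weights: LevelWeights = LevelWeights(),
) -> float:
    """Weighted sum over levels of cross-entropy of softmax(z_l) at y_l.

    ``per_level_outputs`` maps level -> pooled score vector z_l (or is a list
    ordered level 1..4).
    """
    if isinstance(per_level_outputs, dict):
        z = {lvl: np.asarray(per_level_outputs[lvl], dtype=np.float64)
             for lvl in (1, 2, 3, 4)}
    else:
        if len(per_level_outputs) != 4:
            raise ValueError("need one score vector per level")
        z = {lvl: np.asarray(v, dtype=np.float64)
             for lvl, v in zip((1, 2, 3, 4), per_level_outputs)}
    total = 0.0
    for level in (1, 2, 3, 4):
        zl = z[level]
        if zl.ndim != 1:
            raise ValueError(f"level-{level} scores must be a vector")
        y = label.at_level(level)
        if not 0 <= y < zl.size:
            raise ValueError(f"level-{level} label {y} out of range [0, {zl.size})")
        ce, _ = softmax_cross_entropy(zl[None, :], np.array([y]))
        total += weights.at_level(level) * ce
    return total


def _prepare_images(images: np.ndarray) -> np.ndarray:
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValueError(f"expected (N, H, W, 3) images, got {images.shape}")
    return np.stack([normalize_image(img) for img in images])


def _epoch_batches(
    n: int, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def train_slm(
    model: AttNet, images: np.ndarray, labels: np.ndarray, cfg: TrainConfig
) -> TrainResult:
    """Train a single-level model on leaf labels with pooled softmax CE."""
    if len(images) == 0:
        raise ValueError("empty training set")
    labels = np.asarray(labels)
    if labels.shape != (len(images),):
        raise ValueError("labels must be one integer per image")
    x_all = _prepare_images(images)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.initial_lr, grad_decay=cfg.grad_decay,
               squared_grad_decay=cfg.squared_grad_decay)
    history: list[float] = []
    lrs: list[float] = []
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at_epoch(epoch)
        lrs.append(opt.lr)
        batch_losses = []
        for idx in _epoch_batches(len(x_all), cfg.batch_size, rng):
            opt.zero_grad()
            logits = model.forward_logits(x_all[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, lr {opt.lr:g}, "
                    f"batch of {len(idx)}"
                )
            model.backward_from_logits(dlogits)
            opt.step()
            batch_losses.append(loss)
        history.append(float(np.mean(batch_losses)))
    return TrainResult(model=model, loss_history=history, lr_history=lrs)


def train_mlm(
    model: MultiLevelAttNet,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    weights: LevelWeights = LevelWeights(),
) -> TrainResult:
    """Train the multi-level model on (y1..y4) label rows.

    ``labels`` is (N, 4) with columns ordered level 1..4.  The logged total
    is the weighted sum; per-level histories log the unweighted CE terms.
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    labels = np.asarray(labels)
    if labels.shape != (len(images), 4):
        raise ValueError("labels must be (N, 4) level-1..4 id rows")
    x_all = _prepare_images(images)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.initial_lr, grad_decay=cfg.grad_decay,
               squared_grad_decay=cfg.squared_grad_decay)
    history: list[float] = []
    per_level: dict[int, list[float]] = {1: [], 2: [], 3: [], 4: []}
    lrs: list[float] = []
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at_epoch(epoch)
        lrs.append(opt.lr)
        totals = []
        level_sums = {lvl: [] for lvl in (1, 2, 3, 4)}
        for idx in _epoch_batches(len(x_all), cfg.batch_size, rng):
            opt.zero_grad()
            logits = model.forward_logits(x_all[idx], train=True)
            total = 0.0
            dlogits: dict[int, np.ndarray] = {}
            for level in (1, 2, 3, 4):
                ce, dz = softmax_cross_entropy(
                    logits[level], labels[idx, level - 1]
                )
                lam = weights.at_level(level)
                total += lam * ce
                dlogits[level] = lam * dz
                level_sums[level].append(ce)
            if not np.isfinite(total):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, lr {opt.lr:g}"
                )
            model.backward_from_logits(dlogits)
            opt.step()
            totals.append(total)
        history.append(float(np.mean(totals)))
        for level in (1, 2, 3, 4):
            per_level[level].append(float(np.mean(level_sums[level])))
    return TrainResult(
        model=model, loss_history=history, per_level_history=per_level,
        lr_history=lrs,
    )


def predict_labels(model, images: np.ndarray, batch_size: int = 32,
                   level: int = 4) -> np.ndarray:
    """Arg-max class predictions in inference mode (frozen BN statistics)."""
    x_all = _prepare_images(images)
    preds = []
    for i in range(0, len(x_all), batch_size):
        logits = model.forward_logits(x_all[i : i + batch_size], train=False)
        if isinstance(logits, dict):
            logits = logits[level]
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def classification_report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ClassificationReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    accuracy = float(np.mean(y_true == y_pred))
    per_class: dict[int, dict[str, float]] = {}
    precisions, recalls, f1s = [], [], []
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[int(c)] = {"precision": prec, "recall": rec, "f1": f1,
                             "support": float(np.sum(y_true == c))}
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return ClassificationReport(
        accuracy=accuracy,
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
        per_class=per_class,
    )


def evaluate_classification(
    model, images: np.ndarray, labels: np.ndarray, level: int = 4
) -> ClassificationReport:
    """Accuracy plus macro precision/recall/F1 over classes present in labels."""
    if len(images) == 0:
        raise ValueError("empty test set")
    preds = predict_labels(model, images, level=level)
    return classification_report_from_predictions(np.asarray(labels), preds)


def split_80_20(
    labels: np.ndarray, seed: int, stratify: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Seed-stable 80/20 index split; train size is exactly floor(0.8 n).

    With stratification each class contributes floor(0.8 n_c) or one more,
    extra slots going to the classes with the largest fractional remainders.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(0.8 * n))
    if not stratify:
        order = rng.permutation(n)
        return np.sort(order[:n_train]), np.sort(order[n_train:])
    classes = np.unique(labels)
    base, remainders, shuffled = {}, {}, {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 images; cannot stratify")
        shuffled[c] = rng.permutation(idx)
        base[c] = int(np.floor(0.8 * len(idx)))
        remainders[c] = 0.8 * len(idx) - base[c]
    extra = n_train - sum(base.values())
    # largest-remainder allocation keeps the global 80% exact
    by_remainder = sorted(classes, key=lambda c: (-remainders[c], c))
    takes = dict(base)
    for c in by_remainder[:extra]:
        takes[c] += 1
    train_idx = np.concatenate([shuffled[c][: takes[c]] for c in classes])
    test_idx = np.concatenate([shuffled[c][takes[c] :] for c in classes])
    return np.sort(train_idx), np.sort(test_idx)
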