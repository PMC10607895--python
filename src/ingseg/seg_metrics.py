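"""Recognition-oriented segmentation metrics.

All five metrics are set-counting ratios on binary masks: IoU, Dice, Purity
(|A∩B|/|B|, the fraction of a segment lying inside a ground-truth region),
Entirety (|A∩B|/|A|, the fraction of a region covered by a segment) and
LoGTs (the fraction of the ground-truth foreground union missed by every
segment).  Per-image aggregation takes, for each segment, its best purity
over ground-truth regions (averaged into mPurity) and, for each region, its
best entirety / IoU / Dice over segments (averaged into mEntirety, mIoU,
mDice).  Dataset values are unweighted means over images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class EmptyMaskError(ValueError):
    """Raised when a metric's denominator mask set is empty."""


@dataclass
class EvaluationInstance:
    """Ground-truth region masks A_i versus predicted segment masks B_j."""

    gts: list[np.ndarray]
    segments: list[np.ndarray]

    def __post_init__(self):
        if not self.gts:
            raise ValueError("need at least one ground-truth mask")
        shape = self.gts[0].shape
        for m in [*self.gts, *self.segments]:
            if m.shape != shape:
                raise ValueError("all masks must share one shape")
            if m.dtype != bool:
                raise ValueError("masks must be boolean")


@dataclass
class ImageMetrics:
    m_purity: float
    m_entirety: float
    logts: float
    m_iou: float
    m_dice: float
    num_gts: int
    num_segments: int


@dataclass
class MetricsReport:
    per_image: list[ImageMetrics]
    m_purity: float = field(init=False)
    m_entirety: float = field(init=False)
    m_logts: float = field(init=False)
    m_iou: float = field(init=False)
    m_dice: float = field(init=False)

    def __post_init__(self):
        if not self.per_image:
            raise ValueError("need at least one per-image record")

        def mean_of(attr: str) -> float:
            vals = [getattr(r, attr) for r in self.per_image]
            finite = [v for v in vals if not math.isnan(v)]
            return float(np.mean(finite)) if finite else float("nan")

        self.m_purity = mean_of("m_purity")
        self.m_entirety = mean_of("m_entirety")
        self.m_logts = mean_of("logts")
        self.m_iou = mean_of("m_iou")
        self.m_dice = mean_of("m_dice")

    def as_dict(self) -> dict[str, float]:
        return {
            "mPurity": self.m_purity,
            "mEntirety": self.m_entirety,
            "mLoGTs": self.m_logts,
            "mIoU": self.m_iou,
            "mDice": self.m_dice,
        }


def _counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    return inter, int(np.count_nonzero(a)), int(np.count_nonzero(b))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    inter, na, nb = _counts(a, b)
    union = na + nb - inter
    if union == 0:
        raise EmptyMaskError("IoU undefined: both masks are empty")
    return inter / union


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter, na, nb = _counts(a, b)
    if na + nb == 0:
        raise EmptyMaskError("Dice undefined: both masks are empty")
    return 2 * inter / (na + nb)


def purity(a: np.ndarray, b: np.ndarray) -> float:
    inter, _, nb = _counts(a, b)
    if nb == 0:
        raise EmptyMaskError("purity undefined: segment mask is empty")
    return inter / nb


def entirety(a: np.ndarray, b: np.ndarray) -> float:
    inter, na, _ = _counts(a, b)
    if na == 0:
        raise EmptyMaskError("entirety undefined: ground-truth mask is empty")
    return inter / na


def logts(gts: list[np.ndarray], segments: list[np.ndarray]) -> float:
    """Fraction of the ground-truth foreground union left uncovered."""
    union_a = np.zeros(gts[0].shape, dtype=bool)
    for a in gts:
        union_a |= a
    na = int(np.count_nonzero(union_a))
    if na == 0:
        raise EmptyMaskError("LoGTs undefined: ground-truth union is empty")
    union_b = np.zeros_like(union_a)
    for b in segments:
        union_b |= b
    covered = int(np.count_nonzero(union_a & union_b))
    return (na - covered) / na


def image_metrics(inst: EvaluationInstance) -> ImageMetrics:
    """Per-image aggregation; with no segments mPurity is NaN-flagged,
    mEntirety/mIoU/mDice are 0 and LoGTs is 1."""
    gts, segs = inst.gts, inst.segments
    if not segs:
        return ImageMetrics(
            m_purity=float("nan"), m_entirety=0.0, logts=1.0, m_iou=0.0,
            m_dice=0.0, num_gts=len(gts), num_segments=0,
        )
    m_purity = float(np.mean([
        max(purity(a, b) for a in gts) for b in segs
    ]))
    m_entirety = float(np.mean([
        max(entirety(a, b) for b in segs) for a in gts
    ]))
    m_iou = float(np.mean([max(iou(a, b) for b in segs) for a in gts]))
    m_dice = float(np.mean([max(dice(a, b) for b in segs) for a in gts]))
    return ImageMetrics(
        m_purity=m_purity,
        m_entirety=m_entirety,
        logts=logts(gts, segs),
        m_iou=m_iou,
        m_dice=m_dice,
        num_gts=len(gts),
        num_segments=len(segs),
    )


def dataset_metrics(records: list[ImageMetrics]) -> MetricsReport:
    """Unweighted means over images (NaN-flagged values are skipped)."""
    return MetricsReport(per_image=list(records))
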