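"""Detector front- and back-end contracts: geometry, normalization, NMS.

The detector itself (a real-time one-stage network) is an upstream
producer; this module pins down the contracts around it so any detector's
raw output can flow through the pipeline:

- the letterbox geometry used at inference time — aspect-preserving resize
  into a 960 x 544 canvas with zero padding confined to the right and
  bottom margins, so box coordinates map back by a single scale factor;
- the per-channel RGB standardization constants;
- confidence filtering (a prediction is valid only if its score *exceeds*
  the threshold, 0.2 by default);
- classic greedy non-maximum suppression at IoU 0.3, applied independently
  per class so suppression never crosses classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from .evaluation import iou
from .records import DetectionRecord, ValidationError


@dataclass(frozen=True)
class PreprocessConfig:
    """Inference-time input geometry and RGB standardization constants."""

    target_width: int = 960
    target_height: int = 544
    channel_means: Tuple[float, float, float] = (123.675, 116.28, 103.53)
    channel_stds: Tuple[float, float, float] = (58.395, 57.12, 57.375)

    def __post_init__(self) -> None:
        if self.target_width <= 0 or self.target_height <= 0:
            raise ValidationError("target dimensions must be positive")
        if any(s <= 0 for s in self.channel_stds):
            raise ValidationError("channel stds must be strictly positive")


@dataclass(frozen=True)
class PostprocessConfig:
    """Detector output filtering thresholds."""

    confidence_threshold: float = 0.2
    nms_iou_threshold: float = 0.3

    def __post_init__(self) -> None:
        for name in ("confidence_threshold", "nms_iou_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def letterbox_geometry(
    src_width: int, src_height: int, cfg: PreprocessConfig = PreprocessConfig()
) -> Tuple[float, int, int, int, int]:
    """Aspect-preserving resize geometry into the target canvas.

    Returns ``(scale, scaled_width, scaled_height, pad_right, pad_bottom)``
    with ``scale = min(target_w/src_w, target_h/src_h)``, scaled dimensions
    rounded half-away-from-zero (clamped to the target), and zero padding
    on the right/bottom margins only, so that scaled + pad equals the
    target on each axis.
    """
    if src_width <= 0 or src_height <= 0:
        raise ValidationError("source dimensions must be positive")
    scale = min(cfg.target_width / src_width, cfg.target_height / src_height)
    scaled_w = min(cfg.target_width, _round_half_away(src_width * scale))
    scaled_h = min(cfg.target_height, _round_half_away(src_height * scale))
    return (
        scale,
        scaled_w,
        scaled_h,
        cfg.target_width - scaled_w,
        cfg.target_height - scaled_h,
    )


def normalize_pixel(
    rgb: Sequence[float], cfg: PreprocessConfig = PreprocessConfig()
) -> Tuple[float, float, float]:
    """Standardize one RGB pixel: ``(value - mean) / std`` per channel."""
    r, g, b = rgb
    return tuple(
        (v - m) / s for v, m, s in zip((r, g, b), cfg.channel_means, cfg.channel_stds)
    )


def denormalize_pixel(
    rgb: Sequence[float], cfg: PreprocessConfig = PreprocessConfig()
) -> Tuple[float, float, float]:
    """Inverse of :func:`normalize_pixel`."""
    r, g, b = rgb
    return tuple(
        v * s + m for v, m, s in zip((r, g, b), cfg.channel_means, cfg.channel_stds)
    )


def filter_by_confidence(
    dets: Iterable[DetectionRecord], cfg: PostprocessConfig = PostprocessConfig()
) -> List[DetectionRecord]:
    """Keep detections whose confidence strictly exceeds the threshold."""
    return [d for d in dets if d.confidence > cfg.confidence_threshold]


def _nms_sort_key(d: DetectionRecord):
    # deterministic: confidence desc, then class, then box corners
    return (
        -d.confidence,
        d.class_id,
        d.box.x_min,
        d.box.y_min,
        d.box.x_max,
        d.box.y_max,
    )


def nms(
    dets: Sequence[DetectionRecord], cfg: PostprocessConfig = PostprocessConfig()
) -> List[DetectionRecord]:
    """Greedy per-class non-maximum suppression within one frame.

    Repeatedly keeps the highest-confidence remaining box and discards
    same-class boxes overlapping it with IoU above the threshold.
    Suppression never crosses classes: duplicated predictions of
    *different* classes at one location are a distinct detector failure
    mode that evaluation must still see. Output is sorted by descending
    confidence; ties break by class id then box coordinates, so the result
    is deterministic.
    """
    dets = list(dets)
    if len({(d.video_id, d.frame_index) for d in dets}) > 1:
        raise ValidationError("nms operates on a single frame's detections")
    kept: List[DetectionRecord] = []
    remaining = sorted(dets, key=_nms_sort_key)
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            d
            for d in remaining
            if d.class_id != best.class_id or iou(d.box, best.box) <= cfg.nms_iou_threshold
        ]
    return kept


def postprocess_frame(
    dets: Sequence[DetectionRecord], cfg: PostprocessConfig = PostprocessConfig()
) -> List[DetectionRecord]:
    """Confidence filter then per-class NMS for one frame."""
    return nms(filter_by_confidence(dets, cfg), cfg)


def postprocess_detections(
    dets: Iterable[DetectionRecord], cfg: PostprocessConfig = PostprocessConfig()
) -> List[DetectionRecord]:
    """Confidence filter then per-class NMS, applied frame by frame."""
    by_frame = {}
    for d in dets:
        by_frame.setdefault((d.video_id, d.frame_index), []).append(d)
    out: List[DetectionRecord] = []
    for key in sorted(by_frame):
        out.extend(postprocess_frame(by_frame[key], cfg))
    return out
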