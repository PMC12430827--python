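"""IoU-matched detection metrics: precision, sensitivity, F1.

A detection is a true positive when it can be matched one-to-one to a
same-class ground-truth box with IoU strictly greater than the matching
threshold (0.3 by default). Matching is greedy in descending confidence
order, per class, which is the standard detection-evaluation convention;
cross-class overlap never matches, so a correctly located but wrongly
classified prediction costs one FN (for the true class) *and* one FP (for
the predicted class).

Counts are accumulated dataset-wide per class before the metric formulas
are applied:

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Two macro aggregations are deliberately kept distinct, because summary
tables in this field mix them: the harmonic F1 of the macro-averaged
precision and sensitivity (``macro_f1_of_means``), and the plain mean of
the per-class F1 values (``macro_mean_f1``). ``macro_precision`` — the
unweighted mean of per-class precisions — is what detection reports in
this field often label "mAP"; it is *not* a PR-curve area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .records import (
    BoundingBox,
    DetectionRecord,
    GroundTruthRecord,
    ValidationError,
)


@dataclass(frozen=True)
class EvalConfig:
    """Matching threshold: IoU must strictly exceed it for a TP."""

    match_iou_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.match_iou_threshold <= 1.0:
            raise ValidationError("match_iou_threshold must lie in (0, 1]")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclass
class MatchOutcome:
    """Per-class TP/FP/FN tallies plus the matched (detection, GT) pairs."""

    tp: Dict[int, int] = field(default_factory=dict)
    fp: Dict[int, int] = field(default_factory=dict)
    fn: Dict[int, int] = field(default_factory=dict)
    matches: List[Tuple[DetectionRecord, GroundTruthRecord]] = field(
        default_factory=list
    )

    @property
    def classes(self) -> List[int]:
        return sorted(set(self.tp) | set(self.fp) | set(self.fn))

    def counts(self, class_id: int) -> Tuple[int, int, int]:
        return (
            self.tp.get(class_id, 0),
            self.fp.get(class_id, 0),
            self.fn.get(class_id, 0),
        )

    def merge(self, other: "MatchOutcome") -> "MatchOutcome":
        """Accumulate another outcome's tallies into this one (in place)."""
        for src, dst in ((other.tp, self.tp), (other.fp, self.fp), (other.fn, self.fn)):
            for cid, n in src.items():
                dst[cid] = dst.get(cid, 0) + n
        self.matches.extend(other.matches)
        return self

    def _bump(self, table: Dict[int, int], class_id: int, n: int = 1) -> None:
        table[class_id] = table.get(class_id, 0) + n


def match_frame(
    dets: Sequence[DetectionRecord],
    gts: Sequence[GroundTruthRecord],
    cfg: EvalConfig = EvalConfig(),
) -> MatchOutcome:
    """Match one frame's detections to its ground truth, per class.

    Within each class, detections are taken in descending confidence order
    and each is matched greedily to the unmatched same-class ground truth
    with the highest IoU; the match is accepted iff IoU strictly exceeds
    the threshold. Matched detections are TPs, unmatched detections FPs,
    unmatched ground truths FNs. The matching is one-to-one.
    """
    frames = {(r.video_id, r.frame_index) for r in dets} | {
        (r.video_id, r.frame_index) for r in gts
    }
    if len(frames) > 1:
        raise ValidationError("match_frame operates on a single frame's records")

    outcome = MatchOutcome()
    class_ids = sorted({d.class_id for d in dets} | {g.class_id for g in gts})
    for cid in class_ids:
        cls_dets = sorted(
            (d for d in dets if d.class_id == cid), key=lambda d: -d.confidence
        )
        cls_gts = [g for g in gts if g.class_id == cid]
        unmatched = list(range(len(cls_gts)))
        for det in cls_dets:
            best_j, best_iou = None, 0.0
            for j in unmatched:
                v = iou(det.box, cls_gts[j].box)
                if v > best_iou:
                    best_j, best_iou = j, v
            if best_j is not None and best_iou > cfg.match_iou_threshold:
                unmatched.remove(best_j)
                outcome._bump(outcome.tp, cid)
                outcome.matches.append((det, cls_gts[best_j]))
            else:
                outcome._bump(outcome.fp, cid)
        if unmatched:
            outcome._bump(outcome.fn, cid, len(unmatched))
        for table in (outcome.tp, outcome.fp, outcome.fn):
            table.setdefault(cid, 0)
    return outcome


def evaluate_detections(
    dets: Iterable[DetectionRecord],
    gts: Iterable[GroundTruthRecord],
    cfg: EvalConfig = EvalConfig(),
) -> MatchOutcome:
    """Match every frame of a dataset and accumulate the tallies."""
    by_frame_d: Dict[Tuple[str, int], List[DetectionRecord]] = {}
    by_frame_g: Dict[Tuple[str, int], List[GroundTruthRecord]] = {}
    for d in dets:
        by_frame_d.setdefault((d.video_id, d.frame_index), []).append(d)
    for g in gts:
        by_frame_g.setdefault((g.video_id, g.frame_index), []).append(g)
    total = MatchOutcome()
    for key in sorted(set(by_frame_d) | set(by_frame_g)):
        total.merge(match_frame(by_frame_d.get(key, []), by_frame_g.get(key, []), cfg))
    return total


@dataclass(frozen=True)
class ClassMetrics:
    """Precision/sensitivity/F1 of one class, as fractions in [0, 1].

    A metric whose denominator is zero (no detections, or no ground truth,
    for the class in the evaluated set) is ``None`` — undefined, not zero —
    and the class is excluded from macro averages of that metric.
    """

    class_id: int
    precision: Optional[float]
    sensitivity: Optional[float]
    f1: Optional[float]

    @property
    def defined(self) -> bool:
        return self.precision is not None and self.sensitivity is not None


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (scale-invariant)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def class_metrics(outcome: MatchOutcome) -> List[ClassMetrics]:
    """Apply the metric formulas to a dataset-accumulated outcome."""
    out: List[ClassMetrics] = []
    for cid in outcome.classes:
        tp, fp, fn = outcome.counts(cid)
        precision = tp / (tp + fp) if tp + fp > 0 else None
        sensitivity = tp / (tp + fn) if tp + fn > 0 else None
        if precision is not None and sensitivity is not None:
            f1 = f1_score(precision, sensitivity)
        else:
            f1 = None
        out.append(ClassMetrics(cid, precision, sensitivity, f1))
    return out


@dataclass(frozen=True)
class MetricsReport:
    """Per-class metrics plus both macro aggregation conventions."""

    per_class: Tuple[ClassMetrics, ...]
    macro_precision: float  # unweighted mean of per-class precisions ("mAP")
    macro_sensitivity: float
    macro_f1_of_means: float  # harmonic F1 of the two macro means
    macro_mean_f1: float  # unweighted mean of per-class F1
    n_classes_defined: int


def aggregate(per_class: Sequence[ClassMetrics]) -> MetricsReport:
    """Macro-average the defined classes and populate both F1 conventions."""
    precisions = [m.precision for m in per_class if m.precision is not None]
    sensitivities = [m.sensitivity for m in per_class if m.sensitivity is not None]
    f1s = [m.f1 for m in per_class if m.f1 is not None]
    if not precisions or not sensitivities:
        raise ValidationError("no class has defined metrics to aggregate")
    macro_p = sum(precisions) / len(precisions)
    macro_s = sum(sensitivities) / len(sensitivities)
    return MetricsReport(
        per_class=tuple(per_class),
        macro_precision=macro_p,
        macro_sensitivity=macro_s,
        macro_f1_of_means=f1_score(macro_p, macro_s),
        macro_mean_f1=sum(f1s) / len(f1s),
        n_classes_defined=sum(1 for m in per_class if m.defined),
    )


def evaluate_and_report(
    dets: Iterable[DetectionRecord],
    gts: Iterable[GroundTruthRecord],
    cfg: EvalConfig = EvalConfig(),
) -> MetricsReport:
    """Convenience: match a dataset, apply formulas, aggregate."""
    return aggregate(class_metrics(evaluate_detections(dets, gts, cfg)))
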