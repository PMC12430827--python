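"""Synthetic ground truth, detector errors, and skill-conditioned sessions.

No public dataset accompanies the pipeline's original use case, so this
module provides a fully parameterized test bed with known truth:

- smooth random-walk ground-truth boxes per instrument class;
- a detector error model covering the failure modes seen in practice —
  missed detections, spurious boxes, class confusion, localization jitter —
  with Beta-distributed confidence scores so threshold sweeps are
  meaningful;
- two-instrument suturing sessions whose per-stitch path length, moving
  time and velocity are controlled per skill group, with the proficient
  group configured shorter/faster (the direction reported for real
  suturing) so group comparisons have a known answer.

Every generator is deterministic given its seed. Errors are independent
per box and frame (no temporal correlation) — the simplest model that
exercises every downstream branch; see the methods note for what this
does and does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .kinematics import StitchWindow
from .records import (
    DEFAULT_LABELS,
    BoundingBox,
    DetectionRecord,
    GroundTruthRecord,
    ValidationError,
)
from .skill import (
    NON_PROFICIENT,
    PROFICIENT,
    GoalsSheet,
    ProficiencyLabel,
    label_proficiency,
)


@dataclass(frozen=True)
class DetectorErrorModel:
    """Independent per-box/per-frame detector error model.

    miss_rate
        Probability a ground-truth box is not detected; a scalar or a
        per-class mapping.
    false_positive_rate
        Expected spurious boxes per frame (Poisson), uniform in position
        with sizes resampled from the ground-truth size range.
    confusion
        Optional row-stochastic class-relabeling map
        ``{true_class: {emitted_class: prob}}``; classes absent from the
        map keep their label.
    localization_jitter_sd
        Gaussian sd (pixels) added to each box corner independently.
    tp_confidence, fp_confidence
        Beta(a, b) parameters for matched and spurious confidences. The
        defaults, Beta(8, 2) and Beta(2, 4), put most true detections well
        above and many spurious ones below a 0.2 confidence threshold.
    """

    miss_rate: Union[float, Mapping[int, float]] = 0.0
    false_positive_rate: float = 0.0
    confusion: Optional[Mapping[int, Mapping[int, float]]] = None
    localization_jitter_sd: float = 0.0
    tp_confidence: Tuple[float, float] = (8.0, 2.0)
    fp_confidence: Tuple[float, float] = (2.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            [self.miss_rate]
            if isinstance(self.miss_rate, (int, float))
            else list(self.miss_rate.values())
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValidationError("miss_rate values must lie in [0, 1]")
        if self.false_positive_rate < 0 or self.localization_jitter_sd < 0:
            raise ValidationError("rates and jitter must be non-negative")
        if self.confusion is not None:
            for cid, row in self.confusion.items():
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValidationError(f"confusion row for class {cid} must sum to 1")

    def miss_rate_for(self, class_id: int) -> float:
        if isinstance(self.miss_rate, (int, float)):
            return float(self.miss_rate)
        return float(self.miss_rate.get(class_id, 0.0))


def simulate_ground_truth(
    n_frames: int,
    classes: Sequence[int],
    box_size_range: Tuple[float, float] = (40.0, 120.0),
    image_dims: Tuple[int, int] = (960, 544),
    seed: int = 0,
    video_id: str = "sim",
) -> List[GroundTruthRecord]:
    """One smoothly moving box per class per frame, inside the image."""
    if n_frames <= 0 or not classes:
        raise ValidationError("n_frames and classes must be non-empty/positive")
    w_img, h_img = image_dims
    lo, hi = box_size_range
    if hi >= min(w_img, h_img):
        raise ValidationError("box size range exceeds the image dimensions")
    rng = np.random.default_rng(seed)
    records: List[GroundTruthRecord] = []
    for cid in classes:
        bw = float(rng.uniform(lo, hi))
        bh = float(rng.uniform(lo, hi))
        # EMA-smoothed velocity random walk of the box center
        cx = rng.uniform(bw / 2, w_img - bw / 2)
        cy = rng.uniform(bh / 2, h_img - bh / 2)
        vx = vy = 0.0
        for frame in range(n_frames):
            vx = 0.8 * vx + rng.normal(0, 3.0)
            vy = 0.8 * vy + rng.normal(0, 3.0)
            cx = float(np.clip(cx + vx, bw / 2, w_img - bw / 2))
            cy = float(np.clip(cy + vy, bh / 2, h_img - bh / 2))
            records.append(
                GroundTruthRecord(
                    video_id,
                    frame,
                    cid,
                    BoundingBox(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2),
                )
            )
    return records


def _jitter_box(box: BoundingBox, sd: float, rng: np.random.Generator) -> BoundingBox:
    if sd == 0:
        return box
    x0, y0, x1, y1 = (
        box.x_min + rng.normal(0, sd),
        box.y_min + rng.normal(0, sd),
        box.x_max + rng.normal(0, sd),
        box.y_max + rng.normal(0, sd),
    )
    # jitter must not produce a degenerate box
    if x1 <= x0:
        x0, x1 = min(x0, x1), min(x0, x1) + max(box.width * 0.1, 1.0)
    if y1 <= y0:
        y0, y1 = min(y0, y1), min(y0, y1) + max(box.height * 0.1, 1.0)
    return BoundingBox(x0, y0, x1, y1)


def simulate_detector(
    gt: Sequence[GroundTruthRecord],
    model: DetectorErrorModel,
    image_dims: Tuple[int, int] = (960, 544),
) -> List[DetectionRecord]:
    """Corrupt ground truth into detector output under the error model.

    Each ground-truth box is independently dropped with its class's miss
    rate; survivors get jittered corners, a possibly confused class label
    and a TP-distributed confidence. Each frame then receives
    ``Poisson(false_positive_rate)`` spurious boxes, uniform in position,
    with sizes drawn from the range of ground-truth sizes and
    FP-distributed confidences.
    """
    rng = np.random.default_rng(model.seed)
    w_img, h_img = image_dims
    gt = list(gt)
    dets: List[DetectionRecord] = []
    for r in gt:
        if rng.random() < model.miss_rate_for(r.class_id):
            continue
        cid = r.class_id
        if model.confusion is not None and cid in model.confusion:
            row = model.confusion[cid]
            cid = int(rng.choice(list(row.keys()), p=list(row.values())))
        box = _jitter_box(r.box, model.localization_jitter_sd, rng)
        conf = float(rng.beta(*model.tp_confidence))
        dets.append(DetectionRecord(r.video_id, r.frame_index, cid, box, conf))

    if model.false_positive_rate > 0 and gt:
        widths = [r.box.width for r in gt]
        heights = [r.box.height for r in gt]
        classes = sorted({r.class_id for r in gt})
        frames = sorted({(r.video_id, r.frame_index) for r in gt})
        for video_id, frame in frames:
            for _ in range(rng.poisson(model.false_positive_rate)):
                bw = float(rng.uniform(min(widths), max(widths)))
                bh = float(rng.uniform(min(heights), max(heights)))
                cx = rng.uniform(bw / 2, w_img - bw / 2)
                cy = rng.uniform(bh / 2, h_img - bh / 2)
                dets.append(
                    DetectionRecord(
                        video_id,
                        frame,
                        int(rng.choice(classes)),
                        BoundingBox(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2),
                        float(rng.beta(*model.fp_confidence)),
                    )
                )
    return dets


@dataclass(frozen=True)
class GroupMotionParams:
    """Per-skill-group motion parameters of the suturing simulator.

    frames_per_stitch_mean, frames_per_stitch_sd
        Normal draw (rounded, floored at 2) of each stitch's duration.
    step_length
        Mean per-frame displacement of the instrument tip, px/frame; with
        zero noise every segment has exactly this length, so per-stitch
        path is ``(T - 1) * step_length``.
    step_noise_sd
        Gaussian sd of the per-frame displacement magnitude, px.
    """

    frames_per_stitch_mean: float
    frames_per_stitch_sd: float
    step_length: float
    step_noise_sd: float

    def __post_init__(self) -> None:
        if min(self.frames_per_stitch_mean, self.step_length) <= 0:
            raise ValidationError("means must be positive")
        if min(self.frames_per_stitch_sd, self.step_noise_sd) < 0:
            raise ValidationError("sds must be non-negative")

    @property
    def expected_path_length(self) -> float:
        """E[per-stitch path] ~ (E[frames] - 1) * step_length."""
        return (self.frames_per_stitch_mean - 1.0) * self.step_length


#: Default skill contrast, in the direction reported for real suturing:
#: proficient stitches are shorter in frames and faster per frame, hence
#: shorter paths, shorter moving times and higher velocities.
DEFAULT_GROUP_PARAMS: Dict[str, GroupMotionParams] = {
    PROFICIENT: GroupMotionParams(90.0, 20.0, 6.0, 1.5),
    NON_PROFICIENT: GroupMotionParams(160.0, 35.0, 4.5, 3.0),
}


@dataclass(frozen=True)
class SuturingSimConfig:
    """Configuration of the two-instrument suturing-session simulator."""

    n_stitches: int = 9
    image_dims: Tuple[int, int] = (960, 544)
    classes: Tuple[int, int] = (
        DEFAULT_LABELS.id_of("grasping_forceps"),
        DEFAULT_LABELS.id_of("needle_holder"),
    )
    box_size: Tuple[float, float] = (90.0, 60.0)
    direction_smoothing: float = 0.7  # EMA weight on the previous heading
    groups: Mapping[str, GroupMotionParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stitches <= 0:
            raise ValidationError("n_stitches must be positive")
        if not 0.0 <= self.direction_smoothing < 1.0:
            raise ValidationError("direction_smoothing must lie in [0, 1)")


def simulate_suturing_session(
    cfg: SuturingSimConfig,
    group: str,
    video_id: str = "sim",
    seed: Optional[int] = None,
) -> Tuple[List[GroundTruthRecord], List[StitchWindow]]:
    """Simulate one video's two-instrument suturing motion.

    Both instruments move every frame; stitch windows are consecutive
    half-open frame intervals. Per frame each instrument advances by a
    displacement whose magnitude is ``max(0, N(step_length, noise_sd))``
    along an EMA-smoothed heading, reflecting off the image margins, so a
    zero-noise stitch of T frames has path length exactly
    ``(T - 1) * step_length``.
    """
    if group not in cfg.groups:
        raise ValidationError(f"unknown group {group!r}")
    params = cfg.groups[group]
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    w_img, h_img = cfg.image_dims
    bw, bh = cfg.box_size
    margin_x = (bw / 2 + 2.0, w_img - bw / 2 - 2.0)
    margin_y = (bh / 2 + 2.0, h_img - bh / 2 - 2.0)

    durations = [
        max(2, int(round(rng.normal(params.frames_per_stitch_mean, params.frames_per_stitch_sd))))
        for _ in range(cfg.n_stitches)
    ]
    windows: List[StitchWindow] = []
    start = 0
    for sid, t in enumerate(durations, start=1):
        windows.append(StitchWindow(sid, start, start + t))
        start += t
    total_frames = start

    records: List[GroundTruthRecord] = []
    for cid in cfg.classes:
        cx = rng.uniform(w_img * 0.3, w_img * 0.7)
        cy = rng.uniform(h_img * 0.3, h_img * 0.7)
        theta = rng.uniform(0, 2 * math.pi)
        dx, dy = math.cos(theta), math.sin(theta)
        for frame in range(total_frames):
            if frame > 0:
                theta = rng.uniform(0, 2 * math.pi)
                ndx = cfg.direction_smoothing * dx + (1 - cfg.direction_smoothing) * math.cos(theta)
                ndy = cfg.direction_smoothing * dy + (1 - cfg.direction_smoothing) * math.sin(theta)
                norm = math.hypot(ndx, ndy)
                if norm > 0:
                    dx, dy = ndx / norm, ndy / norm
                step = max(0.0, float(rng.normal(params.step_length, params.step_noise_sd)))
                # reflect the heading off any margin the step would cross
                if not margin_x[0] <= cx + dx * step <= margin_x[1]:
                    dx = -dx
                if not margin_y[0] <= cy + dy * step <= margin_y[1]:
                    dy = -dy
                cx = float(np.clip(cx + dx * step, *margin_x))
                cy = float(np.clip(cy + dy * step, *margin_y))
            records.append(
                GroundTruthRecord(
                    video_id,
                    frame,
                    cid,
                    BoundingBox(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2),
                )
            )
    return records, windows


def as_detections(
    gt: Iterable[GroundTruthRecord], confidence: float = 1.0
) -> List[DetectionRecord]:
    """Treat ground truth as perfect detections (identity detector)."""
    return [
        DetectionRecord(r.video_id, r.frame_index, r.class_id, r.box, confidence)
        for r in gt
    ]


@dataclass
class SkillStudy:
    """A simulated cohort: per-video truth, stitch windows, GOALS sheets."""

    ground_truth: Dict[str, List[GroundTruthRecord]]
    windows: Dict[str, List[StitchWindow]]
    sheets: List[GoalsSheet]
    labels: List[ProficiencyLabel]
    group_of: Dict[str, str]


#: Stitch counts per video reproducing the study conditions: 7 proficient
#: videos totalling 62 stitches and 4 non-proficient totalling 28.
DEFAULT_COHORT: Dict[str, Tuple[int, ...]] = {
    PROFICIENT: (9, 9, 9, 9, 9, 9, 8),
    NON_PROFICIENT: (7, 7, 7, 7),
}


def simulate_skill_study(
    cfg: SuturingSimConfig = SuturingSimConfig(),
    cohort: Mapping[str, Tuple[int, ...]] = None,
    n_raters: int = 3,
    seed: int = 0,
) -> SkillStudy:
    """Simulate a full skill-comparison cohort with known group effects.

    GOALS facet scores are drawn per rater in 4-5 for proficient videos
    and 1-2 for non-proficient ones, so mean totals fall on the correct
    side of the cutoff of 12 by construction.
    """
    cohort = dict(DEFAULT_COHORT) if cohort is None else dict(cohort)
    rng = np.random.default_rng(seed)
    study = SkillStudy({}, {}, [], [], {})
    for group, stitch_counts in cohort.items():
        for i, n_stitches in enumerate(stitch_counts, start=1):
            vid = f"{group}_{i:02d}"
            vid_cfg = replace(cfg, n_stitches=n_stitches)
            gt, windows = simulate_suturing_session(
                vid_cfg, group, video_id=vid, seed=int(rng.integers(2**31))
            )
            study.ground_truth[vid] = gt
            study.windows[vid] = windows
            lo, hi = (4, 5) if group == PROFICIENT else (1, 2)
            ratings = tuple(
                tuple(int(rng.integers(lo, hi + 1)) for _ in range(4))
                for _ in range(n_raters)
            )
            sheet = GoalsSheet(vid, ratings)
            study.sheets.append(sheet)
            study.labels.append(label_proficiency(sheet))
            study.group_of[vid] = group
    return study
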