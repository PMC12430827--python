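"""Centroid trajectories and per-stitch kinematic metrics.

Frame-wise detections of one instrument class are reduced to a sequence of
box centroids; centroids in *successive* frames are linked by straight
segments, and the segments are the trajectory. Per stitch (one needle pass
through tissue, delimited by manually supplied frame windows) three metrics
are computed:

- **path length** — summed Euclidean segment length, in pixels;
- **moving time** — the number of trajectory points (frames in which the
  instrument was detected), in frames;
- **movement velocity** — path length divided by moving time, px/frame.

Detection gaps produce no segment: the trajectory simply resumes after the
gap, with no interpolation. A single detected frame therefore contributes
moving time 1 and path length 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .records import BoundingBox, DetectionRecord, ValidationError


@dataclass(frozen=True)
class TrajectoryPoint:
    """One centroid observation: frame, pixel position, detector confidence."""

    frame_index: int
    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError("trajectory coordinates must be finite")


@dataclass(frozen=True)
class Trajectory:
    """An ordered centroid sequence for one instrument class in one video.

    Points are strictly increasing in ``frame_index``. A segment exists
    between two points iff their frame indices differ by exactly 1.
    """

    video_id: str
    class_id: int
    points: Tuple[TrajectoryPoint, ...]

    def __post_init__(self) -> None:
        frames = [p.frame_index for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValidationError("trajectory frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def segments(self) -> List[Tuple[TrajectoryPoint, TrajectoryPoint]]:
        """Pairs of points in consecutive frames (the drawn lines)."""
        return [
            (a, b)
            for a, b in zip(self.points, self.points[1:])
            if b.frame_index - a.frame_index == 1
        ]

    @property
    def path_length(self) -> float:
        """Summed Euclidean length of all segments, in pixels."""
        return sum(math.hypot(b.x - a.x, b.y - a.y) for a, b in self.segments)


@dataclass(frozen=True)
class StitchWindow:
    """Half-open frame interval ``[start_frame, end_frame)`` of one stitch.

    The start of a stitch is the needle's first tissue contact; the end is
    the contact that starts the next stitch. Windows within a video must be
    non-overlapping.
    """

    stitch_id: int
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ValidationError(
                f"stitch {self.stitch_id}: start_frame must be < end_frame"
            )

    def contains(self, frame_index: int) -> bool:
        return self.start_frame <= frame_index < self.end_frame


@dataclass(frozen=True)
class StitchKinematics:
    """Per-stitch kinematics of one instrument class."""

    video_id: str
    stitch_id: int
    class_id: int
    path_length: float
    moving_time: int
    velocity: float

    def __post_init__(self) -> None:
        if self.path_length < 0 or self.moving_time < 1:
            raise ValidationError("path_length must be >= 0 and moving_time >= 1")


def centroid(box: BoundingBox) -> Tuple[float, float]:
    """Centroid of a bounding box: the midpoint of its corners."""
    return box.center


def filter_classes(
    dets: Iterable[DetectionRecord], allowed: Set[int]
) -> List[DetectionRecord]:
    """Keep only detections of the allowed classes, preserving order.

    Restricting tracking to the instruments actually used in the task
    (by default the needle holder and grasping forceps) prevents sporadic
    misclassifications from interrupting the trajectories.
    """
    if not allowed:
        raise ValidationError("allowed class set must be non-empty")
    return [d for d in dets if d.class_id in allowed]


def build_trajectory(
    dets: Iterable[DetectionRecord],
    class_id: int,
    video_id: Optional[str] = None,
) -> Trajectory:
    """Reduce one video's detections of one class to a centroid trajectory.

    If several same-class detections share a frame, the highest-confidence
    one is kept; confidence ties are broken by proximity to the previous
    trajectory point, then by lowest x. An absent class yields an empty
    trajectory.
    """
    per_frame: Dict[int, List[DetectionRecord]] = {}
    vid = video_id
    for d in dets:
        if d.class_id != class_id:
            continue
        if vid is None:
            vid = d.video_id
        elif d.video_id != vid:
            continue
        per_frame.setdefault(d.frame_index, []).append(d)

    points: List[TrajectoryPoint] = []
    prev: Optional[Tuple[float, float]] = None
    for frame in sorted(per_frame):
        candidates = per_frame[frame]
        best_conf = max(c.confidence for c in candidates)
        tied = [c for c in candidates if c.confidence == best_conf]
        if len(tied) > 1 and prev is not None:
            px, py = prev
            tied.sort(
                key=lambda c: (
                    math.hypot(c.box.center[0] - px, c.box.center[1] - py),
                    c.box.center[0],
                )
            )
        elif len(tied) > 1:
            tied.sort(key=lambda c: c.box.center[0])
        chosen = tied[0]
        cx, cy = chosen.box.center
        points.append(TrajectoryPoint(frame, cx, cy, chosen.confidence))
        prev = (cx, cy)
    return Trajectory(vid if vid is not None else "", class_id, tuple(points))


def segment_by_stitch(
    traj: Trajectory, windows: Sequence[StitchWindow]
) -> Dict[int, Trajectory]:
    """Assign trajectory points to stitch windows.

    Each point goes to the window containing its frame (half-open
    ``[start, end)``); points outside every window are dropped. Because a
    sub-trajectory only contains its own points, a segment whose endpoints
    fall in different windows is present in neither.
    """
    ordered = sorted(windows, key=lambda w: w.start_frame)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_frame < a.end_frame:
            raise ValidationError(
                f"stitch windows {a.stitch_id} and {b.stitch_id} overlap"
            )
    out: Dict[int, Trajectory] = {}
    for w in ordered:
        pts = tuple(p for p in traj.points if w.contains(p.frame_index))
        out[w.stitch_id] = Trajectory(traj.video_id, traj.class_id, pts)
    return out


def stitch_kinematics(
    traj: Trajectory, stitch_id: int
) -> Optional[StitchKinematics]:
    """Kinematic metrics of one per-stitch trajectory.

    Returns ``None`` for an empty trajectory (no motion data for this
    stitch; such stitches are excluded from downstream statistics).
    """
    if len(traj) == 0:
        return None
    path = traj.path_length
    time = len(traj)
    return StitchKinematics(
        video_id=traj.video_id,
        stitch_id=stitch_id,
        class_id=traj.class_id,
        path_length=path,
        moving_time=time,
        velocity=path / time,
    )


def compute_stitch_kinematics(
    dets: Iterable[DetectionRecord],
    windows: Sequence[StitchWindow],
    classes: Set[int],
    video_id: Optional[str] = None,
) -> List[StitchKinematics]:
    """End-to-end: class filter, trajectory, stitch windowing, metrics.

    One record per (stitch, class) with at least one detected frame.
    """
    dets = list(filter_classes(dets, classes))
    records: List[StitchKinematics] = []
    for class_id in sorted(classes):
        traj = build_trajectory(dets, class_id, video_id=video_id)
        for stitch_id, sub in segment_by_stitch(traj, windows).items():
            kin = stitch_kinematics(sub, stitch_id)
            if kin is not None:
                records.append(kin)
    return records
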