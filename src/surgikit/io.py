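"""Readers and writers for the pipeline's interchange files.

Boxes travel as COCO object-detection JSON — either a full file with
``images``/``annotations``/``categories`` keys, or (detections only) the
COCO "results" dialect: a bare list of ``{image_id, category_id, bbox,
score}`` objects, which is what most detectors emit. COCO stores boxes as
``[x, y, width, height]``; they are converted to corner form on read.

Image entries may carry explicit ``video_id`` and ``frame_index`` fields;
when absent, the image id doubles as the frame index and the video id
defaults to ``"video"``. Kinematics tables, stitch windows and GOALS score
sheets travel as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .kinematics import StitchKinematics, StitchWindow
from .records import (
    DEFAULT_LABELS,
    BoundingBox,
    DetectionRecord,
    GroundTruthRecord,
    LabelSet,
    ParseError,
    ValidationError,
)
from .skill import FACETS, GoalsSheet

PathLike = Union[str, Path]


def _load_json(path: PathLike):
    try:
        with open(path) as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON ({exc})") from exc


def _image_index(doc: Mapping) -> Dict[int, Tuple[str, int]]:
    """image id -> (video_id, frame_index)."""
    out: Dict[int, Tuple[str, int]] = {}
    for img in doc.get("images", []):
        vid = str(img.get("video_id", "video"))
        frame = int(img.get("frame_index", img["id"]))
        out[int(img["id"])] = (vid, frame)
    return out


def _category_map(doc: Mapping, labels: LabelSet) -> Dict[int, int]:
    """COCO category id -> configured class id.

    A category is accepted if its id is a configured class id, or if its
    name matches a configured display name (the id is then remapped).
    """
    out: Dict[int, int] = {}
    for cat in doc.get("categories", []):
        cid = int(cat["id"])
        if cid in labels.ids:
            out[cid] = cid
        else:
            name = cat.get("name")
            try:
                out[cid] = labels.id_of(name)
            except KeyError:
                raise ValidationError(
                    f"unknown category id {cid} (name={name!r})"
                ) from None
    return out


def _box_from_coco(bbox: Sequence[float], context: str) -> BoundingBox:
    x, y, w, h = (float(v) for v in bbox)
    if w <= 0 or h <= 0:
        raise ValidationError(f"{context}: zero-area box {bbox}")
    return BoundingBox.from_xywh(x, y, w, h)


def read_annotations(
    path: PathLike, labels: LabelSet = DEFAULT_LABELS
) -> List[GroundTruthRecord]:
    """Read ground-truth boxes from a full COCO object-detection file."""
    doc = _load_json(path)
    if not isinstance(doc, Mapping):
        raise ParseError(
            f"{path}: expected a COCO object with an 'annotations' key; "
            "a bare results list holds detections, not annotations"
        )
    images = _image_index(doc)
    cats = _category_map(doc, labels)
    records: List[GroundTruthRecord] = []
    for ann in doc.get("annotations", []):
        cat_id = int(ann["category_id"])
        if cat_id not in cats:
            raise ValidationError(f"unknown category id {cat_id} in annotation {ann.get('id')}")
        video_id, frame = images[int(ann["image_id"])]
        box = _box_from_coco(ann["bbox"], f"annotation {ann.get('id')}")
        records.append(GroundTruthRecord(video_id, frame, cats[cat_id], box))
    return records


def read_detections(
    path: PathLike, labels: LabelSet = DEFAULT_LABELS
) -> List[DetectionRecord]:
    """Read detector outputs from a full COCO file or a COCO results list."""
    doc = _load_json(path)
    if isinstance(doc, list):
        entries = doc
        images: Dict[int, Tuple[str, int]] = {}
        cats: Optional[Dict[int, int]] = None
    elif isinstance(doc, Mapping):
        entries = doc.get("annotations", [])
        images = _image_index(doc)
        cats = _category_map(doc, labels)
    else:
        raise ParseError(f"{path}: not a COCO object or results list")

    records: List[DetectionRecord] = []
    for i, det in enumerate(entries):
        cat_id = int(det["category_id"])
        if cats is not None:
            if cat_id not in cats:
                raise ValidationError(f"unknown category id {cat_id} in detection {i}")
            class_id = cats[cat_id]
        else:
            class_id = labels.validate_class(cat_id)
        image_id = int(det["image_id"])
        if images:
            video_id, frame = images[image_id]
        else:
            video_id, frame = str(det.get("video_id", "video")), image_id
        score = det.get("score")
        if score is None:
            raise ValidationError(f"detection {i}: missing confidence score")
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValidationError(
                f"detection {i}: confidence {score} outside [0, 1]"
            )
        box = _box_from_coco(det["bbox"], f"detection {i}")
        records.append(DetectionRecord(video_id, frame, class_id, box, score))
    return records


def _coco_skeleton(
    records: Sequence, labels: LabelSet
) -> Tuple[List[Mapping], Dict[Tuple[str, int], int], List[Mapping]]:
    keys = sorted({(r.video_id, r.frame_index) for r in records})
    image_ids = {key: i + 1 for i, key in enumerate(keys)}
    images = [
        {
            "id": image_ids[(vid, frame)],
            "video_id": vid,
            "frame_index": frame,
            "file_name": f"{vid}_{frame:06d}.png",
        }
        for vid, frame in keys
    ]
    categories = [{"id": cid, "name": name} for cid, name in labels.classes]
    return images, image_ids, categories


def write_annotations(
    records: Sequence[GroundTruthRecord],
    path: PathLike,
    labels: LabelSet = DEFAULT_LABELS,
) -> None:
    """Write ground truth as a full COCO object-detection file."""
    images, image_ids, categories = _coco_skeleton(records, labels)
    annotations = [
        {
            "id": i + 1,
            "image_id": image_ids[(r.video_id, r.frame_index)],
            "category_id": r.class_id,
            "bbox": list(r.box.to_xywh()),
            "area": r.box.area,
            "iscrowd": 0,
        }
        for i, r in enumerate(records)
    ]
    doc = {"images": images, "annotations": annotations, "categories": categories}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_detections(
    records: Sequence[DetectionRecord],
    path: PathLike,
    labels: LabelSet = DEFAULT_LABELS,
) -> None:
    """Write detections as a full COCO file with per-annotation scores."""
    images, image_ids, categories = _coco_skeleton(records, labels)
    annotations = [
        {
            "id": i + 1,
            "image_id": image_ids[(r.video_id, r.frame_index)],
            "category_id": r.class_id,
            "bbox": list(r.box.to_xywh()),
            "score": r.confidence,
        }
        for i, r in enumerate(records)
    ]
    doc = {"images": images, "annotations": annotations, "categories": categories}
    with open(path, "w") as fh:
        json.dump(doc, fh)


KINEMATICS_COLUMNS = (
    "video_id",
    "stitch_id",
    "class_id",
    "path_length_px",
    "moving_time_frames",
    "velocity_px_per_frame",
    "group",
)


def write_kinematics_table(
    records: Sequence[StitchKinematics],
    path: PathLike,
    groups: Optional[Mapping[str, str]] = None,
) -> None:
    """Write per-stitch kinematics as CSV, one row per (video, stitch, class).

    ``groups`` optionally maps video id to its proficiency-group label.
    """
    if not records:
        raise ValidationError("kinematics table must be non-empty")
    rows = [
        {
            "video_id": r.video_id,
            "stitch_id": r.stitch_id,
            "class_id": r.class_id,
            "path_length_px": r.path_length,
            "moving_time_frames": r.moving_time,
            "velocity_px_per_frame": r.velocity,
            "group": (groups or {}).get(r.video_id, ""),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(KINEMATICS_COLUMNS)).to_csv(path, index=False)


def read_kinematics_table(
    path: PathLike,
) -> Tuple[List[StitchKinematics], Dict[str, str]]:
    """Read a kinematics CSV back into records plus a video->group map."""
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    records = [
        StitchKinematics(
            video_id=str(row.video_id),
            stitch_id=int(row.stitch_id),
            class_id=int(row.class_id),
            path_length=float(row.path_length_px),
            moving_time=int(row.moving_time_frames),
            velocity=float(row.velocity_px_per_frame),
        )
        for row in df.itertuples()
    ]
    groups = {
        str(row.video_id): str(row.group)
        for row in df.itertuples()
        if str(row.group)
    }
    return records, groups


def write_stitch_windows(
    windows: Mapping[str, Sequence[StitchWindow]], path: PathLike
) -> None:
    rows = [
        {
            "video_id": vid,
            "stitch_id": w.stitch_id,
            "start_frame": w.start_frame,
            "end_frame": w.end_frame,
        }
        for vid, ws in windows.items()
        for w in ws
    ]
    pd.DataFrame(
        rows, columns=["video_id", "stitch_id", "start_frame", "end_frame"]
    ).to_csv(path, index=False)


def read_stitch_windows(path: PathLike) -> Dict[str, List[StitchWindow]]:
    """Read stitch boundaries: columns video_id, stitch_id, start_frame, end_frame."""
    df = pd.read_csv(path)
    out: Dict[str, List[StitchWindow]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.video_id), []).append(
            StitchWindow(int(row.stitch_id), int(row.start_frame), int(row.end_frame))
        )
    for ws in out.values():
        ws.sort(key=lambda w: w.start_frame)
    return out


def write_goals_sheets(sheets: Sequence[GoalsSheet], path: PathLike) -> None:
    rows = [
        {"video_id": s.video_id, "rater_id": r + 1, **dict(zip(FACETS, scores))}
        for s in sheets
        for r, scores in enumerate(s.ratings)
    ]
    pd.DataFrame(rows, columns=["video_id", "rater_id", *FACETS]).to_csv(
        path, index=False
    )


def read_goals_sheets(path: PathLike) -> List[GoalsSheet]:
    """Read GOALS scores: columns video_id, rater_id, then one per facet."""
    df = pd.read_csv(path)
    sheets: List[GoalsSheet] = []
    for vid, sub in df.groupby("video_id", sort=True):
        sub = sub.sort_values("rater_id")
        ratings = tuple(
            tuple(int(row[f]) for f in FACETS) for _, row in sub.iterrows()
        )
        sheets.append(GoalsSheet(str(vid), ratings))
    return sheets


def sample_frame_indices(
    total_frames: int, fps: float, interval_seconds: float = 8.0
) -> List[int]:
    """Frame indices sampled at a fixed time interval, starting at frame 0.

    Consecutive video frames are highly redundant, so frames are extracted
    every ``interval_seconds`` (8 s by default). The step is
    ``round(fps * interval_seconds)`` frames; indices are 0-based, strictly
    increasing and strictly less than ``total_frames``.
    """
    if total_frames <= 0 or fps <= 0 or interval_seconds <= 0:
        raise ValidationError(
            "total_frames, fps and interval_seconds must all be positive"
        )
    step = max(1, round(fps * interval_seconds))
    return list(range(0, total_frames, step))
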