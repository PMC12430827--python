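"""Core domain types for frame-wise instrument detection and annotation.

All geometry lives in continuous pixel coordinates with the origin at the
image's top-left corner, x increasing rightward and y increasing downward
(the standard image convention). Boxes are stored in corner form
``(x_min, y_min, x_max, y_max)``; area is plain width x height with no
+1 pixel correction, matching COCO conventions so that IoU values are
scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple


class ValidationError(ValueError):
    """A record or argument violates a domain invariant."""


class ParseError(ValueError):
    """An input file could not be parsed in the expected format."""


@dataclass(frozen=True)
class BoundingBox:
    """An axis-aligned rectangle in pixel coordinates, corner form.

    Parameters
    ----------
    x_min, y_min : float
        Top-left corner.
    x_max, y_max : float
        Bottom-right corner. Must be strictly greater than the
        corresponding minimum: zero-area boxes are invalid.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValidationError(
                f"box must have strictly positive area, got "
                f"({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> Tuple[float, float]:
        """Centroid ``((x_min + x_max)/2, (y_min + y_max)/2)``."""
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        """Build from COCO ``[x, y, width, height]`` form."""
        return cls(x, y, x + w, y + h)

    def to_xywh(self) -> Tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.width, self.height)


@dataclass(frozen=True)
class GroundTruthRecord:
    """One manually annotated instrument box in one video frame."""

    video_id: str
    frame_index: int
    class_id: int
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")


@dataclass(frozen=True)
class DetectionRecord:
    """One detector output box: a ground-truth record plus a confidence score."""

    video_id: str
    frame_index: int
    class_id: int
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(
                f"confidence must lie in [0, 1], got {self.confidence}"
            )


@dataclass(frozen=True)
class LabelSet:
    """The configured instrument classes and the raw-code consolidation map.

    ``classes`` is an ordered list of ``(class_id, display_name)``.
    ``consolidation`` maps raw per-instrument codes (e.g. ``"SI-5"``) to
    consolidated class ids; instruments with near-identical appearance and
    function share one consolidated class.
    """

    classes: Tuple[Tuple[int, str], ...]
    consolidation: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.classes]
        if len(ids) != len(set(ids)):
            raise ValidationError("class ids must be unique")
        unknown = {c for c in self.consolidation.values()} - set(ids)
        if unknown:
            raise ValidationError(
                f"consolidation targets not in the class list: {sorted(unknown)}"
            )

    @property
    def ids(self) -> Tuple[int, ...]:
        return tuple(cid for cid, _ in self.classes)

    def name(self, class_id: int) -> str:
        for cid, nm in self.classes:
            if cid == class_id:
                return nm
        raise KeyError(class_id)

    def id_of(self, name: str) -> int:
        for cid, nm in self.classes:
            if nm == name:
                return cid
        raise KeyError(name)

    def consolidate(self, raw_code: str) -> int:
        """Map a raw instrument code to its consolidated class id."""
        try:
            return self.consolidation[raw_code]
        except KeyError:
            raise ValidationError(f"unknown raw instrument code {raw_code!r}") from None

    def validate_class(self, class_id: int) -> int:
        if class_id not in self.ids:
            raise ValidationError(f"unknown class id {class_id}")
        return class_id


#: Ten consolidated instrument classes from twelve raw instruments: the two
#: ultrasound-knife variants (SI-5/6) and the two grasping-forceps variants
#: (SI-7/8) are merged on appearance and function. Users analysing other
#: instrument sets supply their own LabelSet.
DEFAULT_LABELS = LabelSet(
    classes=(
        (1, "bipolar_forceps_1"),
        (2, "bipolar_forceps_2"),
        (3, "hook_electrode_monopolar"),
        (4, "needle_holder"),
        (5, "ultrasound_knife"),
        (6, "grasping_forceps"),
        (7, "scissors"),
        (8, "suction_irrigation_tube"),
        (9, "myoma_grasping_forceps"),
        (10, "myoma_drill"),
    ),
    consolidation={
        "SI-1": 1,
        "SI-2": 2,
        "SI-3": 3,
        "SI-4": 4,
        "SI-5": 5,
        "SI-6": 5,
        "SI-7": 6,
        "SI-8": 6,
        "SI-9": 7,
        "SI-10": 8,
        "SI-11": 9,
        "SI-12": 10,
    },
)

#: The two instruments that perform vaginal-stump suturing; the default
#: class filter for trajectory tracking.
DEFAULT_TRACKED_CLASSES = frozenset(
    {DEFAULT_LABELS.id_of("needle_holder"), DEFAULT_LABELS.id_of("grasping_forceps")}
)


def records_in_frame(
    records: Sequence, video_id: str, frame_index: int
) -> list:
    """All records of one ``(video, frame)``; order preserved."""
    return [
        r
        for r in records
        if r.video_id == video_id and r.frame_index == frame_index
    ]
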