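"""Pipeline configuration: one YAML-serializable bundle of every knob.

``PipelineConfig`` collects the label set, pre/post-processing constants,
the evaluation threshold, the tracked classes, the proficiency cutoff and
the quartile convention, plus the top-level seed, so a whole run is
reproducible from one file. ``load(save(cfg)) == cfg``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import yaml

from .evaluation import EvalConfig
from .postprocess import PostprocessConfig, PreprocessConfig
from .records import DEFAULT_LABELS, DEFAULT_TRACKED_CLASSES, LabelSet

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PipelineConfig:
    labels: LabelSet = DEFAULT_LABELS
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    tracked_classes: Tuple[int, ...] = tuple(sorted(DEFAULT_TRACKED_CLASSES))
    proficiency_cutoff: float = 12.0
    quartile_method: str = "linear"
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> Dict:
        return {
            "labels": {
                "classes": [list(c) for c in self.labels.classes],
                "consolidation": dict(self.labels.consolidation),
            },
            "preprocess": asdict(self.preprocess),
            "postprocess": asdict(self.postprocess),
            "evaluation": asdict(self.evaluation),
            "tracked_classes": list(self.tracked_classes),
            "proficiency_cutoff": self.proficiency_cutoff,
            "quartile_method": self.quartile_method,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        labels = LabelSet(
            classes=tuple((int(c), str(n)) for c, n in d["labels"]["classes"]),
            consolidation={
                str(k): int(v) for k, v in d["labels"].get("consolidation", {}).items()
            },
        )
        pre = d.get("preprocess", {})
        return cls(
            labels=labels,
            preprocess=PreprocessConfig(
                target_width=int(pre.get("target_width", 960)),
                target_height=int(pre.get("target_height", 544)),
                channel_means=tuple(pre.get("channel_means", (123.675, 116.28, 103.53))),
                channel_stds=tuple(pre.get("channel_stds", (58.395, 57.12, 57.375))),
            ),
            postprocess=PostprocessConfig(**d.get("postprocess", {})),
            evaluation=EvalConfig(**d.get("evaluation", {})),
            tracked_classes=tuple(int(c) for c in d["tracked_classes"]),
            proficiency_cutoff=float(d["proficiency_cutoff"]),
            quartile_method=str(d["quartile_method"]),
            seed=int(d["seed"]),
            out_dir=str(d["out_dir"]),
        )

    def save(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        """Stable hash of the configuration, recorded in run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def file_checksum(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
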