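import json

import numpy as np
import pytest

from surgikit import BoundingBox, DetectionRecord, GroundTruthRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def make_box(x, y, w, h):
    return BoundingBox(x, y, x + w, y + h)


def det(frame, cls, box, conf, video="v"):
    return DetectionRecord(video, frame, cls, box, conf)


def gt(frame, cls, box, video="v"):
    return GroundTruthRecord(video, frame, cls, box)


@pytest.fixture
def coco_file(tmp_path):
    """Write a COCO object-detection JSON and return its path."""

    def _write(images, annotations, categories, name="coco.json"):
        path = tmp_path / name
        path.write_text(
            json.dumps(
                {"images": images, "annotations": annotations, "categories": categories}
            )
        )
        return path

    return _write


def random_frame_records(rng, n_classes=2, max_per_class=4, img=200.0):
    """Random small frame emulating annotated video: well-separated
    same-class ground-truth boxes (one per physical instrument), detections
    as jittered copies of most of them plus Poisson spurious boxes."""
    from surgikit import iou

    dets, gts = [], []
    for cls in range(1, n_classes + 1):
        boxes = []
        n_gt = rng.integers(0, max_per_class + 1)
        tries = 0
        while len(boxes) < n_gt and tries < 100:
            tries += 1
            x, y = rng.uniform(0, img - 50, 2)
            w, h = rng.uniform(15, 45, 2)
            cand = make_box(x, y, w, h)
            if all(iou(cand, b) < 0.05 for b in boxes):
                boxes.append(cand)
        for b in boxes:
            gts.append(gt(0, cls, b))
            if rng.random() < 0.8:  # detected, with localization jitter
                j = rng.normal(0, 4, 4)
                jittered = BoundingBox(
                    b.x_min + j[0],
                    b.y_min + j[1],
                    max(b.x_min + j[0] + 2, b.x_max + j[2]),
                    max(b.y_min + j[1] + 2, b.y_max + j[3]),
                )
                dets.append(det(0, cls, jittered, float(rng.uniform(0.2, 1.0))))
        for _ in range(rng.poisson(0.7)):  # spurious boxes
            x, y = rng.uniform(0, img - 50, 2)
            w, h = rng.uniform(15, 45, 2)
            dets.append(det(0, cls, make_box(x, y, w, h), float(rng.uniform(0.2, 1.0))))
    return dets, gts
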