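"""Domain types, COCO/CSV round-trips, frame sampling."""

import json

import pytest

from surgikit import (
    BoundingBox,
    DetectionRecord,
    GoalsSheet,
    GroundTruthRecord,
    LabelSet,
    ParseError,
    StitchKinematics,
    StitchWindow,
    ValidationError,
)
from surgikit.io import (
    read_annotations,
    read_detections,
    read_goals_sheets,
    read_kinematics_table,
    read_stitch_windows,
    sample_frame_indices,
    write_annotations,
    write_detections,
    write_goals_sheets,
    write_kinematics_table,
    write_stitch_windows,
)
from surgikit.records import DEFAULT_LABELS


class TestBoundingBox:
    def test_corner_conversion_from_coco(self):
        box = BoundingBox.from_xywh(10, 20, 30, 40)
        assert (box.x_min, box.y_min, box.x_max, box.y_max) == (10, 20, 40, 60)
        assert box.area == 30 * 40

    @pytest.mark.parametrize("corners", [(0, 0, 0, 10), (0, 0, 10, 0), (5, 5, 4, 9)])
    def test_degenerate_boxes_rejected(self, corners):
        with pytest.raises(ValidationError):
            BoundingBox(*corners)

    def test_confidence_bounds(self):
        box = BoundingBox(0, 0, 1, 1)
        with pytest.raises(ValidationError):
            DetectionRecord("v", 0, 1, box, 1.2)
        with pytest.raises(ValidationError):
            DetectionRecord("v", 0, 1, box, -0.1)


class TestLabelSet:
    def test_default_consolidation_is_total_over_raw_codes(self):
        for i in range(1, 13):
            assert DEFAULT_LABELS.consolidate(f"SI-{i}") in DEFAULT_LABELS.ids
        # the two merged pairs
        assert DEFAULT_LABELS.consolidate("SI-5") == DEFAULT_LABELS.consolidate("SI-6")
        assert DEFAULT_LABELS.consolidate("SI-7") == DEFAULT_LABELS.consolidate("SI-8")
        assert len(DEFAULT_LABELS.ids) == 10

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            LabelSet(classes=((1, "a"), (1, "b")))


class TestCocoRead:
    def test_annotations_across_images(self, coco_file):
        path = coco_file(
            images=[
                {"id": 1, "frame_index": 3, "video_id": "a"},
                {"id": 2, "frame_index": 9, "video_id": "a"},
            ],
            annotations=[
                {"id": 1, "image_id": 1, "category_id": 4, "bbox": [10, 20, 30, 40]},
                {"id": 2, "image_id": 1, "category_id": 6, "bbox": [0, 0, 5, 5]},
                {"id": 3, "image_id": 2, "category_id": 4, "bbox": [1, 1, 2, 2]},
            ],
            categories=[{"id": 4, "name": "needle_holder"}, {"id": 6, "name": "grasping_forceps"}],
        )
        records = read_annotations(path)
        assert len(records) == 3
        assert {r.frame_index for r in records} == {3, 9}
        assert records[0].box == BoundingBox(10, 20, 40, 60)

    def test_empty_annotation_list(self, coco_file):
        path = coco_file(images=[], annotations=[], categories=[])
        assert read_annotations(path) == []

    def test_unknown_category_named_in_error(self, coco_file):
        path = coco_file(
            images=[{"id": 1}],
            annotations=[{"id": 1, "image_id": 1, "category_id": 99, "bbox": [0, 0, 1, 1]}],
            categories=[{"id": 99, "name": "mystery_tool"}],
        )
        with pytest.raises(ValidationError, match="99"):
            read_annotations(path)

    def test_zero_area_box_named_in_error(self, coco_file):
        path = coco_file(
            images=[{"id": 1}],
            annotations=[{"id": 7, "image_id": 1, "category_id": 4, "bbox": [0, 0, 0, 5]}],
            categories=[{"id": 4, "name": "needle_holder"}],
        )
        with pytest.raises(ValidationError, match="7"):
            read_annotations(path)

    def test_malformed_json(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ParseError):
            read_annotations(path)

    def test_results_list_dialect(self, tmp_path):
        dets = [
            {"image_id": i, "category_id": 4, "bbox": [i, 0, 10, 10], "score": 0.95}
            for i in range(5)
        ]
        path = tmp_path / "results.json"
        path.write_text(json.dumps(dets))
        records = read_detections(path)
        assert len(records) == 5
        assert records[0].confidence == 0.95
        assert [r.frame_index for r in records] == list(range(5))

    def test_out_of_range_score_rejected(self, tmp_path):
        path = tmp_path / "results.json"
        path.write_text(
            json.dumps([{"image_id": 0, "category_id": 4, "bbox": [0, 0, 1, 1], "score": 1.2}])
        )
        with pytest.raises(ValidationError):
            read_detections(path)


class TestRoundTrips:
    def test_annotations_round_trip(self, tmp_path):
        records = [
            GroundTruthRecord("v1", 0, 4, BoundingBox(1, 2, 3, 4)),
            GroundTruthRecord("v1", 5, 6, BoundingBox(10, 10, 50, 40)),
            GroundTruthRecord("v2", 0, 8, BoundingBox(0, 0, 9, 9)),
        ]
        path = tmp_path / "ann.json"
        write_annotations(records, path)
        assert sorted(read_annotations(path), key=str) == sorted(records, key=str)

    def test_detections_round_trip(self, tmp_path):
        records = [
            DetectionRecord("v1", 0, 4, BoundingBox(1, 2, 3, 4), 0.9),
            DetectionRecord("v1", 1, 6, BoundingBox(5, 5, 9, 9), 0.4),
        ]
        path = tmp_path / "dets.json"
        write_detections(records, path)
        assert sorted(read_detections(path), key=str) == sorted(records, key=str)

    def test_kinematics_round_trip_and_row_count(self, tmp_path):
        records = [
            StitchKinematics(f"v{i % 5}", i, 4, float(i * 10), i + 1, 10.0 * i / (i + 1))
            for i in range(90)
        ]
        path = tmp_path / "kin.csv"
        write_kinematics_table(records, path, groups={"v0": "proficient"})
        back, groups = read_kinematics_table(path)
        assert back == records
        assert groups == {"v0": "proficient"}
        assert len(path.read_text().strip().splitlines()) == 91  # header + rows

    def test_empty_kinematics_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_kinematics_table([], tmp_path / "kin.csv")

    def test_stitch_windows_round_trip(self, tmp_path):
        windows = {"v1": [StitchWindow(1, 0, 10), StitchWindow(2, 10, 25)]}
        path = tmp_path / "stitches.csv"
        write_stitch_windows(windows, path)
        assert read_stitch_windows(path) == windows

    def test_goals_round_trip(self, tmp_path):
        sheets = [
            GoalsSheet("v1", ((4, 5, 4, 5), (3, 4, 4, 4))),
            GoalsSheet("v2", ((1, 2, 1, 2),)),
        ]
        path = tmp_path / "goals.csv"
        write_goals_sheets(sheets, path)
        assert read_goals_sheets(path) == sheets


class TestSampleFrameIndices:
    @pytest.mark.parametrize(
        "total,fps,interval,expected",
        [
            (100, 25, 1, [0, 25, 50, 75]),
            (10, 30, 8, [0]),
        ],
    )
    def test_examples(self, total, fps, interval, expected):
        assert sample_frame_indices(total, fps, interval) == expected

    def test_two_hour_count(self):
        # 7200 frames at 30 fps sampled every 8 s: step 240, floor(7199/240)+1
        indices = sample_frame_indices(7200, 30, 8)
        assert len(indices) == 30
        assert indices[0] == 0 and indices[-1] < 7200

    @pytest.mark.parametrize("total,fps,interval", [(0, 30, 8), (10, -1, 8), (10, 30, 0)])
    def test_non_positive_arguments(self, total, fps, interval):
        with pytest.raises(ValidationError):
            sample_frame_indices(total, fps, interval)

    @pytest.mark.parametrize("total,fps,interval", [(50, 7, 3), (1, 24, 8), (999, 29.97, 8)])
    def test_length_formula(self, total, fps, interval):
        step = max(1, round(fps * interval))
        assert len(sample_frame_indices(total, fps, interval)) == (total - 1) // step + 1
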