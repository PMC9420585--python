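"""Pixel-sample mapping, LabelMe parsing, and dataset splitting."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulseseg.annotations import (
    AnnotationSet,
    PixelMapping,
    Span,
    annotation_to_labels,
    labels_to_annotation,
    load_labelme,
    px_to_sample,
    sample_to_px,
    split_dataset,
    write_labelme,
)

M = PixelMapping()  # 2264 px wide image of a 2160-sample signal


class TestPixelMapping:
    @pytest.mark.parametrize("px,expected", [(0, 0), (2264, 2160), (1132, 1080)])
    def test_known_positions(self, px, expected):
        assert px_to_sample(px, M) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            px_to_sample(-1, M)
        with pytest.raises(ValueError):
            px_to_sample(2265, M)

    @given(
        p1=st.floats(0, 2264, allow_nan=False),
        p2=st.floats(0, 2264, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone(self, p1, p2):
        if p1 > p2:
            p1, p2 = p2, p1
        assert px_to_sample(p1, M) <= px_to_sample(p2, M)

    @given(s=st.integers(0, 2160))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_within_one_sample(self, s):
        assert abs(px_to_sample(sample_to_px(s, M), M) - s) <= 1


class TestLabelMe:
    def test_writer_reader_round_trip(self, tmp_path, noiseless_record):
        _, _, labels = noiseless_record
        ann = labels_to_annotation(labels, record_id="rec-1")
        path = tmp_path / "rec-1.json"
        write_labelme(path, ann)
        loaded = load_labelme(path)
        assert loaded.record_id == "rec-1"
        assert [(s.label, s.start_px, s.end_px) for s in loaded.spans] == [
            (s.label, s.start_px, s.end_px) for s in ann.spans
        ]
        relabeled = annotation_to_labels(loaded)
        assert np.array_equal(relabeled.classes, labels.classes)

    def test_case_insensitive_labels(self, tmp_path):
        doc = {
            "shapes": [
                {"label": "Systole", "points": [[0, 0], [500, 10]], "shape_type": "rectangle"}
            ],
            "imageWidth": 2264,
            "imageHeight": 1296,
        }
        path = tmp_path / "a.json"
        path.write_text(json.dumps(doc))
        ann = load_labelme(path)
        assert ann.spans[0].label == "systole"

    def test_polygon_uses_x_extent(self, tmp_path):
        doc = {
            "shapes": [
                {
                    "label": "diastole",
                    "points": [[120, 5], [80, 90], [400, 50], [300, 10]],
                    "shape_type": "polygon",
                }
            ],
            "imageWidth": 2264,
        }
        path = tmp_path / "p.json"
        path.write_text(json.dumps(doc))
        span = load_labelme(path).spans[0]
        assert (span.start_px, span.end_px) == (80, 400)

    def test_unknown_label_rejected_with_name(self, tmp_path):
        doc = {"shapes": [{"label": "spike", "points": [[0, 0], [10, 1]]}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="spike"):
            load_labelme(path)

    def test_overlapping_same_class_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            AnnotationSet(
                [Span("systole", 0, 100), Span("systole", 50, 200)], mapping=M
            )


class TestRasterization:
    def test_half_width_systole_span(self):
        ann = AnnotationSet([Span("systole", 0, 1132)], mapping=M)
        labels = annotation_to_labels(ann)
        assert (labels.classes[:1080] == 1).all()
        assert (labels.classes[1080:] == 0).all()

    def test_empty_annotation_all_background(self):
        labels = annotation_to_labels(AnnotationSet([], mapping=M))
        assert len(labels) == 2160 and not labels.classes.any()

    def test_three_alternating_beats_gapless(self, noiseless_record):
        _, truths, labels = noiseless_record
        ann = labels_to_annotation(labels)
        out = annotation_to_labels(ann)
        segs = out.segments()
        assert [cls for _, _, cls in segs] == [1, 2] * len(truths)
        for (_, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            assert e1 == s2  # no gaps inside the annotated region

    def test_collapsing_span_rejected(self):
        ann = AnnotationSet([Span("systole", 10.0, 10.4)], mapping=M)
        with pytest.raises(ValueError, match="collapses"):
            annotation_to_labels(ann)


class FakeRecord:
    def __init__(self, rid, ptype):
        self.record_id = rid
        self.pulse_type = ptype


class TestSplit:
    def test_reference_sizes_1400(self):
        records = [FakeRecord(str(i), "t") for i in range(1400)]
        parts = split_dataset(records, seed=0, stratify_by_type=False)
        assert tuple(len(p) for p in parts) == (1120, 140, 140)

    def test_smallest_exact_case(self):
        records = [FakeRecord(str(i), "t") for i in range(10)]
        parts = split_dataset(records, seed=0, stratify_by_type=False)
        assert tuple(len(p) for p in parts) == (8, 1, 1)

    def test_deterministic_membership(self):
        records = [FakeRecord(str(i), "ab"[i % 2]) for i in range(20)]
        a = split_dataset(records, seed=5)
        b = split_dataset(records, seed=5)
        assert all(
            [r.record_id for r in pa] == [r.record_id for r in pb]
            for pa, pb in zip(a, b)
        )

    def test_conservation_and_disjointness(self):
        records = [FakeRecord(str(i), "abc"[i % 3]) for i in range(47)]
        train, val, test = split_dataset(records, seed=2)
        ids = [r.record_id for part in (train, val, test) for r in part]
        assert len(ids) == 47 and len(set(ids)) == 47

    def test_stratified_proportions(self):
        records = [FakeRecord(f"a{i}", "a") for i in range(40)] + [
            FakeRecord(f"b{i}", "b") for i in range(10)
        ]
        train, val, test = split_dataset(records, seed=3, stratify_by_type=True)
        assert sum(r.pulse_type == "a" for r in train) == 32
        assert sum(r.pulse_type == "b" for r in train) == 8
        assert sum(r.pulse_type == "b" for r in val) == 1

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="cannot split"):
            split_dataset([FakeRecord("1", "t")], seed=0)
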