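import numpy as np
import pytest

from conftest import random_mask_and_box
from gazefuse.backends import DetectedBox, SemanticSegmentation
from gazefuse.errors import RangeError
from gazefuse.fusion import (
    BinaryMask,
    CandidateBox,
    annotate_fixation,
    candidate_boxes,
    coverage,
    mask_at_point,
    select_box,
)
from gazefuse.taxonomy import ResolutionConfig


def seg_two_car_regions():
    """Two disjoint 'car' regions on 'road', 60x60."""
    label_map = np.zeros((60, 60), dtype=np.int32)
    label_map[5:15, 5:15] = 1
    label_map[40:50, 40:50] = 1
    return SemanticSegmentation(label_map=label_map, vocabulary={0: "road", 1: "car"})


class TestMaskAtPoint:
    def test_class_mode_on_single_region(self, simple_seg):
        mask = mask_at_point(simple_seg, 30, 50, "class")
        assert mask.source_label == "car"
        expected = np.zeros((100, 100), dtype=bool)
        expected[30:70, 20:60] = True
        assert np.array_equal(mask.pixels, expected)

    def test_component_mode_keeps_only_containing_region(self):
        mask = mask_at_point(seg_two_car_regions(), 10, 10, "component")
        assert mask.pixels[10, 10]
        assert mask.pixels.sum() == 100  # only the first 10x10 region

    def test_class_mode_unions_disjoint_regions(self):
        mask = mask_at_point(seg_two_car_regions(), 10, 10, "class")
        assert mask.pixels.sum() == 200

    def test_point_outside_frame_rejected(self, simple_seg):
        with pytest.raises(RangeError):
            mask_at_point(simple_seg, 100, 0)


class TestCoverage:
    def test_mask_filling_box_gives_one(self):
        pixels = np.zeros((20, 20), dtype=bool)
        pixels[2:12, 2:12] = True
        mask = BinaryMask(pixels, "car", "class")
        assert coverage(mask, DetectedBox(2, 2, 12, 12, "car", 0.9)) == 1.0

    def test_partial_closed_form(self):
        pixels = np.zeros((20, 20), dtype=bool)
        pixels[3:7, 2:8] = True  # 6 wide x 4 tall
        mask = BinaryMask(pixels, "car", "class")
        assert coverage(mask, DetectedBox(0, 0, 10, 10, "car", 0.9)) == 24 / 100

    def test_matches_per_pixel_brute_force(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            mask, box = random_mask_and_box(rng)
            count = sum(
                bool(mask.pixels[j, i])
                for i in range(box.x1, box.x2)
                for j in range(box.y1, box.y2)
            )
            assert coverage(mask, box) == count / box.area

    def test_invariant_under_joint_translation(self):
        rng = np.random.default_rng(7)
        pixels = np.zeros((40, 40), dtype=bool)
        pixels[5:15, 5:15] = rng.random((10, 10)) < 0.5
        pixels[7, 7] = True
        mask = BinaryMask(pixels, "car", "class")
        box = DetectedBox(4, 6, 14, 16, "car", 0.9)
        shifted_pixels = np.roll(np.roll(pixels, 9, axis=0), 11, axis=1)
        shifted_mask = BinaryMask(shifted_pixels, "car", "class")
        shifted_box = DetectedBox(4 + 11, 6 + 9, 14 + 11, 16 + 9, "car", 0.9)
        assert coverage(mask, box) == coverage(shifted_mask, shifted_box)

    def test_monotone_as_box_grows_around_contained_mask(self):
        pixels = np.zeros((50, 50), dtype=bool)
        pixels[20:30, 20:30] = True
        mask = BinaryMask(pixels, "car", "class")
        covs = [
            coverage(mask, DetectedBox(20 - g, 20 - g, 30 + g, 30 + g, "car", 0.9))
            for g in range(0, 15)
        ]
        assert all(b <= a for a, b in zip(covs, covs[1:]))
        assert covs[0] == 1.0


class TestCandidateBoxes:
    def setup_method(self):
        pixels = np.zeros((60, 60), dtype=bool)
        pixels[10:20, 10:20] = True
        self.mask = BinaryMask(pixels, "car", "class")

    def test_no_containing_box_gives_empty(self):
        boxes = [DetectedBox(30, 30, 50, 50, "car", 0.9)]
        assert candidate_boxes(boxes, 15, 15, self.mask) == []

    def test_zero_coverage_box_excluded(self):
        # contains the point's column range but no mask pixel
        pixels = np.zeros((60, 60), dtype=bool)
        pixels[50, 50] = True
        far_mask = BinaryMask(pixels, "car", "class")
        boxes = [DetectedBox(10, 10, 20, 20, "car", 0.9)]
        assert candidate_boxes(boxes, 15, 15, far_mask) == []

    def test_nested_boxes_both_retained_with_distinct_coverage(self):
        small = DetectedBox(10, 10, 20, 20, "car", 0.9)
        big = DetectedBox(0, 0, 60, 60, "person", 0.8)
        cands = candidate_boxes([small, big], 15, 15, self.mask)
        assert len(cands) == 2
        by_box = {c.box: c.coverage for c in cands}
        assert by_box[small] == 1.0
        assert by_box[big] == 100 / 3600

    def test_edge_inclusive_point_in_box(self):
        box = DetectedBox(10, 10, 20, 20, "car", 0.9)
        assert box.contains(10, 10) and box.contains(19, 19)
        assert not box.contains(20, 10) and not box.contains(9, 10)


class TestSelectBox:
    def test_tight_box_beats_large_occluder_box(self):
        """A 10x10 box equal to the mask (C=1) wins over a 100x100 (C=0.01)."""
        pixels = np.zeros((100, 100), dtype=bool)
        pixels[40:50, 40:50] = True
        mask = BinaryMask(pixels, "car", "class")
        tight = DetectedBox(40, 40, 50, 50, "car", 0.7)
        huge = DetectedBox(0, 0, 100, 100, "person", 0.99)
        cands = candidate_boxes([huge, tight], 45, 45, mask)
        best = select_box(cands)
        assert best.box == tight
        assert best.coverage == 1.0
        assert {c.box: c.coverage for c in cands}[huge] == 0.01

    def test_single_candidate_returned(self):
        c = CandidateBox(DetectedBox(0, 0, 5, 5, "car", 0.5), 0.3)
        assert select_box([c]) is c

    def test_empty_gives_none(self):
        assert select_box([]) is None

    def test_matches_exhaustive_argmax_with_tie_chain(self):
        rng = np.random.default_rng(55)
        cov_pool = [0.25, 0.5, 0.75, 1.0]
        conf_pool = [0.4, 0.8]
        for _ in range(300):
            cands = []
            for _ in range(int(rng.integers(1, 8))):
                x1 = int(rng.integers(0, 10))
                y1 = int(rng.integers(0, 10))
                w = int(rng.choice([5, 10]))
                cands.append(
                    CandidateBox(
                        DetectedBox(x1, y1, x1 + w, y1 + w, "car", float(rng.choice(conf_pool))),
                        float(rng.choice(cov_pool)),
                    )
                )
            def key(c):
                return (-c.coverage, -c.box.confidence, c.box.area, c.box.x1, c.box.y1)
            expected = min(sorted(cands, key=lambda c: rng.random()), key=key)
            got = select_box(cands)
            assert key(got) == key(expected)


class TestAnnotateFixation:
    def test_no_containing_box_defaults_to_mask_label(self, simple_seg):
        ann = annotate_fixation(0, 0.3, 0.5, simple_seg, [], resolution=ResolutionConfig())
        assert ann.mask_label == "car"
        assert ann.box_label is None
        assert ann.resolved_label == "car"
        assert ann.branch == 1

    def test_agreement_keeps_the_shared_label(self, simple_seg):
        boxes = [DetectedBox(20, 30, 60, 70, "car", 0.9)]
        ann = annotate_fixation(0, 0.3, 0.5, simple_seg, boxes)
        assert ann.resolved_label == "car"
        assert ann.branch == 2
        assert ann.coverage == 1.0

    def test_priority_class_wins_disagreement(self):
        """A small device box over a person mask resolves to the device."""
        label_map = np.zeros((100, 100), dtype=np.int32)
        label_map[20:90, 30:70] = 1  # person
        seg = SemanticSegmentation(label_map=label_map, vocabulary={0: "road", 1: "person"})
        # the person box is looser than the person mask, so its coverage < 1,
        # while the device box sits fully inside the mask (coverage 1)
        person_box = DetectedBox(25, 12, 78, 96, "person", 0.95)
        phone_box = DetectedBox(45, 50, 60, 60, "cell phone", 0.6)
        ann = annotate_fixation(
            0,
            0.5,
            0.55,
            seg,
            [person_box, phone_box],
            resolution=ResolutionConfig(priority_list=("cell phone",)),
        )
        assert ann.mask_label == "person"
        assert ann.box_label == "cell phone"  # tight box has higher coverage
        assert ann.resolved_label == "cell phone"
        assert ann.branch == 3

    def test_totality_everywhere_in_frame(self, simple_seg):
        rng = np.random.default_rng(3)
        for _ in range(100):
            ann = annotate_fixation(
                0, float(rng.random()), float(rng.random()), simple_seg, []
            )
            assert ann.resolved_label in ("road", "car")

    def test_determinism(self, simple_seg):
        boxes = [DetectedBox(10, 20, 70, 80, "car", 0.9), DetectedBox(0, 0, 100, 100, "truck", 0.9)]
        a = annotate_fixation(0, 0.31, 0.52, simple_seg, boxes)
        b = annotate_fixation(0, 0.31, 0.52, simple_seg, boxes)
        assert a == b
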