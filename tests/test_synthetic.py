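import numpy as np
import pytest

from gazefuse.backends import DetectedBox, SyntheticBackend, load_adapter
from gazefuse.errors import CapabilityError, ConfigError
from gazefuse.gaze_io import VideoMeta
from gazefuse.synthetic import (
    CorruptionSpec,
    GazePlan,
    SceneObject,
    SceneSpec,
    corrupt,
    make_exp1_scene,
    make_exp2_scene,
    plan_on_objects,
    render_scene,
    scene_from_yaml,
    scene_to_yaml,
    simulate_gaze,
)

META = VideoMeta(width=100, height=80, fps=30.0, duration=60.0)


def one_car_scene():
    return SceneSpec(
        width=100,
        height=80,
        background="road",
        objects=[SceneObject("rectangle", (20, 30, 40, 30), depth=1, seg_class="car", det_class="car")],
    )


class TestRenderScene:
    def test_empty_scene_is_all_background(self):
        r = render_scene(SceneSpec(width=50, height=40, background="road"))
        assert np.unique(r.segmentation.label_map).tolist() == [0]
        assert r.segmentation.vocabulary == {0: "road"}
        assert r.boxes == []

    def test_single_rectangle_mask_equals_box_interior(self):
        r = render_scene(one_car_scene())
        assert len(np.unique(r.segmentation.label_map)) == 2
        car_id = {v: k for k, v in r.segmentation.vocabulary.items()}["car"]
        mask = r.segmentation.label_map == car_id
        assert mask.sum() == 40 * 30
        (box,) = r.boxes
        assert (box.x1, box.y1, box.x2, box.y2) == (20, 30, 60, 60)
        assert mask[box.y1 : box.y2, box.x1 : box.x2].all()

    def test_occluded_pair_matches_painters_algorithm_oracle(self):
        spec = SceneSpec(
            width=60,
            height=60,
            background="road",
            objects=[
                SceneObject("rectangle", (10, 10, 30, 30), depth=10, seg_class="car", det_class="car"),
                SceneObject("rectangle", (25, 25, 30, 30), depth=5, seg_class="person", det_class="person"),
            ],
        )
        r = render_scene(spec)
        # brute-force per-pixel oracle: nearest (smallest depth) object wins
        name_of = {v: k for k, v in r.segmentation.vocabulary.items()}
        for y in range(60):
            for x in range(60):
                covering = [
                    o for o in spec.objects
                    if o.box[0] <= x < o.box[2] and o.box[1] <= y < o.box[3]
                ]
                expected = min(covering, key=lambda o: o.depth).seg_class if covering else "road"
                assert r.segmentation.vocabulary[int(r.segmentation.label_map[y, x])] == expected
        # masks sum to less than boxes where occlusion happened
        mask_area = (r.segmentation.label_map > 0).sum()
        box_area = sum(b.area for b in r.boxes)
        assert mask_area < box_area

    def test_mask_pixels_lie_inside_truth_boxes(self):
        spec = make_exp2_scene(seed=3)
        r = render_scene(spec)
        for idx, obj in enumerate(spec.objects):
            ys, xs = np.nonzero(r.instance_map == idx)
            if ys.size:
                x1, y1, x2, y2 = obj.box
                assert xs.min() >= x1 and xs.max() < x2
                assert ys.min() >= y1 and ys.max() < y2

    def test_vocabulary_asymmetry_representable(self):
        spec = make_exp2_scene(seed=0)
        seg_classes = {o.seg_class for o in spec.objects if o.seg_class}
        det_classes = {o.det_class for o in spec.objects if o.det_class}
        assert "building" in seg_classes - det_classes  # segmenter-only
        assert "cell phone" in det_classes - seg_classes  # detector-only
        # an object neither model names under its true class
        assert any(o.true_class == "tablet" and o.seg_class is None for o in spec.objects)

    def test_out_of_frame_geometry_rejected(self):
        with pytest.raises(ConfigError):
            SceneSpec(
                width=50,
                height=50,
                objects=[SceneObject("rectangle", (40, 40, 20, 20), depth=1, seg_class="car")],
            )

    def test_duplicate_depths_rejected(self):
        with pytest.raises(ConfigError, match="depth"):
            SceneSpec(
                width=50,
                height=50,
                objects=[
                    SceneObject("rectangle", (0, 0, 10, 10), depth=1, seg_class="car"),
                    SceneObject("rectangle", (20, 20, 10, 10), depth=1, seg_class="person"),
                ],
            )

    def test_pure_function_of_spec(self):
        a = render_scene(make_exp2_scene(seed=4))
        b = render_scene(make_exp2_scene(seed=4))
        assert np.array_equal(a.segmentation.label_map, b.segmentation.label_map)
        assert a.boxes == b.boxes
        assert np.array_equal(a.frame, b.frame)

    def test_yaml_round_trip(self, tmp_path):
        spec = make_exp2_scene(seed=5)
        scene_to_yaml(spec, tmp_path / "scene.yaml")
        assert scene_from_yaml(tmp_path / "scene.yaml") == spec


class TestSimulateGaze:
    def test_noiseless_dwell_is_constant(self):
        plan = GazePlan(targets=[(0.4, 0.6, 0.150)], noise_sigma=0.0)
        rec = simulate_gaze(plan, META, seed=0)
        assert len(rec) == 30
        assert all(s.x_norm == 0.4 and s.y_norm == 0.6 for s in rec.samples)

    def test_sample_count_tracks_total_duration(self):
        plan = GazePlan(targets=[(0.2, 0.2, 0.2), (0.8, 0.8, 0.3)], noise_sigma=0.0)
        rec = simulate_gaze(plan, META, seed=0)
        assert len(rec) == round(plan.total_duration * plan.rate_hz)

    def test_reproducible_per_seed(self):
        plan = GazePlan(targets=[(0.2, 0.2, 0.2), (0.8, 0.8, 0.3)], noise_sigma=0.01)
        a = simulate_gaze(plan, META, seed=9)
        b = simulate_gaze(plan, META, seed=9)
        c = simulate_gaze(plan, META, seed=10)
        assert a.samples == b.samples
        assert a.samples != c.samples


class TestCorrupt:
    def test_all_zero_spec_is_identity(self):
        r = render_scene(one_car_scene())
        out = corrupt(r.boxes, r.segmentation, CorruptionSpec(confidence_range=(1.0, 1.0)), seed=0)
        assert out.boxes == r.boxes
        assert np.array_equal(out.segmentation.label_map, r.segmentation.label_map)

    def test_miss_prob_one_drops_every_box(self):
        r = render_scene(one_car_scene())
        out = corrupt(r.boxes, r.segmentation, CorruptionSpec(miss_prob=1.0), seed=0)
        assert out.boxes == []

    def test_forced_swap_relabels_every_matching_box(self):
        boxes = [
            DetectedBox(0, 0, 10, 10, "tablet", 1.0),
            DetectedBox(20, 20, 30, 30, "tablet", 1.0),
            DetectedBox(40, 40, 50, 50, "car", 1.0),
        ]
        r = render_scene(SceneSpec(width=60, height=60))
        spec = CorruptionSpec(box_swap_prob=1.0, box_swap_table={"tablet": "person", "car": "truck"})
        out = corrupt(boxes, r.segmentation, spec, seed=0)
        assert [b.label for b in out.boxes] == ["person", "person", "truck"]

    def test_seg_swap_relabels_class_regions(self):
        r = render_scene(one_car_scene())
        spec = CorruptionSpec(seg_swap_prob=1.0, seg_swap_table={"car": "truck"})
        out = corrupt(r.boxes, r.segmentation, spec, seed=0)
        names = set(out.segmentation.vocabulary[i] for i in np.unique(out.segmentation.label_map))
        assert "truck" in names and "car" not in names

    def test_deterministic_per_seed(self):
        r = render_scene(make_exp2_scene(seed=2))
        spec = CorruptionSpec(miss_prob=0.4, seg_swap_prob=0.3, box_jitter_px=2, false_positive_rate=1.0)
        a = corrupt(r.boxes, r.segmentation, spec, seed=5)
        b = corrupt(r.boxes, r.segmentation, spec, seed=5)
        assert a.boxes == b.boxes
        assert np.array_equal(a.segmentation.label_map, b.segmentation.label_map)

    def test_morphology_keeps_partition(self):
        r = render_scene(make_exp1_scene(seed=1))
        for radius in (2, -2):
            out = corrupt(r.boxes, r.segmentation, CorruptionSpec(morph_radius=radius), seed=0)
            ids = set(np.unique(out.segmentation.label_map).tolist())
            assert ids <= set(out.segmentation.vocabulary)


class TestSyntheticBackend:
    def test_identical_calls_identical_outputs(self):
        spec = make_exp2_scene(seed=1)
        be = SyntheticBackend({0: spec}, corruption=CorruptionSpec(miss_prob=0.3), seed=4)
        be2 = SyntheticBackend({0: spec}, corruption=CorruptionSpec(miss_prob=0.3), seed=4)
        assert be.detect(0) == be2.detect(0)
        assert np.array_equal(be.segment(0).label_map, be2.segment(0).label_map)

    def test_unknown_frame_rejected(self):
        be = SyntheticBackend({0: one_car_scene()})
        with pytest.raises(ConfigError):
            be.segment(1)

    def test_missing_adapter_raises_capability_error(self):
        with pytest.raises(CapabilityError, match="yolo"):
            load_adapter("yolo")

    def test_unknown_backend_rejected(self):
        with pytest.raises(ConfigError):
            load_adapter("frcnn")


def test_plan_targets_land_on_their_objects():
    spec = make_exp2_scene(seed=6)
    r = render_scene(spec)
    plan, truths = plan_on_objects(r, 20, seed=1)
    assert len(plan.targets) == len(truths) == 20
    for (tx, ty, dwell), truth in zip(plan.targets, truths):
        assert 0.12 <= dwell <= 0.30
        x_px = int(tx * spec.width)
        y_px = int(ty * spec.height)
        assert r.true_class_at(x_px, y_px) == truth
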