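"""Synthetic-session generator tests: determinism, geometry, round-trips."""

import numpy as np
import pytest

from rotoloc.engine import ActivationState, step
from rotoloc.geometry import Box, DecisionConfig, ObjectClass, is_activation_position
from rotoloc.synth import (
    DetectorStub,
    SceneParams,
    ScriptError,
    SessionScript,
    box_to_yolo_line,
    procedure1_script,
    procedure2_script,
    random_scene_script,
    read_yolo_dataset,
    render_frame,
    simulate_session,
    stub_detect,
    write_yolo_dataset,
    yolo_line_to_box,
)

SCENE = SceneParams()


def _tumor(cx, cy, a, b):
    return Box(cx - a, cy - b, 2 * a, 2 * b, class_id=ObjectClass.TUMOR)


class TestRenderFrame:
    def test_deterministic_given_seed(self):
        t = _tumor(320, 200, 40, 25)
        img1, b1 = render_frame(SCENE, None, t, seed=7)
        img2, b2 = render_frame(SCENE, None, t, seed=7)
        assert np.array_equal(img1, img2)
        assert b1 == b2

    def test_zero_noise_is_reproducible_bitwise(self):
        scene = SceneParams(speckle_variance=0.0)
        t = _tumor(320, 200, 40, 25)
        img1, _ = render_frame(scene, None, t, seed=1)
        img2, _ = render_frame(scene, None, t, seed=1)
        assert np.array_equal(img1, img2)

    def test_tight_bounds_arithmetic(self):
        t = _tumor(320, 200, 40, 25)
        _, boxes = render_frame(SCENE, None, t, seed=0)
        (box,) = boxes
        assert (box.x, box.y, box.length, box.height) == (280, 175, 80, 50)

    def test_objects_painted_with_expected_contrast(self):
        scene = SceneParams(speckle_variance=0.0)
        slot = Box(100, 400, 150, 26, class_id=ObjectClass.SLOT)
        t = _tumor(320, 200, 40, 25)
        img, _ = render_frame(scene, slot, t, seed=0)
        assert img[413, 175] > 180          # inside slot: bright
        assert img[200, 320] < 60           # inside tumor: dark
        assert 30 < img[50, 50] < 150       # background: mid

    def test_out_of_frame_rejected(self):
        with pytest.raises(Exception):
            render_frame(SCENE, None, _tumor(630, 200, 40, 25), seed=0)


class TestScripts:
    def test_procedure1_flips_exactly_at_onset(self, cfg):
        script = procedure1_script(200, onset=120, scene=SCENE, cfg=cfg)
        for i in range(200):
            sat = is_activation_position(
                script.slot_boxes[i], script.tumor_boxes[i], cfg
            )
            assert sat == (i >= 120)

    def test_procedure1_visibility_invariant(self):
        script = procedure1_script(50, onset=10)
        assert all(b is not None for b in script.slot_boxes)
        assert all(b is not None for b in script.tumor_boxes)

    def test_procedure2_alternating_visibility(self, cfg):
        script = procedure2_script(cfg=cfg)
        for s, t in zip(script.slot_boxes, script.tumor_boxes):
            assert not (s is not None and t is not None)

    def test_procedure2_expected_prompt_frame(self, cfg):
        """The scripted expectation matches the engine run on ground truth."""
        small = DecisionConfig(overlap_frames_required=40, slot_confirm_frames=5)
        script = procedure2_script(slot_block=10, tumor_block=25, cfg=small)
        state = ActivationState.initial(2)
        fired = None
        from rotoloc.engine import FramePacket

        for i in range(script.n_frames):
            state, e = step(
                state, FramePacket(i, detections=tuple(script.ground_truth(i))), small
            )
            if e is not None:
                fired = e.frame_index
        assert fired == script.expected_prompt_frame

    def test_co_visibility_rejected_in_lateral_script(self):
        slot = Box(10, 10, 50, 20, class_id=ObjectClass.SLOT)
        tum = _tumor(300, 300, 40, 30)
        with pytest.raises(ScriptError):
            SessionScript(2, (slot,), (tum,), None, None)

    def test_script_json_round_trip(self, tmp_path):
        script = procedure1_script(30, onset=10)
        path = tmp_path / "s.json"
        script.to_json(path)
        back = SessionScript.from_json(path)
        assert back.slot_boxes == script.slot_boxes
        assert back.expected_prompt_frame == script.expected_prompt_frame

    def test_zero_frame_script_yields_empty_stream(self):
        script = SessionScript(1, (), (), None, None)
        assert list(simulate_session(script)) == []


class TestSimulateSession:
    def test_deterministic_given_seed(self):
        script = procedure1_script(10, onset=5)
        scene = SceneParams(jitter=2.0)
        a = [(p.frame_index, tuple(gt)) for p, gt, _ in simulate_session(script, scene, seed=3)]
        b = [(p.frame_index, tuple(gt)) for p, gt, _ in simulate_session(script, scene, seed=3)]
        assert a == b

    def test_rendered_images_align_with_ground_truth(self):
        script = procedure1_script(3, onset=1)
        for packet, gt, img in simulate_session(script, SCENE, seed=0, render=True):
            assert img is not None and img.shape == (640, 640)
            assert len(gt) == 2


class TestDetectorStub:
    def test_zero_noise_returns_exact_ground_truth(self):
        gt = [_tumor(320, 200, 40, 25)]
        out = stub_detect(DetectorStub(), gt, frame_index=0)
        assert len(out) == 1
        assert out[0].x == gt[0].x and out[0].confidence == 1.0

    def test_total_miss(self):
        gt = [_tumor(320, 200, 40, 25)]
        assert stub_detect(DetectorStub(miss_prob=1.0), gt, 0) == []

    def test_miss_rate_matches_binomial_expectation(self):
        """10^4 object draws at miss probability 0.1 -> miss rate 0.1 +- 0.01."""
        stub = DetectorStub(miss_prob=0.1, seed=11)
        gt = [_tumor(320, 200, 40, 25)]
        missed = sum(
            not stub_detect(stub, gt, frame_index=i) for i in range(10_000)
        )
        assert missed / 10_000 == pytest.approx(0.1, abs=0.01)

    def test_false_positive_rate(self):
        stub = DetectorStub(fp_rate=0.5, seed=5)
        counts = [len(stub_detect(stub, [], i)) for i in range(4000)]
        assert np.mean(counts) == pytest.approx(0.5, abs=0.05)

    def test_deterministic_per_frame(self):
        stub = DetectorStub(noise_sd=2.0, miss_prob=0.2, fp_rate=0.3, seed=9)
        gt = [_tumor(320, 200, 40, 25)]
        assert stub_detect(stub, gt, 17) == stub_detect(stub, gt, 17)


class TestYoloDataset:
    def test_label_normalization_arithmetic(self):
        b = Box(280, 175, 80, 50, class_id=ObjectClass.TUMOR)
        assert box_to_yolo_line(b, 640, 640) == "1 0.500000 0.312500 0.125000 0.078125"

    def test_line_round_trip(self):
        b = Box(280, 175, 80, 50, class_id=ObjectClass.TUMOR)
        back = yolo_line_to_box(box_to_yolo_line(b, 640, 640), 640, 640)
        assert back.x == pytest.approx(b.x, abs=0.5)
        assert back.length == pytest.approx(b.length, abs=0.5)

    def test_dataset_round_trip_and_empty_label_files(self, tmp_path):
        rng = np.random.default_rng(0)
        scene = SceneParams(width=320, height=320,
                            tumor_axes=(30, 20), slot_size=(80, 18))
        sessions = [
            ("patA", random_scene_script(rng, scene)),
            ("patB", SessionScript(1, (None,), (None,), None, None)),  # empty frame
        ]
        out = tmp_path / "ds"
        manifest = write_yolo_dataset(sessions, out, scene, seed=0)
        assert manifest["n_images"] == 2
        label_files = sorted((out / "labels").glob("*.txt"))
        assert len(label_files) == 2          # empty frame still gets a file
        assert label_files[1].read_text() == ""
        boxes, patients, _ = read_yolo_dataset(out)
        assert set(patients.values()) == {"patA", "patB"}
        orig = sessions[0][1].ground_truth(0)
        got = sorted(boxes[sorted(boxes)[0]], key=lambda b: b.class_id)
        orig = sorted(orig, key=lambda b: b.class_id)
        for o, g in zip(orig, got):
            assert g.x == pytest.approx(o.x, abs=0.5)
            assert g.y == pytest.approx(o.y, abs=0.5)
            assert g.length == pytest.approx(o.length, abs=0.5)
            assert g.height == pytest.approx(o.height, abs=0.5)
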