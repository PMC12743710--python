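"""Greedy box refinement: monotonicity, convergence, exhaustive-search agreement."""

import numpy as np
import pytest

from cxrseg import (
    OracleDetector,
    OracleSegmenter,
    RefineConfig,
    refine_all,
    refine_box,
    tight_box,
)
from cxrseg.refine import RefinementError


def exhaustive_translation_optimum(image, box, segmenter, radius):
    """Objective max over every integer translation within +/-radius."""
    best = -1.0
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            cand = box.translate(dx, dy).clip_to(image.shape)
            if cand is None:
                continue
            v = segmenter.segment_raw(image, cand).candidates[0][1]
            best = max(best, v)
    return best


class TestRefineBox:
    def test_fixed_point_at_optimum(self, phantom128):
        _, image, masks = phantom128
        box = tight_box(masks["right"])
        trace = refine_box(image, box, OracleSegmenter())
        assert trace.converged
        assert trace.n_sweeps == 1
        assert trace.final_box.to_dict() == pytest.approx(box.to_dict())
        assert trace.records[-1].move == (0, 0, 1.0)

    def test_recovers_from_known_offset_to_exhaustive_optimum(self, phantom64):
        """Initial box displaced by (10, 0): greedy must reach the best box
        on the translation lattice (independent exhaustive-search oracle)."""
        _, image, masks = phantom64
        seg = OracleSegmenter()
        box = tight_box(masks["right"]).translate(10, 0)
        trace = refine_box(image, box, seg, RefineConfig())
        optimum = exhaustive_translation_optimum(image, box, seg, radius=12)
        assert trace.final_objective == pytest.approx(optimum)
        assert trace.final_objective == 1.0

    def test_single_iteration_budget_does_one_sweep(self, phantom64):
        _, image, masks = phantom64
        box = tight_box(masks["right"]).translate(10, 5)
        trace = refine_box(image, box, OracleSegmenter(), RefineConfig(max_iterations=1))
        assert trace.n_sweeps == 1
        assert not trace.converged or trace.records[-1].move == (0, 0, 1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_sequence_monotone_and_never_worse(self, phantom128, seed):
        _, image, masks = phantom128
        rng = np.random.default_rng(seed)
        dx, dy = rng.integers(-15, 16, size=2)
        box = tight_box(masks["left"]).translate(int(dx), int(dy)).clip_to(image.shape)
        trace = refine_box(image, box, OracleSegmenter())
        objs = trace.objectives
        assert all(b >= a for a, b in zip(objs, objs[1:]))
        assert trace.final_objective >= trace.initial_objective

    def test_boxes_stay_inside_image(self, phantom64):
        _, image, masks = phantom64
        h, w = image.shape
        box = tight_box(masks["right"]).translate(-8, -8).clip_to(image.shape)
        trace = refine_box(image, box, OracleSegmenter())
        for rec in trace.records:
            assert 0 <= rec.box.x_min < rec.box.x_max <= w
            assert 0 <= rec.box.y_min < rec.box.y_max <= h

    def test_deterministic_traces(self, phantom64):
        _, image, masks = phantom64
        box = tight_box(masks["left"]).translate(7, -4)
        t1 = refine_box(image, box, OracleSegmenter())
        t2 = refine_box(image, box, OracleSegmenter())
        assert [r.to_dict() for r in t1.records] == [r.to_dict() for r in t2.records]

    def test_detector_confidence_objective(self, phantom64):
        _, image, masks = phantom64
        det = OracleDetector(masks)
        box = tight_box(masks["right"]).translate(5, 0)
        cfg = RefineConfig(objective="detector_confidence")
        trace = refine_box(image, box, None, cfg, detector=det, phrase="right lung")
        assert trace.final_objective == pytest.approx(1.0)
        ref = tight_box(masks["right"])
        assert trace.final_box.x_min == ref.x_min

    def test_bpiou_objective_against_reference(self, phantom64):
        _, image, masks = phantom64
        cfg = RefineConfig(objective="bpiou_vs_reference", reference_mask=masks["left"])
        box = tight_box(masks["left"]).translate(-5, 2)
        trace = refine_box(image, box, OracleSegmenter(), cfg)
        assert trace.final_objective >= trace.initial_objective
        assert trace.final_objective == 1.0

    def test_objective_failure_carries_partial_trace(self, phantom64):
        _, image, masks = phantom64

        class FailsLater:
            backend_id = "stub"

            def __init__(self):
                self.calls = 0

            def segment_raw(self, image, box):
                self.calls += 1
                if self.calls > 3:
                    raise RuntimeError("boom")
                from cxrseg import SegmentationResult

                return SegmentationResult([(np.zeros(image.shape, bool), 0.1)], box)

        box = tight_box(masks["right"])
        with pytest.raises(RefinementError) as err:
            refine_box(image, box, FailsLater())
        assert len(err.value.partial_trace.records) >= 1

    def test_trace_serializes_to_jsonl(self, phantom64, tmp_path):
        _, image, masks = phantom64
        trace = refine_box(image, tight_box(masks["right"]), OracleSegmenter())
        path = tmp_path / "trace.jsonl"
        trace.to_jsonl(path)
        import json

        lines = [json.loads(l) for l in path.read_text().splitlines()]
        assert len(lines) == len(trace.records)
        assert lines[0]["iteration"] == 0


class TestRefineConfig:
    def test_identity_move_required(self):
        with pytest.raises(ValueError):
            RefineConfig(translation_steps=(2, 5))
        with pytest.raises(ValueError):
            RefineConfig(scale_steps=(0.9,))

    def test_move_order_identity_then_magnitude_then_x_axis(self):
        moves = RefineConfig(translation_steps=(0, 2, 5)).moves()
        assert moves[0] == (0, 0, 1.0)
        mags = [dx * dx + dy * dy for dx, dy, _ in moves[1:]]
        assert mags == sorted(mags)
        # equal magnitude: pure-x moves precede pure-y moves
        i_x = moves.index((2, 0, 1.0))
        i_y = moves.index((0, 2, 1.0))
        assert i_x < i_y

    def test_scale_steps_resize_the_box(self, phantom64):
        _, image, masks = phantom64
        seg = OracleSegmenter()
        small = tight_box(masks["right"])
        shrunk = type(small)(
            small.x_min + 3, small.y_min + 5, small.x_max - 3, small.y_max - 5
        )
        cfg = RefineConfig(translation_steps=(0, 2), scale_steps=(1.0, 1.15, 1.3))
        trace = refine_box(image, shrunk, seg, cfg)
        assert trace.final_objective > trace.initial_objective
        assert trace.final_box.area > shrunk.area


class TestRefineAll:
    def test_boxes_at_optima_all_converge_immediately(self, phantom128):
        _, image, masks = phantom128
        boxes = [tight_box(masks["right"]), tight_box(masks["left"])]
        traces = refine_all(image, boxes, OracleSegmenter())
        assert all(t.converged and t.n_sweeps == 1 for t in traces)

    def test_singleton_list_matches_refine_box(self, phantom64):
        _, image, masks = phantom64
        box = tight_box(masks["right"]).translate(4, 4)
        single = refine_box(image, box, OracleSegmenter())
        batch = refine_all(image, [box], OracleSegmenter())
        assert [r.to_dict() for r in batch[0].records] == [
            r.to_dict() for r in single.records
        ]

    def test_empty_list_rejected(self, phantom64):
        _, image, _ = phantom64
        with pytest.raises(ValueError):
            refine_all(image, [], OracleSegmenter())

    def test_per_box_error_carries_index(self, phantom64):
        _, image, masks = phantom64
        from cxrseg import BoundingBox

        good = tight_box(masks["right"])
        bad = BoundingBox(500, 500, 600, 600)
        with pytest.raises(RefinementError, match="box 1"):
            refine_all(image, [good, bad], OracleSegmenter())
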