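"""Segmentation-evaluation metrics against brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mams_quant import seg_eval
from mams_quant.seg_eval import Detection, average_precision, instance_iou, match_and_score
from mams_quant.types import OrganelleInstance

from conftest import rect_mask


SHAPE = (64, 64)


def det(fp, score, cls="mitochondrion"):
    return Detection(fp, cls, score)


def test_iou_identical_disjoint_and_shifted():
    a = rect_mask(10, 10, 10, 10, SHAPE)
    b = rect_mask(10, 15, 10, 10, SHAPE)  # 5-px horizontal shift
    c = rect_mask(40, 40, 10, 10, SHAPE)
    assert instance_iou(a, a) == 1.0
    assert instance_iou(a, c) == 0.0
    assert instance_iou(a, b) == pytest.approx(50 / 150)
    with pytest.raises(ValueError):
        instance_iou(np.zeros(SHAPE, bool), np.zeros(SHAPE, bool))


def test_perfect_detections_score_one():
    refs = [rect_mask(5, 5, 8, 8, SHAPE), rect_mask(30, 30, 8, 8, SHAPE)]
    dets = [det(r, 1.0) for r in refs]
    res = match_and_score(dets, refs, 0.5)
    assert res.precision == res.recall == 1.0
    assert res.dice_matched == 1.0 and res.miou == 1.0


def test_no_detections_convention():
    refs = [rect_mask(5, 5, 8, 8, SHAPE)]
    res = match_and_score([], refs, 0.5)
    assert res.recall == 0.0
    assert res.precision == 1.0
    assert any("convention" in n for n in res.notes)


def test_greedy_matching_equals_hungarian_on_separated_toy():
    """3 references, 4 detections with well-separated IoUs: greedy matching
    must reach the optimal-assignment TP count."""
    refs = [
        rect_mask(4, 4, 10, 10, SHAPE),
        rect_mask(24, 24, 10, 10, SHAPE),
        rect_mask(44, 44, 10, 10, SHAPE),
    ]
    dets = [
        det(rect_mask(4, 5, 10, 10, SHAPE), 0.9),   # good match ref0
        det(rect_mask(24, 25, 10, 10, SHAPE), 0.8),  # good match ref1
        det(rect_mask(44, 46, 10, 10, SHAPE), 0.7),  # good match ref2
        det(rect_mask(4, 40, 10, 10, SHAPE), 0.95),  # spurious
    ]
    res = match_and_score(dets, refs, 0.5)
    iou = np.array([[instance_iou(d.footprint, r) for r in refs] for d in dets])
    rows, cols = linear_sum_assignment(-iou)
    optimal_tp = sum(iou[r, c] >= 0.5 for r, c in zip(rows, cols))
    assert (res.tp, res.fp, res.fn) == (optimal_tp, 4 - optimal_tp, 3 - optimal_tp)


def test_ap_hand_calculation_two_detections_one_reference():
    """Spurious top-scored detection, then the true one: precision at full
    recall is 1/2, so AP = 0.5."""
    ref = rect_mask(10, 10, 10, 10, SHAPE)
    dets = [
        det(rect_mask(40, 40, 10, 10, SHAPE), 0.95),  # spurious
        det(ref, 0.9),
    ]
    assert average_precision(dets, [ref], 0.5) == pytest.approx(0.5)


def test_ap_all_correct_is_one_for_any_scores():
    rng = np.random.default_rng(0)
    refs = [rect_mask(4 + 12 * i, 4, 8, 8, SHAPE) for i in range(4)]
    for _ in range(5):
        scores = rng.random(4)
        dets = [det(r, s) for r, s in zip(refs, scores)]
        assert average_precision(dets, refs, 0.5) == pytest.approx(1.0)


def _staircase_ap_oracle(tp_flags_in_score_order, n_refs):
    """Independent all-points AP: direct O(n^2) max-precision-to-the-right."""
    tp = np.asarray(tp_flags_in_score_order, dtype=float)
    n = len(tp)
    ap, r_prev = 0.0, 0.0
    for i in range(n):
        recall = tp[: i + 1].sum() / n_refs
        best_p = max(
            tp[: j + 1].sum() / (j + 1) for j in range(i, n)
        )
        ap += (recall - r_prev) * best_p
        r_prev = recall
    return ap


def test_ap_matches_staircase_enumeration_on_random_toys():
    rng = np.random.default_rng(1)
    for trial in range(10):
        n_refs = int(rng.integers(2, 6))
        refs = [rect_mask(2 + 12 * i, 2, 8, 8, SHAPE) for i in range(n_refs)]
        dets = []
        for i in range(n_refs):
            if rng.random() < 0.7:  # true detection
                dets.append(det(refs[i], float(rng.random())))
        for _ in range(int(rng.integers(0, 4))):  # spurious
            dets.append(det(rect_mask(50, 2 + 12 * int(rng.integers(0, 4)), 8, 8, SHAPE),
                            float(rng.random())))
        if not dets:
            continue
        ap = average_precision(dets, refs, 0.5)
        res = match_and_score(dets, refs, 0.5)
        order = np.argsort([-d.score for d in dets], kind="stable")
        flags = [res.det_is_tp[i] for i in order]
        assert ap == pytest.approx(_staircase_ap_oracle(flags, n_refs), abs=1e-12)


def test_ap_non_increasing_in_iou_threshold():
    rng = np.random.default_rng(2)
    refs = [rect_mask(4 + 14 * i, 4, 10, 10, SHAPE) for i in range(4)]
    dets = [
        det(rect_mask(4 + 14 * i, 4 + int(rng.integers(0, 6)), 10, 10, SHAPE),
            float(rng.random()))
        for i in range(4)
    ]
    aps = [average_precision(dets, refs, t) for t in seg_eval.IOU_GRID]
    assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))


def test_ap_zero_references_reported_missing():
    assert average_precision([det(rect_mask(2, 2, 4, 4, SHAPE), 1.0)], [], 0.5) is None


def test_self_evaluation_all_metrics_one(phantom_field):
    _, _, instances, _ = phantom_field
    refs = [i for i in instances if i.organelle_class in ("mitochondrion", "ER")]
    dets = [det(i.footprint, 1.0, i.organelle_class) for i in refs]
    report = seg_eval.evaluate_detections(dets, refs)
    assert report.mean_ap == 1.0
    assert report.miou == 1.0
    assert report.dice_matched == 1.0
    assert report.precision == 1.0 and report.recall == 1.0
    assert all(v == 1.0 for v in report.dice_pixel.values())


def test_baseline_segments_clean_phantom_with_high_dice():
    from mams_quant.phantom import PhantomSpec, generate_field

    spec = PhantomSpec(
        n_mitochondria=4, noise_sd=0.0, blur_sigma_px=0.5,
        er_gap_nm=(40.0,), er_overlap_nm=(500.0,), seed=21,
    )
    field, instances, _ = generate_field(spec)
    dets = seg_eval.baseline_segment(field)
    mito_refs = [i for i in instances if i.organelle_class == "mitochondrion"]
    for ref in mito_refs:
        dices = [
            2 * np.logical_and(d.footprint, ref.footprint).sum()
            / (d.footprint.sum() + ref.footprint.sum())
            for d in dets
        ]
        assert max(dices) >= 0.9


def test_baseline_on_pure_noise_yields_few_spurious():
    from mams_quant.phantom import PhantomSpec, generate_field

    field, _, _ = generate_field(PhantomSpec(n_mitochondria=0, seed=5))
    dets = seg_eval.baseline_segment(field)
    assert len(dets) <= 2


def test_baseline_deterministic(phantom_field):
    _, field, _, _ = phantom_field
    d1 = seg_eval.baseline_segment(field)
    d2 = seg_eval.baseline_segment(field)
    assert len(d1) == len(d2)
    for a, b in zip(d1, d2):
        assert a.score == b.score and np.array_equal(a.footprint, b.footprint)
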