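"""Mask assembly, postprocessing, matching and average precision."""

import numpy as np
import pytest

from podkit.arch_builder import PodkitError, ShapeMismatchError
from podkit.mask_eval import (
    EvalReport, InstancePrediction, PostprocessConfig, PrototypeBundle,
    assemble_instance_masks, average_precision, box_iou, coco_gt_to_masks,
    evaluate_dataset, mask_iou, masks_to_coco_gt, match_instances, postprocess,
    rle_decode, rle_encode,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _pred(box, conf, mask=None, coeff=None):
    return InstancePrediction(box=box, confidence=conf, coefficients=coeff,
                              mask=mask)


def _blob(h, w, ys, xs):
    m = np.zeros((h, w), dtype=bool)
    m[ys, xs] = True
    return m


# ---------------------------------------------------------------------------
# mask assembly
# ---------------------------------------------------------------------------

def test_zero_planes_give_empty_mask_under_strict_threshold():
    # logistic(0) = 0.5 exactly; binarisation is strict > 0.5
    b = PrototypeBundle(np.zeros((1, 6, 6)))
    p = _pred((0, 0, 6, 6), 0.9, coeff=np.array([3.0]))
    assemble_instance_masks(b, [p])
    assert not p.mask.any()


@pytest.mark.parametrize("seed", range(12))
def test_assembly_matches_per_pixel_brute_force(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 5))
    h, w = int(rng.integers(3, 9)), int(rng.integers(3, 9))
    planes = rng.standard_normal((k, h, w))
    coeff = rng.standard_normal(k)
    x1, y1 = rng.uniform(0, w - 1), rng.uniform(0, h - 1)
    box = (x1, y1, x1 + rng.uniform(1, w - x1), y1 + rng.uniform(1, h - y1))
    p = _pred(box, 0.8, coeff=coeff)
    assemble_instance_masks(PrototypeBundle(planes), [p])
    # independent double-loop oracle
    expected = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            s = 0.0
            for j in range(k):
                s += coeff[j] * planes[j, r, c]
            inside_box = (int(np.floor(box[0])) <= c < int(np.ceil(box[2])) and
                          int(np.floor(box[1])) <= r < int(np.ceil(box[3])))
            expected[r, c] = inside_box and (_sigmoid(s) > 0.5)
    assert np.array_equal(p.mask, expected)


def test_assembled_mask_never_leaks_outside_box():
    rng = np.random.default_rng(5)
    planes = rng.standard_normal((2, 8, 8)) * 4
    p = _pred((2.0, 3.0, 5.0, 7.0), 0.9, coeff=np.array([2.0, -1.0]))
    assemble_instance_masks(PrototypeBundle(planes), [p])
    outside = np.ones((8, 8), dtype=bool)
    outside[3:7, 2:5] = False
    assert not p.mask[outside].any()


def test_assembly_rejects_coefficient_length_mismatch():
    b = PrototypeBundle(np.zeros((3, 4, 4)))
    p = _pred((0, 0, 4, 4), 0.5, coeff=np.array([1.0, 2.0]))
    with pytest.raises(ShapeMismatchError):
        assemble_instance_masks(b, [p])


# ---------------------------------------------------------------------------
# postprocessing
# ---------------------------------------------------------------------------

def test_nms_collapses_duplicate_boxes():
    preds = [_pred((0, 0, 10, 10), 0.9), _pred((0, 0, 10, 10), 0.8)]
    kept = postprocess(preds, PostprocessConfig())
    assert len(kept) == 1 and kept[0].confidence == 0.9


def test_confidence_threshold_drops_everything_below():
    preds = [_pred((0, 0, 4, 4), 0.29), _pred((5, 5, 9, 9), 0.1)]
    assert postprocess(preds, PostprocessConfig()) == []


def test_greedy_nms_hand_case_three_boxes():
    # pairwise IoUs: (a,b)=0.6 -> b suppressed; c survives (IoU 0.1 with a)
    a = _pred((0.0, 0.0, 10.0, 8.0), 0.9)
    b = _pred((0.0, 2.0, 10.0, 10.0), 0.8)
    c = _pred((11.0, 0.0, 16.0, 12.0), 0.7)
    assert box_iou(a.box, b.box) == pytest.approx(0.6)
    assert box_iou(a.box, c.box) < 0.15 and box_iou(b.box, c.box) < 0.15
    kept = postprocess([a, b, c], PostprocessConfig())
    assert [p.confidence for p in kept] == [0.9, 0.7]


# ---------------------------------------------------------------------------
# IoU and matching
# ---------------------------------------------------------------------------

def test_mask_iou_basics():
    m = _blob(4, 4, [0, 1], [0, 1])
    assert mask_iou(m, m) == 1.0
    assert mask_iou(m, _blob(4, 4, [3], [3])) == 0.0
    a = _blob(2, 2, [0, 0], [0, 1])
    b = _blob(2, 2, [0, 1], [1, 1])
    assert mask_iou(a, b) == pytest.approx(1 / 3)
    assert mask_iou(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0
    with pytest.raises(ShapeMismatchError):
        mask_iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


def test_match_perfect_predictions():
    truths = [_blob(8, 8, [1, 2], [1, 1]), _blob(8, 8, [5, 6], [5, 5])]
    preds = [_pred((0, 0, 3, 4), 0.9, mask=truths[0]),
             _pred((4, 4, 7, 8), 0.8, mask=truths[1])]
    r = match_instances(preds, truths, 0.5)
    assert (r.tp, r.fp, r.fn) == (2, 0, 0)


def test_match_no_predictions():
    truths = [_blob(4, 4, [0], [0]), _blob(4, 4, [3], [3])]
    r = match_instances([], truths, 0.5)
    assert (r.tp, r.fp, r.fn) == (0, 0, 2)


def test_match_greedy_confidence_order():
    # higher-confidence prediction claims the single truth despite lower IoU
    truth = np.zeros((10, 10), dtype=bool)
    truth[0:5, 0:4] = True  # 20 px
    m_iou06 = np.zeros_like(truth)
    m_iou06[0:5, 0:3] = True  # IoU 15/20 = 0.75 -> adjust to ~0.6 below
    m_iou06[5:7, 0:2] = True  # adds 4 fp px: inter 15, union 29 -> 0.52
    m_conf95 = np.zeros_like(truth)
    m_conf95[0:5, 0:4] = True
    m_conf95[5:9, 0:2] = True  # inter 20, union 28 -> 0.71
    p_low = _pred((0, 0, 4, 7), 0.9, mask=m_iou06)
    p_high = _pred((0, 0, 4, 9), 0.95, mask=m_conf95)
    r = match_instances([p_low, p_high], [truth], 0.5)
    assert (r.tp, r.fp, r.fn) == (1, 1, 0)
    assert r.matches[0][0] == 1  # the conf-0.95 prediction matched


def test_match_conserves_counts_on_random_sets(rng):
    for _ in range(5):
        truths = [_blob(12, 12, rng.integers(0, 12, 4), rng.integers(0, 12, 4))
                  for _ in range(int(rng.integers(1, 5)))]
        preds = [_pred((0, 0, 12, 12), float(rng.uniform(0.1, 1.0)),
                       mask=_blob(12, 12, rng.integers(0, 12, 4),
                                  rng.integers(0, 12, 4)))
                 for _ in range(int(rng.integers(0, 6)))]
        r = match_instances(preds, truths, 0.5)
        assert r.tp + r.fn == len(truths)
        assert r.tp + r.fp == len(preds)


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def _two_truth_dataset():
    t1 = _blob(10, 10, [1, 1, 2], [1, 2, 1])
    t2 = _blob(10, 10, [7, 7, 8], [7, 8, 7])
    far = _blob(10, 10, [4], [9])
    preds = [_pred((0, 0, 4, 4), 0.9, mask=t1),      # rank 1: TP
             _pred((8, 3, 10, 6), 0.8, mask=far),    # rank 2: FP
             _pred((6, 6, 10, 10), 0.7, mask=t2)]    # rank 3: TP
    return [(preds, [t1, t2])]


def test_perfect_ranking_gives_unit_ap():
    t1 = _blob(6, 6, [1], [1])
    t2 = _blob(6, 6, [4], [4])
    preds = [_pred((0, 0, 3, 3), 0.9, mask=t1), _pred((3, 3, 6, 6), 0.8, mask=t2)]
    assert average_precision([(preds, [t1, t2])], 0.5) == 1.0


def test_no_predictions_gives_zero_ap():
    assert average_precision([([], [_blob(4, 4, [1], [1])])], 0.5) == 0.0


def test_ap_matches_hand_enumerated_pr_curve():
    # ranks (TP, FP, TP) over 2 truths: precision 1, 1/2, 2/3 at recall
    # 1/2, 1/2, 1 -> 101-point AP = (51*1 + 50*(2/3)) / 101
    expected = (51 + 50 * (2 / 3)) / 101
    assert average_precision(_two_truth_dataset(), 0.5) == pytest.approx(expected)


def test_ap_undefined_without_ground_truth():
    with pytest.raises(PodkitError):
        average_precision([([], [])], 0.5)


def test_appending_lowest_rank_fp_never_increases_ap():
    per_image = _two_truth_dataset()
    base = average_precision(per_image, 0.5)
    preds, truths = per_image[0]
    worse = preds + [_pred((0, 5, 3, 9), 0.05, mask=_blob(10, 10, [6], [1]))]
    assert average_precision([(worse, truths)], 0.5) <= base


def test_ap_invariant_to_equal_confidence_input_order():
    t1 = _blob(8, 8, [1, 2], [1, 1])
    t2 = _blob(8, 8, [5, 6], [6, 6])
    a = _pred((0, 0, 3, 4), 0.5, mask=t1)
    b = _pred((5, 4, 8, 8), 0.5, mask=t2)
    ap1 = average_precision([([a, b], [t1, t2])], 0.5)
    ap2 = average_precision([([b, a], [t1, t2])], 0.5)
    assert ap1 == ap2


def test_map50_95_never_exceeds_map50(easy_scenes):
    # imperfect predictions derived from ground truth with erosion noise
    rng = np.random.default_rng(1)
    per_image = []
    for sc in easy_scenes[:6]:
        preds = []
        for ann in sc.annotations:
            m = ann.mask.copy()
            ys, xs = np.nonzero(m)
            drop = rng.random(len(ys)) < 0.25
            m[ys[drop], xs[drop]] = False
            if not m.any():
                continue
            preds.append(_pred(ann.box, float(rng.uniform(0.4, 1.0)), mask=m))
        per_image.append((preds, [a.mask for a in sc.annotations]))
    rep = evaluate_dataset(per_image, 0.5)
    assert rep.map50_95 <= rep.map50
    assert 0.0 <= rep.map50_95 <= rep.map50 <= 1.0


def test_eval_report_validates_ranges():
    with pytest.raises(Exception):
        EvalReport(precision=1.2, recall=0.0, map50=0.0, map50_95=0.0)


# ---------------------------------------------------------------------------
# COCO-style interchange
# ---------------------------------------------------------------------------

def test_rle_roundtrip(rng):
    m = rng.random((13, 9)) > 0.6
    assert np.array_equal(rle_decode(rle_encode(m)), m)


def test_coco_gt_roundtrip():
    masks = {0: [_blob(6, 8, [1, 2], [3, 3]), _blob(6, 8, [4], [0])]}
    doc = masks_to_coco_gt(masks)
    back = coco_gt_to_masks(doc)
    assert all(np.array_equal(a, b) for a, b in zip(masks[0], back[0]))
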