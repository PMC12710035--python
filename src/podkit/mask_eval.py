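"""Prototype-coefficient mask assembly and instance-segmentation evaluation.

An instance mask is the logistic transform of a linear combination of k
prototype planes, cropped to the instance box and binarised (strict > 0.5).
Evaluation follows the common mask-benchmark protocol: greedy one-to-one
matching by *mask* IoU at a threshold (box IoU is used only inside NMS),
precision/recall from TP/FP/FN counts, and 101-point interpolated average
precision — mAP@50 at IoU 0.5 and mAP@50-95 averaged over IoU 0.50:0.05:0.95.

Conventions (pinned by tests):
* boxes are (x1, y1, x2, y2) pixels, 0-based, half-open;
* empty-vs-empty mask IoU is defined as 1.0;
* confidence ties break by input order, IoU ties by truth index;
* NMS suppresses boxes with IoU strictly greater than the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .arch_builder import PodkitError, InvalidConfigError, ShapeMismatchError

__all__ = [
    "PrototypeBundle", "InstancePrediction", "MatchResult", "EvalReport",
    "PostprocessConfig", "assemble_instance_masks", "postprocess",
    "mask_iou", "box_iou", "match_instances", "average_precision",
    "evaluate_dataset", "predictions_to_coco", "coco_to_predictions",
    "masks_to_coco_gt", "coco_gt_to_masks", "rle_encode", "rle_decode",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class PrototypeBundle:
    """k real-valued prototype planes of identical spatial size."""

    planes: np.ndarray  # (k, h, w)

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise InvalidConfigError(
                f"prototype planes must be (k, h, w) with k >= 1, got {self.planes.shape}")

    @property
    def k(self) -> int:
        return self.planes.shape[0]


@dataclass
class InstancePrediction:
    box: tuple[float, float, float, float]
    confidence: float
    coefficients: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise InvalidConfigError(f"degenerate box {self.box}")
        if not (0.0 <= self.confidence <= 1.0):
            raise InvalidConfigError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    matches: tuple[tuple[int, int, float], ...]  # (pred index, truth index, IoU)


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    map50: float
    map50_95: float

    def __post_init__(self) -> None:
        for name in ("precision", "recall", "map50", "map50_95"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall,
                "map50": self.map50, "map50_95": self.map50_95}


@dataclass(frozen=True)
class PostprocessConfig:
    conf_threshold: float = 0.3
    iou_threshold: float = 0.5
    mask_binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("conf_threshold", "iou_threshold", "mask_binarize_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InvalidConfigError(f"{name}={v} outside (0, 1)")


# ---------------------------------------------------------------------------
# mask assembly
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def assemble_instance_masks(protos: PrototypeBundle,
                            preds: list[InstancePrediction],
                            binarize_threshold: float = 0.5
                            ) -> list[InstancePrediction]:
    """Combine prototypes with per-instance coefficients into binary masks.

    Per pixel: ``logistic(sum_j coeff_j * plane_j)``, cropped to the instance
    box (outside set to 0) and binarised strictly above the threshold.
    """
    h, w = protos.planes.shape[1:]
    out = []
    for p in preds:
        coeff = np.asarray(p.coefficients, dtype=np.float64)
        if coeff.shape != (protos.k,):
            raise ShapeMismatchError(
                f"coefficient length {coeff.shape} does not match k={protos.k}")
        prob = _sigmoid(np.tensordot(coeff, protos.planes, axes=(0, 0)))
        mask = prob > binarize_threshold
        x1, y1, x2, y2 = p.box
        keep = np.zeros((h, w), dtype=bool)
        ys = slice(max(int(np.floor(y1)), 0), min(int(np.ceil(y2)), h))
        xs = slice(max(int(np.floor(x1)), 0), min(int(np.ceil(x2)), w))
        keep[ys, xs] = True
        p.mask = mask & keep
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# postprocessing
# ---------------------------------------------------------------------------

def box_iou(a, b) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def postprocess(preds: list[InstancePrediction],
                cfg: PostprocessConfig = PostprocessConfig()
                ) -> list[InstancePrediction]:
    """Confidence filtering followed by greedy box NMS (descending confidence;
    ties broken by input index)."""
    cand = [(i, p) for i, p in enumerate(preds) if p.confidence >= cfg.conf_threshold]
    cand.sort(key=lambda t: (-t[1].confidence, t[0]))
    kept: list[InstancePrediction] = []
    for _, p in cand:
        if all(box_iou(p.box, q.box) <= cfg.iou_threshold for q in kept):
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# matching and metrics
# ---------------------------------------------------------------------------

def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∩ b| / |a ∪ b|; 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _truth_mask(t) -> np.ndarray:
    return t if isinstance(t, np.ndarray) else t.mask


def match_instances(preds: list[InstancePrediction], truths,
                    iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching by mask IoU, confidence-descending.

    Each prediction (in confidence order, input-index tie-break) claims the
    unmatched truth of highest IoU >= threshold (truth-index tie-break);
    remaining predictions are FP and remaining truths FN.
    """
    t_masks = [_truth_mask(t) for t in truths]
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
    taken = [False] * len(t_masks)
    matches = []
    for pi in order:
        best_iou, best_t = 0.0, -1
        for ti, tm in enumerate(t_masks):
            if taken[ti]:
                continue
            iou = mask_iou(preds[pi].mask, tm)
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_t = iou, ti
        if best_t >= 0:
            taken[best_t] = True
            matches.append((pi, best_t, best_iou))
    tp = len(matches)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(t_masks) - tp,
                       matches=tuple(matches))


def _ranked_tp_flags(per_image, iou_threshold: float):
    """Flatten dataset predictions into confidence rank order and mark TPs by
    per-image greedy matching."""
    flat = []  # (conf, image idx, pred idx within image)
    for im, (preds, _) in enumerate(per_image):
        for pi, p in enumerate(preds):
            flat.append((p.confidence, im, pi))
    flat.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken = [[False] * len(truths) for _, truths in per_image]
    flags = np.zeros(len(flat), dtype=bool)
    for r, (_, im, pi) in enumerate(flat):
        preds, truths = per_image[im]
        t_masks = [_truth_mask(t) for t in truths]
        best_iou, best_t = 0.0, -1
        for ti, tm in enumerate(t_masks):
            if taken[im][ti]:
                continue
            iou = mask_iou(preds[pi].mask, tm)
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_t = iou, ti
        if best_t >= 0:
            taken[im][best_t] = True
            flags[r] = True
    return flags


def average_precision(per_image, iou_threshold: float = 0.5,
                      interpolation: str = "101point") -> float:
    """Interpolated AP from the confidence-ranked PR curve over a dataset.

    ``per_image``: list of (predictions-with-masks, truth masks) pairs.
    ``interpolation``: "101point" (default) or "allpoint".
    """
    n_truth = sum(len(truths) for _, truths in per_image)
    if n_truth == 0:
        raise PodkitError("average precision undefined: zero ground-truth instances")
    flags = _ranked_tp_flags(per_image, iou_threshold)
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope: best precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "101point":
        grid = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(recall, grid, side="left")
        vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(vals.mean())
    if interpolation == "allpoint":
        r = np.concatenate([[0.0], recall])
        e = np.concatenate([env[:1] if env.size else [0.0], env])
        return float(np.sum((r[1:] - r[:-1]) * e[1:]))
    raise InvalidConfigError(f"unknown interpolation {interpolation!r}")


def evaluate_dataset(per_image, iou_threshold: float = 0.5) -> EvalReport:
    """Precision/recall at the matching threshold plus mAP@50 and mAP@50-95."""
    tp = fp = fn = 0
    for preds, truths in per_image:
        r = match_instances(preds, truths, iou_threshold)
        tp, fp, fn = tp + r.tp, fp + r.fp, fn + r.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    map50 = average_precision(per_image, 0.5)
    aps = [average_precision(per_image, t) for t in np.arange(0.5, 0.96, 0.05)]
    return EvalReport(precision=precision, recall=recall, map50=map50,
                      map50_95=float(np.mean(aps)))


# ---------------------------------------------------------------------------
# COCO-style JSON interchange (polygon or uncompressed RLE)
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed column-major run-length encoding (starts with a 0-run)."""
    m = np.asarray(mask, dtype=bool).flatten(order="F")
    counts = []
    prev, run = False, 0
    for v in m:
        if v == prev:
            run += 1
        else:
            counts.append(run)
            prev, run = v, 1
    counts.append(run)
    return {"size": list(mask.shape), "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for run in rle["counts"]:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    return flat.reshape((h, w), order="F")


def _segmentation_to_mask(seg, size: tuple[int, int]) -> np.ndarray:
    from .dataset_io import polygon_to_mask  # lazy: avoids import cycle
    if isinstance(seg, dict):
        return rle_decode(seg)
    h, w = size
    mask = np.zeros((h, w), dtype=bool)
    for poly in seg:
        pts = np.asarray(poly, dtype=float).reshape(-1, 2)
        pts_norm = pts / np.array([w, h])
        mask |= polygon_to_mask(pts_norm, (h, w))
    return mask


def predictions_to_coco(preds_by_image: dict[int, list[InstancePrediction]]
                        ) -> list[dict]:
    out = []
    for image_id, preds in preds_by_image.items():
        for p in preds:
            x1, y1, x2, y2 = p.box
            out.append({
                "image_id": int(image_id), "category_id": 1,
                "bbox": [x1, y1, x2 - x1, y2 - y1],
                "score": float(p.confidence),
                "segmentation": rle_encode(p.mask) if p.mask is not None else None,
            })
    return out


def coco_to_predictions(records: list[dict], size: tuple[int, int]
                        ) -> dict[int, list[InstancePrediction]]:
    by_image: dict[int, list[InstancePrediction]] = {}
    for r in records:
        x, y, w, h = r["bbox"]
        p = InstancePrediction(box=(x, y, x + w, y + h),
                               confidence=float(r.get("score", 1.0)))
        if r.get("segmentation") is not None:
            p.mask = _segmentation_to_mask(r["segmentation"], size)
        by_image.setdefault(int(r["image_id"]), []).append(p)
    return by_image


def masks_to_coco_gt(masks_by_image: dict[int, list[np.ndarray]]) -> dict:
    anns, images = [], []
    aid = 1
    for image_id, masks in masks_by_image.items():
        if masks:
            h, w = masks[0].shape
            images.append({"id": int(image_id), "height": h, "width": w})
        for m in masks:
            ys, xs = np.nonzero(m)
            bbox = [float(xs.min()), float(ys.min()),
                    float(xs.max() + 1 - xs.min()), float(ys.max() + 1 - ys.min())] \
                if xs.size else [0.0, 0.0, 0.0, 0.0]
            anns.append({"id": aid, "image_id": int(image_id), "category_id": 1,
                         "bbox": bbox, "area": float(m.sum()),
                         "segmentation": rle_encode(m), "iscrowd": 0})
            aid += 1
    return {"images": images,
            "categories": [{"id": 1, "name": "pod"}],
            "annotations": anns}


def coco_gt_to_masks(gt: dict) -> dict[int, list[np.ndarray]]:
    sizes = {im["id"]: (im["height"], im["width"]) for im in gt.get("images", [])}
    out: dict[int, list[np.ndarray]] = {}
    for ann in gt["annotations"]:
        size = sizes.get(ann["image_id"])
        if size is None:
            raise PodkitError(f"annotation references unknown image {ann['image_id']}")
        out.setdefault(int(ann["image_id"]), []).append(
            _segmentation_to_mask(ann["segmentation"], size))
    return out


def report_to_json(report: EvalReport, path) -> None:
    with open(path, "w") as f:
        json.dump(report.to_dict(), f, indent=2)
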