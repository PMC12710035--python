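"""Numeric operations: EMA attention forward pass and the toy trainer.

Everything here is plain NumPy.  The toy trainer is a deliberately small,
fully hand-differentiated realization of the prototype-coefficient
segmentation family (conv backbone, per-cell objectness/box/coefficient
heads, a prototype branch, sigmoid-of-linear-combination mask assembly).
It exists so that the pipeline — synthetic scenes in, masks and mAP out —
can be exercised end to end on a CPU; it makes no claim of replicating any
full-scale training recipe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arch_builder import InvalidConfigError
from . import mask_eval

__all__ = ["ema_layer", "train_toy", "ToyTrainResult", "toy_predict",
           "evaluate_toy", "save_toy", "load_toy", "init_toy"]


# ---------------------------------------------------------------------------
# small tensor utilities
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray, axis: int) -> np.ndarray:
    m = x - x.max(axis=axis, keepdims=True)
    e = np.exp(m)
    return e / e.sum(axis=axis, keepdims=True)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """x: (C,H,W) -> cols (C*k*k, Ho*Wo)."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.empty((c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = xp[:, i:i + stride * ho:stride, j:j + stride * wo:stride]
    return cols.reshape(c * k * k, ho * wo), (ho, wo)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    dxp = np.zeros((c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dc = dcols.reshape(c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, i:i + stride * ho:stride, j:j + stride * wo:stride] += dc[:, i, j]
    return dxp[:, pad:pad + h, pad:pad + w]


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
           stride: int = 1, pad: int = 0):
    """Forward conv; returns (y, cache) for backprop."""
    f, c, k, _ = w.shape
    cols, (ho, wo) = _im2col(x, k, stride, pad)
    y = w.reshape(f, -1) @ cols
    if b is not None:
        y += b[:, None]
    return y.reshape(f, ho, wo), (x.shape, cols, w, stride, pad)


def conv2d_backward(dy: np.ndarray, cache):
    x_shape, cols, w, stride, pad = cache
    f, c, k, _ = w.shape
    dy_mat = dy.reshape(f, -1)
    dw = (dy_mat @ cols.T).reshape(w.shape)
    db = dy_mat.sum(axis=1)
    dcols = w.reshape(f, -1).T @ dy_mat
    dx = _col2im(dcols, x_shape, k, stride, pad)
    return dx, dw, db


# ---------------------------------------------------------------------------
# EMA attention (efficient multiscale attention, cross-spatial variant)
# ---------------------------------------------------------------------------

def _ema_params(cg: int, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    return {
        "gn_w": np.ones(cg),
        "gn_b": np.zeros(cg),
        "w1": rng.standard_normal((cg, cg, 1, 1)) * 0.3,
        "b1": np.zeros(cg),
        "w3": rng.standard_normal((cg, cg, 3, 3)) * 0.1,
        "b3": np.zeros(cg),
    }


def ema_layer(x: np.ndarray, groups: int,
              params: dict[str, np.ndarray] | None = None,
              seed: int = 0) -> np.ndarray:
    """Efficient multiscale attention over a (c, h, w) feature map.

    The channel axis is reshaped into ``groups`` sub-maps (channel-to-batch
    grouping: no channel dimensionality reduction), each processed by two
    parallel branches — a 1x1 branch gated by pooled directional (H and W)
    descriptors, and a 3x3 local branch — whose outputs are fused by
    cross-spatial attention: each branch's globally pooled, channel-softmaxed
    descriptor weights the *other* branch's spatial map.  The sigmoid of the
    fused map rescales the input.  Output shape equals input shape.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise InvalidConfigError(f"ema_layer expects (c, h, w), got shape {x.shape}")
    c, h, w = x.shape
    if c % groups:
        raise InvalidConfigError(f"channels {c} not divisible by groups {groups}")
    cg = c // groups
    p = params if params is not None else _ema_params(cg, seed)
    gx = x.reshape(groups, cg, h, w)
    out = np.empty_like(gx)
    w1 = p["w1"].reshape(cg, cg)
    for g in range(groups):
        xg = gx[g]
        # directional pooling + shared 1x1 along the channel axis
        x_h = xg.mean(axis=2)                      # (cg, h)
        x_w = xg.mean(axis=1)                      # (cg, w)
        hw = w1 @ np.concatenate([x_h, x_w], axis=1) + p["b1"][:, None]
        a_h = _sigmoid(hw[:, :h])[:, :, None]      # (cg, h, 1)
        a_w = _sigmoid(hw[:, h:])[:, None, :]      # (cg, 1, w)
        gated = xg * a_h * a_w
        # group-norm with one group per channel: per-channel standardisation
        mu = gated.mean(axis=(1, 2), keepdims=True)
        var = gated.var(axis=(1, 2), keepdims=True)
        x1 = (gated - mu) / np.sqrt(var + 1e-5)
        x1 = x1 * p["gn_w"][:, None, None] + p["gn_b"][:, None, None]
        # parallel 3x3 branch (edge-replicate padding keeps constant inputs
        # constant, so attention degenerates gracefully on flat regions)
        xg_pad = np.pad(xg, ((0, 0), (1, 1), (1, 1)), mode="edge")
        x2, _ = conv2d(xg_pad, p["w3"], p["b3"], stride=1, pad=0)
        # cross-spatial fusion
        a1 = _softmax(x1.mean(axis=(1, 2)), axis=0)      # (cg,)
        a2 = _softmax(x2.mean(axis=(1, 2)), axis=0)
        fused = np.tensordot(a1, x2, axes=(0, 0)) + np.tensordot(a2, x1, axes=(0, 0))
        out[g] = xg * _sigmoid(fused)[None, :, :]
    return out.reshape(c, h, w)


# ---------------------------------------------------------------------------
# toy trainer
# ---------------------------------------------------------------------------

TOY_SIZE = 64          # input resolution of the toy realization
TOY_CELL = 8           # head cell stride
TOY_GRID = TOY_SIZE // TOY_CELL
TOY_PROTO = 16         # prototype plane resolution (1/4 of input)
TOY_K = 8              # prototype count of the toy realization


@dataclass
class ToyTrainResult:
    report: "mask_eval.EvalReport"
    losses: list[float]
    weights: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)


def init_toy(seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)

    def he(f, c, k):
        return (rng.standard_normal((f, c, k, k)) * np.sqrt(2.0 / (c * k * k)))

    return {
        "c1w": he(16, 3, 3), "c1b": np.zeros(16),
        "c2w": he(32, 16, 3), "c2b": np.zeros(32),
        "c3w": he(32, 32, 3), "c3b": np.zeros(32),
        "objw": he(1, 32, 1), "objb": np.full(1, -2.0),
        "boxw": he(4, 32, 1), "boxb": np.zeros(4),
        "cofw": he(TOY_K, 32, 1), "cofb": np.zeros(TOY_K),
        "p1w": he(16, 32, 3), "p1b": np.zeros(16),
        "p2w": he(TOY_K, 16, 1), "p2b": np.zeros(TOY_K),
    }


def _toy_forward(wts: dict[str, np.ndarray], img: np.ndarray):
    """img: (3, S, S) float in [0,1]."""
    cache = {}
    z1, cache["c1"] = conv2d(img, wts["c1w"], wts["c1b"], 2, 1)
    a1 = np.maximum(z1, 0.0)
    z2, cache["c2"] = conv2d(a1, wts["c2w"], wts["c2b"], 2, 1)
    a2 = np.maximum(z2, 0.0)
    z3, cache["c3"] = conv2d(a2, wts["c3w"], wts["c3b"], 2, 1)
    a3 = np.maximum(z3, 0.0)
    obj, cache["obj"] = conv2d(a3, wts["objw"], wts["objb"])
    box, cache["box"] = conv2d(a3, wts["boxw"], wts["boxb"])
    cof, cache["cof"] = conv2d(a3, wts["cofw"], wts["cofb"])
    zp, cache["p1"] = conv2d(a2, wts["p1w"], wts["p1b"], 1, 1)
    ap = np.maximum(zp, 0.0)
    planes, cache["p2"] = conv2d(ap, wts["p2w"], wts["p2b"])
    cache["acts"] = (z1, z2, z3, zp)
    return obj, box, cof, planes, cache


def _toy_targets(scene) -> tuple[np.ndarray, np.ndarray, list]:
    """Cell assignment: each instance claims the cell holding its box centre;
    on collision the larger instance wins."""
    obj_t = np.zeros((TOY_GRID, TOY_GRID))
    owners: dict[tuple[int, int], object] = {}
    for ann in scene.annotations:
        x1, y1, x2, y2 = ann.box
        cx, cy = (x1 + x2) / 2.0, (y1 + y2) / 2.0
        j = min(int(cx // TOY_CELL), TOY_GRID - 1)
        i = min(int(cy // TOY_CELL), TOY_GRID - 1)
        prev = owners.get((i, j))
        if prev is None or ann.mask.sum() > prev.mask.sum():
            owners[(i, j)] = ann
    for (i, j) in owners:
        obj_t[i, j] = 1.0
    return obj_t, owners


def _downsample_mask(mask: np.ndarray, out: int) -> np.ndarray:
    s = mask.shape[0] // out
    return mask.reshape(out, s, out, s).mean(axis=(1, 3)) > 0.25


def _bce_grad(z: np.ndarray, t: np.ndarray, weight=1.0):
    """Returns (loss_sum, dL/dz) for sum of weighted BCE-with-logits."""
    loss = weight * (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    grad = weight * (_sigmoid(z) - t)
    return float(np.sum(loss)), grad


def _scene_loss(wts, scene):
    """Composite loss (objectness + box regression + instance mask BCE) and
    gradients for one scene."""
    img = scene.image.astype(np.float64).transpose(2, 0, 1) / 255.0
    obj, box, cof, planes, cache = _toy_forward(wts, img)
    obj_t, owners = _toy_targets(scene)
    n_cells = TOY_GRID * TOY_GRID
    n_pos = max(len(owners), 1)

    w_obj = np.where(obj_t > 0, 8.0, 1.0) / n_cells
    l_obj, d_obj = _bce_grad(obj[0], obj_t, w_obj)
    d_obj = d_obj[None]

    d_box = np.zeros_like(box)
    d_cof = np.zeros_like(cof)
    d_planes = np.zeros_like(planes)
    l_box = 0.0
    l_mask = 0.0
    for (i, j), ann in owners.items():
        x1, y1, x2, y2 = ann.box
        cx, cy = (x1 + x2) / 2.0, (y1 + y2) / 2.0
        bw, bh = max(x2 - x1, 2.0), max(y2 - y1, 2.0)
        t = np.array([cx / TOY_CELL - j, cy / TOY_CELL - i,
                      np.log(bw / TOY_CELL), np.log(bh / TOY_CELL)])
        p = box[:, i, j]
        off = _sigmoid(p[:2])
        err_off = off - t[:2]
        err_sz = p[2:] - t[2:]
        l_box += float(np.sum(err_off ** 2) + np.sum(err_sz ** 2)) / n_pos
        d_box[:2, i, j] += 2.0 * err_off * off * (1 - off) / n_pos
        d_box[2:, i, j] += 2.0 * err_sz / n_pos

        coeff = cof[:, i, j]
        logits = np.tensordot(coeff, planes, axes=(0, 0))
        m_t = _downsample_mask(ann.mask, TOY_PROTO).astype(np.float64)
        w_m = np.where(m_t > 0, 3.0, 1.0) / (TOY_PROTO * TOY_PROTO * n_pos)
        lm, dz = _bce_grad(logits, m_t, w_m)
        l_mask += lm
        d_cof[:, i, j] += np.tensordot(dz, planes, axes=([0, 1], [1, 2]))
        d_planes += coeff[:, None, None] * dz[None]

    # backprop
    grads = {}
    z1, z2, z3, zp = cache["acts"]
    da3 = np.zeros_like(z3)
    for dy, key in ((d_obj, "obj"), (d_box, "box"), (d_cof, "cof")):
        dx, dw, db = conv2d_backward(dy, cache[key])
        grads[key + "w"], grads[key + "b"] = dw, db
        da3 += dx
    dz3 = da3 * (z3 > 0)
    dx3, grads["c3w"], grads["c3b"] = conv2d_backward(dz3, cache["c3"])

    dxp, grads["p2w"], grads["p2b"] = conv2d_backward(d_planes, cache["p2"])
    dzp = dxp * (zp > 0)
    dxp1, grads["p1w"], grads["p1b"] = conv2d_backward(dzp, cache["p1"])

    da2 = dx3 + dxp1
    dz2 = da2 * (z2 > 0)
    dx2, grads["c2w"], grads["c2b"] = conv2d_backward(dz2, cache["c2"])
    dz1 = dx2 * (z1 > 0)
    _, grads["c1w"], grads["c1b"] = conv2d_backward(dz1, cache["c1"])

    return l_obj + l_box + l_mask, grads


def _augment_scene(scene, rng):
    """Random flips, quarter-turn rotation and translate-crop (pad-back)."""
    from .synth_fixtures import SyntheticScene  # local import avoids a cycle
    img = scene.image
    anns = [a.copy() for a in scene.annotations]

    def apply(f_img, f_mask):
        nonlocal img, anns
        img = f_img(img)
        for a in anns:
            a.set_mask(f_mask(a.mask))

    if rng.random() < 0.5:
        apply(lambda im: im[:, ::-1].copy(), lambda m: m[:, ::-1].copy())
    if rng.random() < 0.5:
        apply(lambda im: im[::-1].copy(), lambda m: m[::-1].copy())
    k = int(rng.integers(0, 4))
    if k:
        apply(lambda im: np.rot90(im, k).copy(), lambda m: np.rot90(m, k).copy())
    if rng.random() < 0.5:
        s = img.shape[0]
        c = int(s * 0.85)
        oy, ox = rng.integers(0, s - c, size=2)
        py, px = rng.integers(0, s - c, size=2)
        base = np.full_like(img, img.reshape(-1, 3).mean(axis=0).astype(img.dtype))
        base[py:py + c, px:px + c] = img[oy:oy + c, ox:ox + c]
        img = base
        kept = []
        for a in anns:
            m = np.zeros_like(a.mask)
            m[py:py + c, px:px + c] = a.mask[oy:oy + c, ox:ox + c]
            if m.sum() >= 3:
                a.set_mask(m)
                kept.append(a)
        anns = kept
    return SyntheticScene(image=img, annotations=anns, config=scene.config)


def _resize_scene(scene):
    if scene.image.shape[0] == TOY_SIZE and scene.image.shape[1] == TOY_SIZE:
        return scene
    from skimage.transform import resize
    from .synth_fixtures import SyntheticScene
    img = (resize(scene.image, (TOY_SIZE, TOY_SIZE), anti_aliasing=True,
                  preserve_range=True)).astype(np.uint8)
    anns = []
    for a in scene.annotations:
        m = resize(a.mask.astype(float), (TOY_SIZE, TOY_SIZE), order=0,
                   preserve_range=True) > 0.5
        if m.sum() >= 3:
            b = a.copy()
            b.set_mask(m)
            anns.append(b)
    return SyntheticScene(image=img, annotations=anns, config=scene.config)


def toy_predict(wts: dict[str, np.ndarray], scene, conf: float = 0.3,
                iou: float = 0.5) -> list:
    """Run the toy network on a scene and return postprocessed predictions."""
    scene = _resize_scene(scene)
    img = scene.image.astype(np.float64).transpose(2, 0, 1) / 255.0
    obj, box, cof, planes, _ = _toy_forward(wts, img)
    scores = _sigmoid(obj[0])
    preds = []
    up = planes.repeat(4, axis=1).repeat(4, axis=2)   # nearest to input res
    bundle = mask_eval.PrototypeBundle(up)
    for i in range(TOY_GRID):
        for j in range(TOY_GRID):
            if scores[i, j] < min(conf, 0.05):
                continue
            p = box[:, i, j]
            ox, oy = _sigmoid(p[0]), _sigmoid(p[1])
            cx, cy = (j + ox) * TOY_CELL, (i + oy) * TOY_CELL
            bw = float(np.clip(TOY_CELL * np.exp(p[2]), 2, TOY_SIZE))
            bh = float(np.clip(TOY_CELL * np.exp(p[3]), 2, TOY_SIZE))
            x1 = float(np.clip(cx - bw / 2, 0, TOY_SIZE - 1))
            y1 = float(np.clip(cy - bh / 2, 0, TOY_SIZE - 1))
            x2 = float(np.clip(cx + bw / 2, x1 + 1, TOY_SIZE))
            y2 = float(np.clip(cy + bh / 2, y1 + 1, TOY_SIZE))
            preds.append(mask_eval.InstancePrediction(
                box=(x1, y1, x2, y2), confidence=float(scores[i, j]),
                coefficients=cof[:, i, j].copy()))
    preds = mask_eval.assemble_instance_masks(bundle, preds)
    cfg = mask_eval.PostprocessConfig(conf_threshold=conf, iou_threshold=iou)
    return mask_eval.postprocess(preds, cfg)


def evaluate_toy(wts: dict[str, np.ndarray], scenes, conf: float = 0.3,
                 iou: float = 0.5) -> "mask_eval.EvalReport":
    per_image = []
    for sc in scenes:
        sc = _resize_scene(sc)
        preds = toy_predict(wts, sc, conf=conf, iou=iou)
        truths = [a.mask for a in sc.annotations]
        per_image.append((preds, truths))
    return mask_eval.evaluate_dataset(per_image, iou_threshold=iou)


def train_toy(graph, scenes, steps: int = 600, seed: int = 0, *,
              lr: float = 3e-3, batch_size: int = 8,
              val_fraction: float = 0.25, augment: bool = True,
              val_scenes=None) -> ToyTrainResult:
    """Train the toy realization on synthetic scenes.

    ``graph`` supplies interface metadata (class count, prototype count); the
    trainable network is a fixed reduced-width realization suitable for a
    CPU.  Deterministic given ``seed``.  Returns the held-out evaluation
    report, the per-step loss trace and the trained weights.
    """
    scenes = [s for s in scenes]
    if not scenes:
        raise InvalidConfigError("train_toy requires at least one scene")
    if any(len(s.annotations) == 0 for s in scenes):
        raise InvalidConfigError("every training scene must contain >= 1 instance")
    if steps < 1:
        raise InvalidConfigError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    scenes = [_resize_scene(s) for s in scenes]
    if val_scenes is None:
        n_val = max(1, int(len(scenes) * val_fraction))
        order = rng.permutation(len(scenes))
        val_scenes = [scenes[i] for i in order[:n_val]]
        train_scenes = [scenes[i] for i in order[n_val:]] or val_scenes
    else:
        val_scenes = [_resize_scene(s) for s in val_scenes]
        train_scenes = scenes

    wts = init_toy(seed)
    m = {k: np.zeros_like(v) for k, v in wts.items()}
    v = {k: np.zeros_like(w) for k, w in wts.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    losses: list[float] = []
    for step in range(1, steps + 1):
        idx = rng.integers(0, len(train_scenes), size=min(batch_size, len(train_scenes)))
        total = 0.0
        gacc = {k: np.zeros_like(w) for k, w in wts.items()}
        for i in idx:
            sc = train_scenes[int(i)]
            if augment:
                sc = _augment_scene(sc, rng)
                if not sc.annotations:
                    sc = train_scenes[int(i)]
            loss, grads = _scene_loss(wts, sc)
            total += loss
            for k, g in grads.items():
                gacc[k] += g
        total /= len(idx)
        losses.append(total)
        for k in wts:
            g = gacc[k] / len(idx)
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g * g
            mhat = m[k] / (1 - b1 ** step)
            vhat = v[k] / (1 - b2 ** step)
            wts[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    report = evaluate_toy(wts, val_scenes)
    return ToyTrainResult(report=report, losses=losses, weights=wts,
                          meta={"seed": seed, "steps": steps,
                                "nc": graph.meta.get("nc", 1),
                                "k": graph.meta.get("k", 32)})


def save_toy(path, wts: dict[str, np.ndarray]) -> None:
    np.savez(path, **wts)


def load_toy(path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}
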