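"""Synthetic backdrop scenes of dense elliptical "pods" with occlusion.

The generator emulates side-view imaging of a plant row against a uniform
backdrop: pods are filled rotated ellipses with mildly noisy boundaries,
clustered around vertical stem lines; occluders are elongated quadrilaterals
("stems") and broad elliptical blobs ("leaves") drawn over the pods.  Ground
truth stores the *visible* (post-occlusion) mask of every pod, matching how
field annotations are drawn on visible pod regions.  This is a deliberate
cartoon of field imagery — colour statistics, lighting and plant structure
are not modelled.

All randomness flows through ``numpy.random.default_rng(seed)``, whose bit
stream is stable across platforms, so scenes are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .arch_builder import PodkitError, InvalidConfigError
from .dataset_io import InstanceAnnotation
from .iqa_harvest import FrameSequence

__all__ = ["SceneConfig", "SyntheticScene", "generate_scene", "generate_clip",
           "easy_scene_config"]


@dataclass(frozen=True)
class SceneConfig:
    """Knobs of the synthetic pod scene renderer.

    Axis lengths are full lengths in pixels (major, minor).  ``cluster_std``
    controls how tightly pod centres hug their stem line (fraction of image
    width).  ``allow_overlap=False`` rejects pod placements that touch an
    already-placed pod.
    """

    image_size: tuple[int, int] = (256, 256)     # (height, width)
    n_pods: int = 24
    pod_length: tuple[float, float] = (26.0, 42.0)
    pod_width: tuple[float, float] = (10.0, 16.0)
    orientation_deg: tuple[float, float] = (-55.0, 55.0)  # from vertical
    cluster_std: float = 0.08
    n_stems: int = 2
    n_occluders: int = 4
    backdrop_rgb: tuple[int, int, int] = (235, 235, 230)
    noise_std: float = 4.0
    blur_sigma: float = 0.0
    allow_overlap: bool = True
    boundary_noise: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pods < 0:
            raise InvalidConfigError("n_pods must be >= 0")
        if min(self.pod_length[0], self.pod_width[0]) < 2:
            raise InvalidConfigError("pod axis lengths must be >= 2 pixels")
        if self.blur_sigma < 0 or self.noise_std < 0:
            raise InvalidConfigError("noise and blur levels must be >= 0")


@dataclass
class SyntheticScene:
    image: np.ndarray                     # (H, W, 3) uint8
    annotations: list[InstanceAnnotation]
    config: SceneConfig | None = None
    occluder_mask: np.ndarray | None = None
    pod_masks: list[np.ndarray] = field(default_factory=list)  # pre-occlusion


def _ellipse_mask(h, w, cy, cx, a, b, theta, wobble, rng) -> np.ndarray:
    """Filled rotated ellipse with a mildly perturbed boundary radius."""
    ys, xs = np.mgrid[0:h, 0:w]
    dy, dx = ys - cy, xs - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if wobble > 0:
        phase = rng.uniform(0, 2 * np.pi, size=2)
        ang = np.arctan2(v, u)
        r = r * (1.0 + wobble * (0.6 * np.sin(3 * ang + phase[0])
                                 + 0.4 * np.sin(5 * ang + phase[1])))
    return r <= 1.0


def _quad_mask(h, w, p0, p1, width) -> np.ndarray:
    """Thick line segment ("stem") as a distance band."""
    ys, xs = np.mgrid[0:h, 0:w]
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    L2 = float(d @ d) or 1.0
    t = np.clip(((xs - p0[0]) * d[0] + (ys - p0[1]) * d[1]) / L2, 0, 1)
    px = p0[0] + t * d[0]
    py = p0[1] + t * d[1]
    return (xs - px) ** 2 + (ys - py) ** 2 <= (width / 2.0) ** 2


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Render one scene; exactly ``cfg.n_pods`` instances, deterministic per seed.

    Raises when pods cannot be placed after bounded retries (e.g. overlap
    disabled with pods larger than the canvas allows).
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.array(cfg.backdrop_rgb, dtype=np.float64)
    if cfg.noise_std > 0:
        img += rng.normal(0.0, cfg.noise_std, size=img.shape)

    stem_xs = [(i + 1) / (cfg.n_stems + 1) * w for i in range(max(cfg.n_stems, 1))]

    pod_masks: list[np.ndarray] = []
    occupied = np.zeros((h, w), dtype=bool)
    for _ in range(cfg.n_pods):
        placed = False
        for _attempt in range(60):
            a = rng.uniform(*cfg.pod_length) / 2.0
            b = rng.uniform(*cfg.pod_width) / 2.0
            sx = stem_xs[int(rng.integers(0, len(stem_xs)))]
            cx = float(np.clip(rng.normal(sx, cfg.cluster_std * w), a, w - 1 - a))
            cy = float(rng.uniform(a, h - 1 - a))
            theta = np.deg2rad(90.0 + rng.uniform(*cfg.orientation_deg))
            m = _ellipse_mask(h, w, cy, cx, a, b, theta, cfg.boundary_noise, rng)
            if m.sum() < 8:
                continue
            if not cfg.allow_overlap and (m & occupied).any():
                continue
            pod_masks.append(m)
            occupied |= m
            placed = True
            break
        if not placed:
            raise PodkitError(
                f"could not place pod {len(pod_masks) + 1}/{cfg.n_pods} after "
                f"bounded retries (canvas {cfg.image_size}, overlap="
                f"{cfg.allow_overlap})")

    # paint pods (later pods occlude earlier ones)
    for m in pod_masks:
        base = np.array([rng.uniform(110, 150), rng.uniform(150, 190),
                         rng.uniform(60, 95)])
        shade = rng.uniform(0.85, 1.1)
        img[m] = base * shade + rng.normal(0, 3.0, size=(int(m.sum()), 3))

    # occluders drawn over everything
    occl = np.zeros((h, w), dtype=bool)
    for _ in range(cfg.n_occluders):
        if rng.random() < 0.5:  # stem: elongated band
            x0 = rng.uniform(0, w)
            seg = _quad_mask(h, w, (x0, 0), (x0 + rng.uniform(-w / 6, w / 6), h - 1),
                             rng.uniform(2, 5))
            color = np.array([105, 88, 50]) + rng.normal(0, 6, size=3)
        else:  # leaf: broad blob
            seg = _ellipse_mask(h, w, rng.uniform(0, h), rng.uniform(0, w),
                                rng.uniform(h / 8, h / 4), rng.uniform(h / 12, h / 6),
                                rng.uniform(0, np.pi), 0.15, rng)
            color = np.array([55, 110, 45]) + rng.normal(0, 8, size=3)
        occl |= seg
        img[seg] = color + rng.normal(0, 3.0, size=(int(seg.sum()), 3))

    if cfg.blur_sigma > 0:
        for c in range(3):
            img[..., c] = ndimage.gaussian_filter(img[..., c], cfg.blur_sigma)
    image = np.clip(img, 0, 255).astype(np.uint8)

    # visible ground truth: own ellipse minus later pods minus occluders
    annotations = []
    kept_pod_masks = []
    n = len(pod_masks)
    for i, m in enumerate(pod_masks):
        visible = m.copy()
        for j in range(i + 1, n):
            visible &= ~pod_masks[j]
        visible &= ~occl
        if visible.sum() >= 3:
            annotations.append(InstanceAnnotation.from_mask(0, visible))
            kept_pod_masks.append(m)
    if cfg.n_pods > 0 and len(annotations) < cfg.n_pods:
        # a pod fully hidden by occluders/other pods: regenerate with a
        # shifted stream so the scene still carries the requested count
        if cfg.seed > 10_000_000:
            raise PodkitError("could not produce the requested number of "
                              "visible pods after bounded retries")
        return generate_scene(replace(cfg, seed=cfg.seed + 1_000_003))
    return SyntheticScene(image=image, annotations=annotations, config=cfg,
                          occluder_mask=occl, pod_masks=kept_pod_masks)


def easy_scene_config(seed: int = 0, size: int = 64) -> SceneConfig:
    """Large, pairwise-disjoint, unoccluded pods on a clean backdrop — the
    separable regime used for end-to-end toy-training smoke runs."""
    return SceneConfig(image_size=(size, size), n_pods=3,
                       pod_length=(size * 0.30, size * 0.42),
                       pod_width=(size * 0.14, size * 0.20),
                       orientation_deg=(-40.0, 40.0),
                       cluster_std=0.25, n_stems=2, n_occluders=0,
                       noise_std=2.0, allow_overlap=False,
                       boundary_noise=0.03, seed=seed)


def generate_clip(cfg: SceneConfig, duration_s: float, fps: float,
                  jitter: float = 0.0, blur_schedule=None,
                  speed_px_s: float = 12.0) -> FrameSequence:
    """Laterally scanning clip over a wide rendered scene.

    ``blur_schedule`` maps a timestamp (seconds) to a Gaussian σ (callable,
    sequence per frame, or None).  ``jitter`` is the std of per-frame
    horizontal jitter in pixels; with jitter 0 consecutive frames differ
    only by the programmed translation.
    """
    if duration_s <= 0 or fps <= 0:
        raise InvalidConfigError("duration and fps must be positive")
    n_frames = int(round(duration_s * fps))
    h, w = cfg.image_size
    travel = int(np.ceil(speed_px_s * duration_s)) + 1
    wide_w = w + travel
    wide = replace(cfg, image_size=(h, wide_w),
                   n_pods=max(1, int(round(cfg.n_pods * wide_w / w))),
                   blur_sigma=0.0)
    base = generate_scene(wide).image
    rng = np.random.default_rng(cfg.seed + 7919)
    frames = []
    for f in range(n_frames):
        t = f / fps
        x0 = speed_px_s * t
        if jitter > 0:
            x0 += rng.normal(0.0, jitter)
        x0 = int(np.clip(round(x0), 0, wide_w - w))
        frame = base[:, x0:x0 + w].copy()
        sigma = 0.0
        if callable(blur_schedule):
            sigma = float(blur_schedule(t))
        elif blur_schedule is not None:
            sigma = float(blur_schedule[min(f, len(blur_schedule) - 1)])
        if sigma > 0:
            frame = np.stack([ndimage.gaussian_filter(frame[..., c].astype(float), sigma)
                              for c in range(3)], axis=-1)
            frame = np.clip(frame, 0, 255).astype(np.uint8)
        frames.append(frame)
    return FrameSequence(frames=frames, fps=fps, clip_id=f"synclip{cfg.seed}")
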