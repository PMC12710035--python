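"""Frame harvesting from field video and no-reference image quality filtering.

Four indicators screen frames decomposed from handheld field video:

* clarity — variance of the Laplacian response on grayscale; 0 for constant
  images, decreasing under defocus blur;
* edge sharpness — mean Tenengrad (squared Sobel gradient magnitude);
* entropy — Shannon entropy of the 256-bin intensity histogram, in bits
  (in [0, 8] for 8-bit grayscale);
* GLCM energy — angular second moment of the symmetric, normalized
  gray-level co-occurrence matrix (32 gray levels, offsets (0,1) and (1,0),
  averaged); 1.0 for constant images, lower for textured ones.

Filtering is two-staged: a loose pass over everything, then per-subset
tuned thresholds, with a per-frame audit trail of the failing indicators.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix

from .arch_builder import PodkitError, InvalidConfigError

__all__ = [
    "QualityIndicators", "FrameRecord", "FrameSequence", "ThresholdProfile",
    "to_grayscale", "clarity", "edge_sharpness", "image_entropy", "glcm_energy",
    "score_frame", "extract_frames", "two_stage_filter",
    "INDICATOR_NAMES",
]

INDICATOR_NAMES = ("clarity", "edge_sharpness", "entropy_bits", "glcm_energy")

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


# ---------------------------------------------------------------------------
# indicators
# ---------------------------------------------------------------------------

def to_grayscale(image: np.ndarray) -> np.ndarray:
    """8-bit grayscale via standard luma weights."""
    img = np.asarray(image)
    if img.size == 0:
        raise InvalidConfigError("empty image")
    if img.ndim == 3:
        img = img[..., :3].astype(np.float64) @ _LUMA
    else:
        img = img.astype(np.float64)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def clarity(image: np.ndarray) -> float:
    """Variance of the Laplacian response (4-neighbour kernel, reflect pad)."""
    g = to_grayscale(image).astype(np.float64)
    kernel = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
    resp = ndimage.convolve(g, kernel, mode="reflect")
    return float(resp.var())


def edge_sharpness(image: np.ndarray) -> float:
    """Mean Tenengrad: mean squared Sobel gradient magnitude (reflect pad)."""
    g = to_grayscale(image).astype(np.float64)
    gx = ndimage.sobel(g, axis=1, mode="reflect")
    gy = ndimage.sobel(g, axis=0, mode="reflect")
    return float(np.mean(gx * gx + gy * gy))


def image_entropy(image: np.ndarray) -> float:
    """Shannon entropy of the 256-bin intensity histogram, in bits."""
    g = to_grayscale(image)
    counts = np.bincount(g.ravel(), minlength=256)
    p = counts[counts > 0] / g.size
    return float(max(0.0, -(p * np.log2(p)).sum()))


def glcm_energy(image: np.ndarray, levels: int = 32,
                offsets=((0, 1), (1, 0))) -> float:
    """Angular second moment of the normalized symmetric co-occurrence matrix.

    The grayscale image is quantized to ``levels`` gray levels; one GLCM per
    offset is accumulated symmetrically and normalized, and the per-offset
    energies Σ p(i,j)² are averaged.  1.0 for constant images.
    """
    g = to_grayscale(image)
    q = (g.astype(np.uint16) * levels // 256).astype(np.uint8)
    angle_of = {(0, 1): 0.0, (1, 0): np.pi / 2}
    energies = []
    for off in offsets:
        off = tuple(off)
        if off not in angle_of:
            raise InvalidConfigError(f"unsupported GLCM offset {off}")
        P = graycomatrix(q, distances=[1], angles=[angle_of[off]],
                         levels=levels, symmetric=True, normed=True)[:, :, 0, 0]
        energies.append(float((P * P).sum()))
    return float(np.mean(energies))


@dataclass(frozen=True)
class QualityIndicators:
    clarity: float
    edge_sharpness: float
    entropy_bits: float
    glcm_energy: float

    def __post_init__(self) -> None:
        if self.clarity < 0 or self.edge_sharpness < 0:
            raise InvalidConfigError("clarity and edge sharpness are non-negative")
        if not (0.0 <= self.entropy_bits <= 8.0):
            raise InvalidConfigError("entropy must lie in [0, 8] bits")
        if not (0.0 < self.glcm_energy <= 1.0):
            raise InvalidConfigError("GLCM energy must lie in (0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in INDICATOR_NAMES}


def score_frame(image: np.ndarray) -> QualityIndicators:
    return QualityIndicators(clarity=clarity(image),
                             edge_sharpness=edge_sharpness(image),
                             entropy_bits=image_entropy(image),
                             glcm_energy=glcm_energy(image))


# ---------------------------------------------------------------------------
# frame extraction
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """In-memory clip: a stack of RGB frames at a fixed frame rate."""

    frames: list
    fps: float
    clip_id: str = "clip"


@dataclass
class FrameRecord:
    clip_id: str
    timestamp: float
    image: np.ndarray
    indicators: QualityIndicators | None = None
    kept: bool | None = None
    reject_stage: int | None = None
    reject_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise InvalidConfigError("timestamp must be >= 0")


def _load_clip(video) -> FrameSequence:
    if isinstance(video, FrameSequence):
        return video
    path = Path(video)
    if path.is_dir():
        meta = path / "clip.json"
        if not meta.exists():
            raise PodkitError(f"clip {path.name}: frame directory lacks clip.json")
        fps = float(json.loads(meta.read_text())["fps"])
        import imageio.v3 as iio
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in
                       (".png", ".jpg", ".jpeg"))
        return FrameSequence([iio.imread(p) for p in files], fps, path.name)
    try:
        import imageio.v3 as iio
        meta = iio.immeta(path)
        frames = list(iio.imiter(path))
        fps = float(meta.get("fps", 0) or 0)
        if fps <= 0:
            raise PodkitError(f"clip {path.name}: unknown frame rate")
        return FrameSequence(frames, fps, path.stem)
    except PodkitError:
        raise
    except Exception as e:  # unreadable container/codec
        raise PodkitError(f"clip {Path(video).name}: cannot read video ({e})") from e


def extract_frames(video, interval_seconds: float = 1.0) -> list[FrameRecord]:
    """Decompose a clip into frames sampled once per interval starting at t=0.

    Yields floor(duration/interval)+1 frames, capped by frame availability
    (the final sample is included only if its frame exists).
    """
    if interval_seconds <= 0:
        raise InvalidConfigError("interval must be positive")
    clip = _load_clip(video)
    n = len(clip.frames)
    records = []
    i = 0
    while True:
        t = i * interval_seconds
        idx = round(t * clip.fps)
        if idx >= n:
            break
        records.append(FrameRecord(clip_id=clip.clip_id, timestamp=float(t),
                                   image=np.asarray(clip.frames[idx])))
        i += 1
    return records


# ---------------------------------------------------------------------------
# two-stage threshold filtering
# ---------------------------------------------------------------------------

Bounds = dict[str, tuple[float | None, float | None]]  # indicator -> (min, max)


@dataclass
class ThresholdProfile:
    """Loose stage-1 bounds for all frames, tuned stage-2 bounds per subset.

    Stage-2 bounds must be at least as strict as stage 1 for any indicator
    they share.  A ``"default"`` stage-2 key applies to subsets without an
    entry; with no stage-2 table at all, only stage 1 applies.
    """

    stage1: Bounds = field(default_factory=dict)
    stage2: dict[str, Bounds] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for subset, bounds in self.stage2.items():
            for ind, (lo2, hi2) in bounds.items():
                lo1, hi1 = self.stage1.get(ind, (None, None))
                if lo1 is not None and (lo2 is None or lo2 < lo1):
                    raise InvalidConfigError(
                        f"stage-2 bound for {ind!r} in subset {subset!r} is looser "
                        f"than stage 1")
                if hi1 is not None and (hi2 is None or hi2 > hi1):
                    raise InvalidConfigError(
                        f"stage-2 bound for {ind!r} in subset {subset!r} is looser "
                        f"than stage 1")

    @classmethod
    def from_percentiles(cls, frames: list[FrameRecord], q: float = 5.0,
                         indicators=INDICATOR_NAMES) -> "ThresholdProfile":
        """Loose lower bounds at the q-th percentile of each indicator."""
        stage1: Bounds = {}
        for ind in indicators:
            vals = [getattr(f.indicators, ind) for f in frames
                    if f.indicators is not None]
            if vals:
                stage1[ind] = (float(np.percentile(vals, q)), None)
        return cls(stage1=stage1)

    def to_yaml(self, path) -> None:
        import yaml
        doc = {"stage1": {k: list(v) for k, v in self.stage1.items()},
               "stage2": {s: {k: list(v) for k, v in b.items()}
                          for s, b in self.stage2.items()}}
        with open(path, "w") as f:
            yaml.safe_dump(doc, f)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdProfile":
        import yaml
        with open(path) as f:
            doc = yaml.safe_load(f)
        fix = lambda b: {k: tuple(v) for k, v in (b or {}).items()}
        return cls(stage1=fix(doc.get("stage1")),
                   stage2={s: fix(b) for s, b in (doc.get("stage2") or {}).items()})


def _failing(ind: QualityIndicators, bounds: Bounds) -> tuple[str, ...]:
    bad = []
    for name, (lo, hi) in bounds.items():
        v = getattr(ind, name)
        if (lo is not None and v < lo) or (hi is not None and v > hi):
            bad.append(name)
    return tuple(bad)


def two_stage_filter(frames: list[FrameRecord], profile: ThresholdProfile,
                     subset_of=None):
    """Apply loose then per-subset thresholds; returns (kept, audit log).

    ``subset_of(frame)`` maps a frame to its stage-2 subset id (default: the
    clip id).  A subset with no stage-2 entry and no "default" entry is an
    error.  Filtering is per-frame, hence order-independent.
    """
    subset_of = subset_of or (lambda fr: fr.clip_id)
    kept, audit = [], []
    for fr in frames:
        if fr.indicators is None:
            fr.indicators = score_frame(fr.image)
        reasons = _failing(fr.indicators, profile.stage1)
        stage = 1 if reasons else None
        if not reasons and profile.stage2:
            subset = subset_of(fr)
            bounds = profile.stage2.get(subset, profile.stage2.get("default"))
            if bounds is None:
                raise PodkitError(f"unknown stage-2 subset id {subset!r}")
            reasons = _failing(fr.indicators, bounds)
            stage = 2 if reasons else None
        fr.kept = not reasons
        fr.reject_stage = stage
        fr.reject_reasons = reasons
        if fr.kept:
            kept.append(fr)
        audit.append({"clip": fr.clip_id, "t": fr.timestamp,
                      **fr.indicators.as_dict(),
                      "kept": fr.kept, "stage": stage, "reasons": reasons})
    return kept, audit


def audit_to_csv(audit: list[dict], path) -> None:
    cols = ["clip", "t", *INDICATOR_NAMES, "kept", "stage", "reasons"]
    with open(path, "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=cols)
        w.writeheader()
        for row in audit:
            row = dict(row)
            row["reasons"] = ";".join(row["reasons"])
            w.writerow(row)
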