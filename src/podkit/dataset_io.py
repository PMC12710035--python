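"""Instance-segmentation label I/O, geometry, splits, statistics, augmentation.

Label dialect: one instance per line, ``class_id x1 y1 x2 y2 x3 y3 ...`` with
normalized polygon coordinates in [0, 1] (x rightward, y downward).  All
geometric operations share one convention: 0-based pixel indices, half-open
boxes, even-odd polygon fill over pixel centers at (col + 0.5, row + 0.5).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
from matplotlib.path import Path as MplPath
from skimage import measure

from .arch_builder import PodkitError, InvalidConfigError

__all__ = [
    "InstanceAnnotation", "DatasetSplit", "DatasetStats",
    "read_labels", "write_labels", "polygon_to_mask", "mask_to_polygon",
    "split_dataset", "compute_stats", "augment",
]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def polygon_to_mask(polygon: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    """Rasterise one normalized polygon ring to a boolean mask.

    A pixel is set iff its center lies strictly inside the ring (even-odd
    rule); an axis-aligned rectangle [x1, x2) x [y1, y2) in pixel units
    therefore covers exactly (x2-x1)*(y2-y1) pixels.
    """
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InvalidConfigError(
            f"polygon must be (n >= 3, 2) vertex array, got shape {pts.shape}")
    h, w = image_size
    px = pts * np.array([w, h])
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    centers = np.column_stack([cols.ravel(), rows.ravel()])
    inside = MplPath(px).contains_points(centers, radius=-1e-9)
    return inside.reshape(h, w)


def mask_to_polygon(mask: np.ndarray) -> list[np.ndarray]:
    """Trace a boolean mask into normalized polygon ring(s).

    Multi-part masks yield multiple rings.  Empty masks yield an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    h, w = mask.shape
    padded = np.pad(mask.astype(float), 1)
    rings = []
    for contour in measure.find_contours(padded, 0.5):
        # contour is (row, col) in padded index space; pixel centers sit at
        # integer indices, so +0.5 maps to our center convention, -1 unpads
        xy = np.column_stack([contour[:, 1] - 1 + 0.5, contour[:, 0] - 1 + 0.5])
        if len(xy) >= 3:
            rings.append(xy / np.array([w, h]))
    rings.sort(key=len, reverse=True)
    return rings


# ---------------------------------------------------------------------------
# annotation container
# ---------------------------------------------------------------------------

@dataclass
class InstanceAnnotation:
    """One pod instance: class id plus polygon(s); mask and box derived.

    Either ``polygons`` (normalized rings) or a mask must be supplied; the
    other representation is derived lazily.  Multi-part masks (e.g. after
    cropping) are kept as multiple rings under one instance.
    """

    class_id: int
    image_size: tuple[int, int]
    polygons: list[np.ndarray] = field(default_factory=list)
    _mask: np.ndarray | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_polygon(cls, class_id: int, polygon, image_size) -> "InstanceAnnotation":
        pts = np.asarray(polygon, dtype=float)
        if pts.shape[0] < 3:
            raise InvalidConfigError("polygon needs at least 3 vertices")
        if pts.min() < 0.0 or pts.max() > 1.0:
            raise InvalidConfigError("normalized coordinates must lie in [0, 1]")
        return cls(class_id=class_id, image_size=tuple(image_size), polygons=[pts])

    @classmethod
    def from_mask(cls, class_id: int, mask: np.ndarray) -> "InstanceAnnotation":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise InvalidConfigError("instance mask must be non-empty")
        ann = cls(class_id=class_id, image_size=mask.shape)
        ann._mask = mask
        return ann

    # -- derived views ------------------------------------------------------

    @property
    def polygon(self) -> np.ndarray:
        """Largest ring (vertex-count order)."""
        if not self.polygons:
            self.polygons = mask_to_polygon(self.mask)
        return self.polygons[0]

    @property
    def mask(self) -> np.ndarray:
        if self._mask is None:
            m = np.zeros(self.image_size, dtype=bool)
            for ring in self.polygons:
                m ^= polygon_to_mask(ring, self.image_size)
            self._mask = m
        return self._mask

    @property
    def box(self) -> tuple[float, float, float, float]:
        """Tight half-open pixel box around the mask."""
        ys, xs = np.nonzero(self.mask)
        if xs.size == 0:
            raise PodkitError("cannot derive a box from an empty mask")
        return (float(xs.min()), float(ys.min()),
                float(xs.max() + 1), float(ys.max() + 1))

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def set_mask(self, mask: np.ndarray) -> None:
        self._mask = np.asarray(mask, dtype=bool)
        self.image_size = self._mask.shape
        self.polygons = []

    def copy(self) -> "InstanceAnnotation":
        ann = InstanceAnnotation(self.class_id, tuple(self.image_size),
                                 [p.copy() for p in self.polygons])
        ann._mask = None if self._mask is None else self._mask.copy()
        return ann


# ---------------------------------------------------------------------------
# label files
# ---------------------------------------------------------------------------

def read_labels(source, image_size: tuple[int, int]) -> list[InstanceAnnotation]:
    """Parse a polygon-per-line label file.

    Each line: class id followed by an even number (>= 6) of normalized
    coordinates.  Malformed lines raise with their 1-based line number.
    """
    if isinstance(source, (str, FsPath)):
        with open(source) as f:
            lines = f.readlines()
    elif isinstance(source, io.IOBase):
        lines = source.readlines()
    else:
        lines = list(source)
    out = []
    for ln, raw in enumerate(lines, start=1):
        raw = raw.strip()
        if not raw:
            continue
        parts = raw.split()
        try:
            cid = int(parts[0])
            coords = [float(v) for v in parts[1:]]
        except ValueError as e:
            raise PodkitError(f"line {ln}: unparseable token ({e})") from None
        if len(coords) < 6 or len(coords) % 2:
            raise PodkitError(
                f"line {ln}: expected an even number >= 6 of coordinates, "
                f"got {len(coords)}")
        if min(coords) < 0.0 or max(coords) > 1.0:
            bad = next(v for v in coords if not 0.0 <= v <= 1.0)
            raise PodkitError(f"line {ln}: coordinate {bad} outside [0, 1]")
        poly = np.array(coords, dtype=float).reshape(-1, 2)
        out.append(InstanceAnnotation.from_polygon(cid, poly, image_size))
    return out


def write_labels(target, annotations: list[InstanceAnnotation],
                 precision: int = 6) -> None:
    """Write annotations in the polygon-per-line dialect (one line per ring)."""
    lines = []
    for ann in annotations:
        rings = ann.polygons or mask_to_polygon(ann.mask)
        for ring in rings:
            coords = " ".join(f"{v:.{precision}f}" for v in np.asarray(ring).ravel())
            lines.append(f"{ann.class_id} {coords}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(target, (str, FsPath)):
        with open(target, "w") as f:
            f.write(text)
    else:
        target.write(text)


# ---------------------------------------------------------------------------
# splits and statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSplit:
    train: tuple
    val: tuple
    test: tuple
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        total = len(self.train) + len(self.val) + len(self.test)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise PodkitError("split partitions overlap")


def split_dataset(ids, sizes: tuple[int, int, int] = (406, 47, 35),
                  seed: int = 0) -> DatasetSplit:
    """Uniformly random, seed-reproducible train/val/test partition."""
    ids = list(ids)
    if sum(sizes) != len(ids):
        raise PodkitError(
            f"split sizes {sizes} sum to {sum(sizes)} but there are {len(ids)} ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n1, n2, _ = sizes
    pick = lambda sl: tuple(ids[i] for i in order[sl])
    return DatasetSplit(train=pick(slice(0, n1)),
                        val=pick(slice(n1, n1 + n2)),
                        test=pick(slice(n1 + n2, None)), seed=seed)


@dataclass
class DatasetStats:
    per_image_counts: list[int]
    mean_instances: float
    total_instances: int
    per_image_areas: list[list[int]]
    density: np.ndarray  # (G, G) bounding-box-center histogram

    def __post_init__(self) -> None:
        if int(self.density.sum()) != self.total_instances:
            raise PodkitError("density grid does not conserve the instance count")


def compute_stats(annotations_per_image: list[list[InstanceAnnotation]],
                  grid: int = 64) -> DatasetStats:
    """Per-image counts/areas and the normalized box-center density map."""
    counts, areas = [], []
    density = np.zeros((grid, grid), dtype=int)
    for anns in annotations_per_image:
        counts.append(len(anns))
        areas.append([a.area for a in anns])
        for a in anns:
            x1, y1, x2, y2 = a.box
            h, w = a.image_size
            cx, cy = (x1 + x2) / 2.0 / w, (y1 + y2) / 2.0 / h
            col = min(int(cx * grid), grid - 1)
            row = min(int(cy * grid), grid - 1)
            density[row, col] += 1
    total = int(sum(counts))
    mean = total / len(counts) if counts else 0.0
    return DatasetStats(per_image_counts=counts, mean_instances=mean,
                        total_instances=total, per_image_areas=areas,
                        density=density)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_OPS = {"crop", "rotate", "flip_h", "flip_v"}
MIN_INSTANCE_PIXELS = 3


def augment(image: np.ndarray, annotations: list[InstanceAnnotation],
            ops, seed: int = 0, *, crop_frac: float = 0.8,
            crop_window: tuple[int, int, int, int] | None = None,
            rotate_quarters: int | None = None):
    """Apply geometric training augmentations to an image and its masks.

    ``ops`` is an ordered subset of {crop, rotate, flip_h, flip_v} (hyphens
    accepted).  Rotation is by quarter turns (area-preserving); cropping
    uses ``crop_window`` = (row, col, height, width) when given, otherwise a
    seed-determined window of side ``crop_frac`` times the image.  Masks
    transform with the image; instances reduced below
    ``MIN_INSTANCE_PIXELS`` are dropped.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image)
    masks = [a.mask.copy() for a in annotations]
    cids = [a.class_id for a in annotations]

    for op in ops:
        op = str(op).replace("-", "_")
        if op not in _OPS:
            raise InvalidConfigError(f"unknown augmentation op {op!r}")
        if op == "flip_h":
            img = img[:, ::-1].copy()
            masks = [m[:, ::-1].copy() for m in masks]
        elif op == "flip_v":
            img = img[::-1].copy()
            masks = [m[::-1].copy() for m in masks]
        elif op == "rotate":
            k = rotate_quarters if rotate_quarters is not None else int(rng.integers(1, 4))
            img = np.rot90(img, k).copy()
            masks = [np.rot90(m, k).copy() for m in masks]
        elif op == "crop":
            h, w = img.shape[:2]
            if crop_window is not None:
                r0, c0, ch, cw = crop_window
            else:
                ch, cw = int(h * crop_frac), int(w * crop_frac)
                r0 = int(rng.integers(0, h - ch + 1))
                c0 = int(rng.integers(0, w - cw + 1))
            if r0 < 0 or c0 < 0 or r0 + ch > h or c0 + cw > w or ch < 1 or cw < 1:
                raise PodkitError(
                    f"crop window {(r0, c0, ch, cw)} outside image of size {(h, w)}")
            img = img[r0:r0 + ch, c0:c0 + cw].copy()
            masks = [m[r0:r0 + ch, c0:c0 + cw].copy() for m in masks]

    out_anns = []
    for cid, m in zip(cids, masks):
        if m.sum() >= MIN_INSTANCE_PIXELS:
            out_anns.append(InstanceAnnotation.from_mask(cid, m))
    return img, out_anns
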