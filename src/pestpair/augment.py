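"""Preprocessing and augmentation operators for multi-label insect scenes.

All operators are pure functions over ``(sample, rng)``: letterbox resize,
CutMix with area-ratio soft labels, periodic GridMask occlusion, small-object
copy-scale-paste, a multi-scale resize pyramid, and photometric/geometric
jitter. Boxes use the package-wide half-open pixel convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "AugmentedSample",
    "PyramidSet",
    "resize_letterbox",
    "cutmix",
    "gridmask",
    "small_object_boost",
    "build_pyramid",
    "photometric_geometric_jitter",
    "JitterConfig",
    "SMALL_OBJECT_AREA_FRACTION",
]

# A box is "small" when it covers less than 0.5% of the image, mirroring the
# 32^2-in-640^2 small-object convention from common detection benchmarks.
SMALL_OBJECT_AREA_FRACTION = 0.005


@dataclass
class AugmentedSample:
    image: np.ndarray
    soft_labels: np.ndarray  # length-C, entries in [0, 1]
    boxes: list[tuple]  # (category, x0, y0, x1, y1)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.soft_labels = np.asarray(self.soft_labels, dtype=np.float64)
        if np.any(self.soft_labels < 0) or np.any(self.soft_labels > 1):
            raise ValueError("soft labels must lie in [0, 1]")
        h, w = self.image.shape[:2]
        for _, x0, y0, x1, y1 in self.boxes:
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError("augmented box outside image bounds")


@dataclass
class PyramidSet:
    scales: list[float]
    images: list[np.ndarray]


def resize_letterbox(
    image: np.ndarray,
    target_h: int,
    target_w: int,
    boxes: list[tuple] | None = None,
    fill: tuple[int, int, int] | None = None,
):
    """Aspect-preserving resize with centred constant-colour padding.

    Content is scaled by ``min(target_h/H, target_w/W)`` and boxes follow the
    same affine map. ``fill`` defaults to the image mean colour to avoid hard
    pad edges. Returns ``image`` or ``(image, boxes)`` when boxes are given.
    """
    if target_h < 1 or target_w < 1:
        raise ValueError("target dimensions must be >= 1")
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]
    scale = min(target_h / h, target_w / w)
    new_h, new_w = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    resized = np.asarray(
        Image.fromarray(image).resize((new_w, new_h), Image.BILINEAR), dtype=image.dtype
    )
    if fill is None:
        fill = tuple(int(round(v)) for v in image.reshape(-1, image.shape[-1]).mean(axis=0))
    out = np.empty((target_h, target_w, image.shape[-1]), dtype=image.dtype)
    out[...] = np.asarray(fill, dtype=image.dtype)
    off_y = (target_h - new_h) // 2
    off_x = (target_w - new_w) // 2
    out[off_y : off_y + new_h, off_x : off_x + new_w] = resized
    if boxes is None:
        return out
    new_boxes = []
    for c, x0, y0, x1, y1 in boxes:
        nx0 = int(round(x0 * scale)) + off_x
        ny0 = int(round(y0 * scale)) + off_y
        nx1 = int(round(x1 * scale)) + off_x
        ny1 = int(round(y1 * scale)) + off_y
        if nx1 > nx0 and ny1 > ny0:
            new_boxes.append((c, nx0, ny0, nx1, ny1))
    return out, new_boxes


def _box_overlap(box_a, box_b) -> int:
    _, ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    return max(0, min(ax1, bx1) - max(ax0, bx0)) * max(0, min(ay1, by1) - max(ay0, by0))


def cutmix(
    sample_a,
    sample_b,
    region: tuple[int, int, int, int] | None = None,
    rng: np.random.Generator | None = None,
    min_visible: float = 0.25,
) -> AugmentedSample:
    """Paste a rectangle of image A onto image B; mix labels by area ratio.

    The binary mask M is 1 inside ``region`` (half-open ``x0, y0, x1, y1``),
    so the output is ``M*x_A + (1-M)*x_B`` and
    ``soft = lam*y_A + (1-lam)*y_B`` with ``lam = |M| / (H*W)``. Boxes from A
    are clipped to the region; boxes from either source are dropped when
    their visible area falls below ``min_visible`` of the original box.
    """
    if sample_a.image.shape != sample_b.image.shape:
        raise ValueError("cutmix requires images of identical shape")
    h, w = sample_a.image.shape[:2]
    if region is None:
        rng = rng or np.random.default_rng()
        frac = rng.uniform(0.1, 0.5)
        rw = max(1, int(round(w * np.sqrt(frac))))
        rh = max(1, int(round(h * np.sqrt(frac))))
        x0 = int(rng.integers(0, w - rw + 1))
        y0 = int(rng.integers(0, h - rh + 1))
        region = (x0, y0, x0 + rw, y0 + rh)
    x0, y0, x1, y1 = region
    if not (0 <= x0 <= x1 <= w and 0 <= y0 <= y1 <= h):
        raise ValueError("cutmix region outside image bounds")

    out = sample_b.image.copy()
    out[y0:y1, x0:x1] = sample_a.image[y0:y1, x0:x1]
    lam = (x1 - x0) * (y1 - y0) / (h * w)
    ya = np.asarray(sample_a.labels if hasattr(sample_a, "labels") else sample_a.soft_labels, float)
    yb = np.asarray(sample_b.labels if hasattr(sample_b, "labels") else sample_b.soft_labels, float)
    soft = lam * ya + (1.0 - lam) * yb

    boxes = []
    for c, bx0, by0, bx1, by1 in sample_a.boxes:
        area = (bx1 - bx0) * (by1 - by0)
        cx0, cy0 = max(bx0, x0), max(by0, y0)
        cx1, cy1 = min(bx1, x1), min(by1, y1)
        visible = max(0, cx1 - cx0) * max(0, cy1 - cy0)
        if area > 0 and visible / area >= min_visible:
            boxes.append((c, cx0, cy0, cx1, cy1))
    for box in sample_b.boxes:
        c, bx0, by0, bx1, by1 = box
        area = (bx1 - bx0) * (by1 - by0)
        visible = area - _box_overlap(box, region)
        if area > 0 and visible / area >= min_visible:
            boxes.append(box)
    return AugmentedSample(out, np.clip(soft, 0, 1), boxes, provenance=[f"cutmix(lam={lam:.4f})"])


def gridmask(
    image: np.ndarray,
    unit: int,
    keep_ratio: float,
    offsets: tuple[int, int] | None = (0, 0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero a periodic grid of square blocks: ``x * (1 - G)``.

    The mask G tiles the image with period ``unit``; within each cell a
    square block of side ``round((1 - keep_ratio) * unit)`` at ``offsets``
    is removed, so the masked fraction is ``(1 - keep_ratio)**2`` on
    divisible dimensions.
    """
    h, w = image.shape[:2]
    if unit < 2:
        raise ValueError("unit must be >= 2")
    if unit > min(h, w):
        raise ValueError("unit larger than the image")
    if not (0.0 <= keep_ratio <= 1.0):
        raise ValueError("keep_ratio must lie in [0, 1]")
    if offsets is None:
        rng = rng or np.random.default_rng()
        offsets = (int(rng.integers(0, unit)), int(rng.integers(0, unit)))
    block = int(round((1.0 - keep_ratio) * unit))
    if block == 0:
        return image.copy()
    oy, ox = offsets
    rows = ((np.arange(h) - oy) % unit) < block
    cols = ((np.arange(w) - ox) % unit) < block
    g = np.outer(rows, cols)
    out = image.copy()
    out[g] = 0
    return out


def small_object_boost(
    sample,
    n_copies: int,
    scale_factor: float,
    rng: np.random.Generator,
    area_threshold: float = SMALL_OBJECT_AREA_FRACTION,
    max_attempts: int = 20,
) -> AugmentedSample:
    """Duplicate small-object patches at scaled size into free locations.

    Each box covering less than ``area_threshold`` of the image is cropped,
    scaled by ``scale_factor`` and pasted (overwrite, not blended) at up to
    ``n_copies`` uniformly sampled locations that do not overlap existing
    boxes; placements that fail after ``max_attempts`` tries are skipped.
    Labels are unchanged — the copied categories are already present.
    """
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    image = sample.image.copy()
    h, w = image.shape[:2]
    boxes = list(sample.boxes)
    labels = np.asarray(sample.labels if hasattr(sample, "labels") else sample.soft_labels, float)
    small = [b for b in boxes if (b[3] - b[1]) * (b[4] - b[2]) < area_threshold * h * w]
    if not small or n_copies == 0:
        return AugmentedSample(image, labels, boxes, provenance=["small_object_boost(noop)"])
    placed = 0
    for c, bx0, by0, bx1, by1 in small:
        patch = image[by0:by1, bx0:bx1]
        ph = max(1, int(round((by1 - by0) * scale_factor)))
        pw = max(1, int(round((bx1 - bx0) * scale_factor)))
        if ph >= h or pw >= w:
            continue
        patch = np.asarray(Image.fromarray(patch).resize((pw, ph), Image.BILINEAR))
        for _ in range(n_copies):
            for _attempt in range(max_attempts):
                nx0 = int(rng.integers(0, w - pw + 1))
                ny0 = int(rng.integers(0, h - ph + 1))
                cand = (nx0, ny0, nx0 + pw, ny0 + ph)
                if all(_box_overlap(b, cand) == 0 for b in boxes):
                    image[ny0 : ny0 + ph, nx0 : nx0 + pw] = patch
                    boxes.append((c, *cand))
                    placed += 1
                    break
    return AugmentedSample(
        image, labels, boxes, provenance=[f"small_object_boost(placed={placed})"]
    )


def build_pyramid(image: np.ndarray, scales: list[float]) -> PyramidSet:
    """Aspect-preserving resized copies of the image, one per scale factor."""
    if not scales:
        raise ValueError("scales must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    h, w = image.shape[:2]
    images = []
    for s in scales:
        nh, nw = max(1, int(round(h * s))), max(1, int(round(w * s)))
        if (nh, nw) == (h, w):
            images.append(image.copy())
        else:
            images.append(np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR)))
    return PyramidSet(list(scales), images)


@dataclass
class JitterConfig:
    brightness: float = 0.2  # multiplicative range half-width
    crop: float = 0.1  # max fraction cropped per side before resize back
    hflip: bool = True
    rotate_deg: float = 10.0


def photometric_geometric_jitter(
    image: np.ndarray,
    config: JitterConfig,
    rng: np.random.Generator,
    brightness_scale: float | None = None,
) -> np.ndarray:
    """Brightness scaling, random crop-and-resize, flip and small rotation.

    Deterministic under a seeded ``rng``; with all magnitudes zero and flips
    disabled the input is returned unchanged. ``brightness_scale`` overrides
    the sampled factor (useful for controlled tests).
    """
    out = image
    scale = brightness_scale
    if scale is None:
        scale = 1.0 if config.brightness == 0 else rng.uniform(
            1.0 - config.brightness, 1.0 + config.brightness
        )
    if scale != 1.0:
        out = np.clip(np.round(out.astype(np.float64) * scale), 0, 255).astype(image.dtype)
    h, w = out.shape[:2]
    if config.crop > 0:
        cx0 = int(rng.uniform(0, config.crop) * w)
        cx1 = w - int(rng.uniform(0, config.crop) * w)
        cy0 = int(rng.uniform(0, config.crop) * h)
        cy1 = h - int(rng.uniform(0, config.crop) * h)
        if (cy1 - cy0, cx1 - cx0) != (h, w):
            out = np.asarray(
                Image.fromarray(out[cy0:cy1, cx0:cx1]).resize((w, h), Image.BILINEAR)
            )
    if config.hflip and rng.random() < 0.5:
        out = out[:, ::-1].copy()
    if config.rotate_deg > 0:
        angle = rng.uniform(-config.rotate_deg, config.rotate_deg)
        out = np.asarray(Image.fromarray(out).rotate(angle, Image.BILINEAR))
    return out
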