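"""Seedable synthetic predator/pest scene generator.

Scenes are procedurally drawn glyph compositions on cluttered backgrounds:
each of the eight categories has a distinct shape/colour glyph, pests are
rendered small (average box area under 1% of the canvas), and category
co-presence follows the planted :class:`~pestpair.schema.CooccurrenceModel`.
Every emitted byte — pixels, boxes, JSON — is a deterministic function of
(schema, model, seed).

Pixel coordinates are 0-based and boxes are half-open ``[x_min, x_max) x
[y_min, y_max)`` everywhere in this package; the COCO JSON written by
:func:`generate_dataset` uses COCO's ``[x, y, width, height]`` convention and
1-based category ids, converted internally on load.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .schema import CategorySchema, CooccurrenceModel

__all__ = [
    "SceneSample",
    "sample_scene",
    "generate_dataset",
    "split_train_val",
    "holdout_pair_split",
    "load_manifest",
    "manifest_arrays",
]

Box = tuple[int, int, int, int, int]  # (category, x0, y0, x1, y1), half-open


@dataclass
class SceneSample:
    image: np.ndarray  # H x W x 3 uint8
    labels: np.ndarray  # length-C multi-hot
    boxes: list[Box]
    seed_record: dict = field(default_factory=dict)

    def __post_init__(self):
        h, w = self.image.shape[:2]
        present = np.zeros_like(self.labels)
        for c, x0, y0, x1, y1 in self.boxes:
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"box ({x0},{y0},{x1},{y1}) outside {w}x{h} canvas")
            present[c] = 1
        if not np.array_equal(present, self.labels):
            raise ValueError("labels vector does not match box categories")


# --------------------------------------------------------------------- glyphs

_SIZE_FRACTIONS = {"small": (0.07, 0.11), "medium": (0.12, 0.20), "large": (0.20, 0.30)}


def _jitter_colour(rgb, rng, amount=18):
    return tuple(int(np.clip(v + rng.integers(-amount, amount + 1), 0, 255)) for v in rgb)


def _draw_glyph(draw: ImageDraw.ImageDraw, glyph: str, box, rng: np.random.Generator):
    x0, y0, x1, y1 = box
    w, h = x1 - x0, y1 - y0
    if glyph == "red-ellipse-black-spots":
        draw.ellipse([x0, y0, x1 - 1, y1 - 1], fill=_jitter_colour((200, 30, 30), rng))
        for _ in range(3):
            sx = x0 + int(rng.uniform(0.2, 0.7) * w)
            sy = y0 + int(rng.uniform(0.2, 0.7) * h)
            r = max(1, w // 8)
            draw.ellipse([sx, sy, sx + r, sy + r], fill=(10, 10, 10))
    elif glyph == "cyan-lacewing-veined":
        draw.ellipse([x0, y0 + h // 4, x1 - 1, y1 - 1 - h // 4], fill=_jitter_colour((40, 210, 220), rng))
        for k in range(1, 4):
            draw.line([x0 + k * w // 4, y0 + h // 4, x0 + k * w // 4, y1 - h // 4], fill=(10, 90, 110))
    elif glyph == "navy-oval-white-band":
        draw.ellipse([x0, y0, x1 - 1, y1 - 1], fill=_jitter_colour((25, 30, 90), rng))
        draw.rectangle([x0, y0 + h // 2 - max(1, h // 8), x1 - 1, y0 + h // 2 + max(1, h // 8)], fill=(230, 230, 230))
    elif glyph == "amber-wasp-wedge":
        draw.polygon([(x0, y1 - 1), (x0 + w // 2, y0), (x1 - 1, y1 - 1)], fill=_jitter_colour((230, 170, 40), rng))
    elif glyph == "pink-cluster-dot":
        for _ in range(3):
            cx = x0 + int(rng.uniform(0.1, 0.6) * w)
            cy = y0 + int(rng.uniform(0.1, 0.6) * h)
            r = max(1, w // 3)
            draw.ellipse([cx, cy, min(cx + r, x1 - 1), min(cy + r, y1 - 1)], fill=_jitter_colour((250, 170, 195), rng, amount=12))
    elif glyph == "magenta-sliver":
        mid = y0 + h // 2
        draw.ellipse([x0, max(y0, mid - max(1, h // 3)), x1 - 1, min(y1 - 1, mid + max(1, h // 3))], fill=_jitter_colour((235, 25, 130), rng, amount=12))
    elif glyph == "cream-striped-larva":
        draw.ellipse([x0, y0 + h // 5, x1 - 1, y1 - 1 - h // 5], fill=_jitter_colour((245, 245, 235), rng, amount=8))
        for k in range(1, 4):
            draw.line([x0 + k * w // 4, y0 + h // 5, x0 + k * w // 4, y1 - h // 5], fill=(15, 15, 15))
    elif glyph == "violet-wedge-hopper":
        draw.ellipse([x0, y0, x1 - 1, y1 - 1], fill=_jitter_colour((150, 60, 230), rng))
        draw.polygon([(x1 - 1, y0), (x1 - 1, y1 - 1), (x0 + w // 2, y0 + h // 2)], fill=_jitter_colour((90, 20, 160), rng))
    else:  # pragma: no cover - schema is validated upstream
        raise ValueError(f"unknown glyph {glyph!r}")


def _draw_background(draw, size, rng):
    base = _jitter_colour((70, 100, 55), rng, amount=25)
    draw.rectangle([0, 0, size - 1, size - 1], fill=base)
    for _ in range(int(rng.integers(6, 14))):  # leafy clutter blobs
        cx, cy = rng.integers(0, size, size=2)
        r = int(rng.integers(size // 16, size // 4))
        col = _jitter_colour((60 + rng.integers(0, 60), 90 + rng.integers(0, 70), 40), rng)
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=tuple(int(v) for v in col))
    for _ in range(int(rng.integers(3, 8))):  # stem-like strokes
        x0, y0 = rng.integers(0, size, size=2)
        x1b, y1b = rng.integers(0, size, size=2)
        draw.line([int(x0), int(y0), int(x1b), int(y1b)], fill=(95, 125, 70), width=1 + int(size >= 128))


def sample_scene(
    schema: CategorySchema,
    model: CooccurrenceModel,
    canvas_size: int = 224,
    rng_seed: int = 0,
) -> SceneSample:
    """Render one synthetic scene; deterministic given ``rng_seed``.

    Category presence is drawn from the pairwise-coupled Bernoulli model,
    each present category is rendered as at least one glyph, and mild
    occlusion clutter is painted over a random instance edge.
    """
    if rng_seed < 0:
        raise ValueError("rng_seed must be non-negative")
    if canvas_size < 32:
        raise ValueError("canvas_size must be at least 32")
    if model.n_categories != schema.n_categories:
        raise ValueError("co-occurrence model size does not match schema")
    rng = np.random.default_rng(rng_seed)
    presence = model.sample_presence(rng)

    img = Image.new("RGB", (canvas_size, canvas_size))
    draw = ImageDraw.Draw(img)
    _draw_background(draw, canvas_size, rng)

    boxes: list[Box] = []
    for ci in np.flatnonzero(presence):
        record = schema.categories[ci]
        if record.role == "pest":  # pests cluster: dense scenes are the norm
            n_inst = 2 + int(rng.random() < 0.5) + int(rng.random() < 0.3)
        else:
            n_inst = 1 + int(rng.random() < 0.3)
        lo, hi = _SIZE_FRACTIONS[record.size_class]
        for _ in range(n_inst):
            side = max(3, int(round(rng.uniform(lo, hi) * canvas_size)))
            aspect = rng.uniform(0.7, 1.4)
            bw = min(canvas_size, max(3, int(round(side * aspect))))
            bh = min(canvas_size, side)
            x0 = int(rng.integers(0, canvas_size - bw + 1))
            y0 = int(rng.integers(0, canvas_size - bh + 1))
            box = (x0, y0, x0 + bw, y0 + bh)
            _draw_glyph(draw, record.glyph, box, rng)
            boxes.append((int(ci), *box))

    # partial occlusion: paint a foliage blob over one box corner
    if boxes and rng.random() < 0.4:
        c, x0, y0, x1, y1 = boxes[int(rng.integers(0, len(boxes)))]
        r = max(2, (x1 - x0) // 3)
        cx = x0 if rng.random() < 0.5 else x1 - 1
        cy = y0 if rng.random() < 0.5 else y1 - 1
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=_jitter_colour((65, 95, 50), rng))

    labels = presence.astype(np.int64)
    return SceneSample(
        image=np.asarray(img, dtype=np.uint8),
        labels=labels,
        boxes=boxes,
        seed_record={"rng_seed": int(rng_seed), "canvas_size": int(canvas_size)},
    )


# ------------------------------------------------------------------- datasets


def _coco_dict(schema: CategorySchema, samples_meta) -> dict:
    categories = [
        {"id": i + 1, "name": c.name, "supercategory": c.role}
        for i, c in enumerate(schema.categories)
    ]
    images, annotations = [], []
    ann_id = 1
    for meta in samples_meta:
        images.append(
            {
                "id": meta["id"],
                "file_name": meta["file"],
                "width": meta["canvas"],
                "height": meta["canvas"],
                "multi_hot": meta["labels"],
            }
        )
        for c, x0, y0, x1, y1 in meta["boxes"]:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": meta["id"],
                    "category_id": c + 1,
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "area": (x1 - x0) * (y1 - y0),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {"images": images, "annotations": annotations, "categories": categories}


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def generate_dataset(
    n: int,
    schema: CategorySchema,
    model: CooccurrenceModel,
    seed: int,
    out_dir: str | Path,
    canvas_size: int = 224,
) -> Path:
    """Write ``n`` PNG scenes plus COCO-style JSON and a seeded manifest.

    Returns the manifest path. Regeneration with the same arguments
    reproduces identical annotation bytes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    samples_meta = []
    for i in range(n):
        s = sample_scene(schema, model, canvas_size, int(child_seeds[i]))
        fname = f"scene_{i:05d}.png"
        Image.fromarray(s.image).save(out_dir / fname)
        samples_meta.append(
            {
                "id": i,
                "file": fname,
                "canvas": canvas_size,
                "labels": [int(v) for v in s.labels],
                "boxes": [[int(v) for v in b] for b in s.boxes],
                "seed": int(child_seeds[i]),
            }
        )
    _write_json(out_dir / "annotations.json", _coco_dict(schema, samples_meta))
    manifest = {
        "seed": int(seed),
        "n": int(n),
        "canvas_size": int(canvas_size),
        "categories": [
            {"name": c.name, "role": c.role, "glyph": c.glyph, "size_class": c.size_class}
            for c in schema.categories
        ],
        "canonical_pairs": [list(p) for p in schema.canonical_pairs],
        "marginals": [float(v) for v in model.marginals],
        "coupled": [[int(i), int(j), float(q)] for (i, j), q in sorted(model.coupled.items())],
        "coco_json": "annotations.json",
        "images": [
            {"id": m["id"], "file": m["file"], "labels": m["labels"], "seed": m["seed"],
             "boxes": m["boxes"]}
            for m in samples_meta
        ],
    }
    manifest_path = out_dir / "manifest.json"
    _write_json(manifest_path, manifest)
    return manifest_path


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def manifest_arrays(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load (images, labels) arrays for every image referenced by a manifest."""
    manifest = load_manifest(path)
    base = Path(path).parent
    images = np.stack(
        [np.asarray(Image.open(base / rec["file"]), dtype=np.uint8) for rec in manifest["images"]]
    )
    labels = np.asarray([rec["labels"] for rec in manifest["images"]], dtype=np.int64)
    return images, labels


def _write_submanifest(src_manifest: dict, records: list[dict], path: Path, extra: dict) -> Path:
    sub = {k: v for k, v in src_manifest.items() if k != "images"}
    sub.update(extra)
    sub["n"] = len(records)
    sub["images"] = records
    _write_json(path, sub)
    return path


def split_train_val(
    manifest_path: str | Path, ratio: float, seed: int
) -> tuple[Path, Path]:
    """Stratified train/validation split by exact label multiset.

    Images are grouped by their multi-hot vector and each group is divided
    ``ratio : 1-ratio`` (largest-remainder rounding keeps the overall split
    exact), so per-category prevalence is preserved in both halves. A
    category appearing in fewer than two images cannot be stratified; a
    warning is emitted and those images fall back to the random pool.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must lie strictly between 0 and 1")
    manifest = load_manifest(manifest_path)
    records = manifest["images"]
    n = len(records)
    labels = np.asarray([r["labels"] for r in records])
    per_cat = labels.sum(axis=0)
    rare = np.flatnonzero((per_cat > 0) & (per_cat < 2))
    if rare.size:
        warnings.warn(
            f"categories {rare.tolist()} have fewer than 2 images; "
            "falling back to random assignment for their images"
        )
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[int]] = {}
    for idx, r in enumerate(records):
        groups.setdefault(tuple(r["labels"]), []).append(idx)

    target_train = int(round(n * ratio))
    keys = sorted(groups)
    base_counts, remainders = [], []
    for k in keys:
        size = len(groups[k])
        exact = size * ratio
        base_counts.append(int(np.floor(exact)))
        remainders.append(exact - np.floor(exact))
    deficit = target_train - sum(base_counts)
    order = sorted(range(len(keys)), key=lambda i: (-remainders[i], i))
    for i in order:
        if deficit <= 0:
            break
        if base_counts[i] < len(groups[keys[i]]):
            base_counts[i] += 1
            deficit -= 1

    train_idx, val_idx = [], []
    for k, take in zip(keys, base_counts):
        idxs = list(groups[k])
        rng.shuffle(idxs)
        train_idx.extend(idxs[:take])
        val_idx.extend(idxs[take:])
    train_idx.sort()
    val_idx.sort()

    src = Path(manifest_path)
    train_path = src.with_name(src.stem + "_train.json")
    val_path = src.with_name(src.stem + "_val.json")
    meta = {"split_seed": int(seed), "split_ratio": float(ratio), "parent": src.name}
    _write_submanifest(manifest, [records[i] for i in train_idx], train_path, meta)
    _write_submanifest(manifest, [records[i] for i in val_idx], val_path, meta)
    return train_path, val_path


def holdout_pair_split(
    manifest_path: str | Path, pairs: list[tuple[int, int]]
) -> tuple[Path, Path]:
    """Move every image jointly containing a held-out pair to the test set.

    Images containing only one member of a pair stay in train, so each
    category remains individually learnable while the joint combination is
    unseen.
    """
    manifest = load_manifest(manifest_path)
    roles = [c["role"] for c in manifest["categories"]]
    n_cat = len(roles)
    for i, j in pairs:
        if not (0 <= i < n_cat and 0 <= j < n_cat):
            raise ValueError(f"holdout pair ({i},{j}) indexes unknown categories")
        if roles[i] == roles[j]:
            warnings.warn(f"holdout pair ({i},{j}) joins two {roles[i]}s; allowed but unusual")
    records = manifest["images"]
    test_records, train_records = [], []
    for r in records:
        joint = any(r["labels"][i] and r["labels"][j] for i, j in pairs)
        (test_records if joint else train_records).append(r)
    src = Path(manifest_path)
    train_path = src.with_name(src.stem + "_pairtrain.json")
    test_path = src.with_name(src.stem + "_pairtest.json")
    meta = {"holdout_pairs": [list(p) for p in pairs], "parent": src.name}
    _write_submanifest(manifest, train_records, train_path, meta)
    _write_submanifest(manifest, test_records, test_path, meta)
    return train_path, test_path
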