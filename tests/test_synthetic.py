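"""Synthetic scene generator: determinism, consistency, planted structure,
dataset writing and manifest splits."""

import json
from pathlib import Path

import numpy as np
import pytest

from pestpair import (
    CooccurrenceModel,
    generate_dataset,
    holdout_pair_split,
    sample_scene,
    split_train_val,
)
from pestpair.synthetic import load_manifest, manifest_arrays


class TestSampleScene:
    def test_same_seed_byte_identical(self, schema, cooc):
        a = sample_scene(schema, cooc, 64, rng_seed=41)
        b = sample_scene(schema, cooc, 64, rng_seed=41)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.labels, b.labels)
        assert a.boxes == b.boxes

    def test_labels_match_box_categories(self, schema, cooc):
        for seed in range(40):
            s = sample_scene(schema, cooc, 64, rng_seed=seed)
            cats = {b[0] for b in s.boxes}
            assert set(np.flatnonzero(s.labels)) == cats

    def test_boxes_inside_canvas(self, schema, cooc):
        for seed in range(40):
            s = sample_scene(schema, cooc, 96, rng_seed=seed)
            for _, x0, y0, x1, y1 in s.boxes:
                assert 0 <= x0 < x1 <= 96 and 0 <= y0 < y1 <= 96

    def test_zero_marginals_give_empty_scene(self, schema):
        model = CooccurrenceModel(np.zeros(8))
        s = sample_scene(schema, model, 64, rng_seed=5)
        assert s.labels.sum() == 0
        assert s.boxes == []

    def test_negative_seed_rejected(self, schema, cooc):
        with pytest.raises(ValueError, match="non-negative"):
            sample_scene(schema, cooc, 64, rng_seed=-1)

    def test_tiny_canvas_rejected(self, schema, cooc):
        with pytest.raises(ValueError, match="at least 32"):
            sample_scene(schema, cooc, 16, rng_seed=0)

    def test_pest_boxes_small_on_average(self, schema, cooc):
        areas = []
        for seed in range(60):
            s = sample_scene(schema, cooc, 128, rng_seed=seed)
            for c, x0, y0, x1, y1 in s.boxes:
                if schema.categories[c].role == "pest":
                    areas.append((x1 - x0) * (y1 - y0))
        assert np.mean(areas) < 0.01 * 128 * 128

    def test_planted_copresence_frequency(self, schema):
        """Empirical ladybug-aphid co-presence matches the configured joint."""
        marg = np.full(8, 0.5)
        model = CooccurrenceModel(marg, {(0, 4): 0.4})
        rng = np.random.default_rng(7)
        draws = np.array([model.sample_presence(rng) for _ in range(10000)])
        freq = np.mean(draws[:, 0] & draws[:, 4])
        se = np.sqrt(0.4 * 0.6 / 10000)
        assert abs(freq - 0.4) <= 3 * se


class TestGenerateDataset:
    def test_file_and_entry_counts(self, desk_dataset):
        manifest = load_manifest(desk_dataset)
        base = Path(desk_dataset).parent
        assert manifest["n"] == 80
        assert len(manifest["images"]) == 80
        assert len(list(base.glob("scene_*.png"))) == 80
        coco = json.loads((base / "annotations.json").read_text())
        assert len(coco["images"]) == 80
        assert len(coco["categories"]) == 8

    def test_coco_bbox_convention(self, desk_dataset):
        base = Path(desk_dataset).parent
        coco = json.loads((base / "annotations.json").read_text())
        for ann in coco["annotations"]:
            x, y, w, h = ann["bbox"]
            assert w > 0 and h > 0
            assert 0 <= x and x + w <= 64 and 0 <= y and y + h <= 64
        # category ids are 1-based in the COCO file
        assert {c["id"] for c in coco["categories"]} == set(range(1, 9))
        # COCO annotations agree with the manifest's half-open boxes
        manifest = load_manifest(desk_dataset)
        boxes_by_img = {img["id"]: img["boxes"] for img in manifest["images"]}
        for ann in coco["annotations"][:80]:
            x, y, w, h = ann["bbox"]
            assert [ann["category_id"] - 1, x, y, x + w, y + h] in boxes_by_img[ann["image_id"]]

    def test_regeneration_identical_annotations(self, schema, cooc, tmp_path):
        m1 = generate_dataset(12, schema, cooc, seed=5, out_dir=tmp_path / "a", canvas_size=64)
        m2 = generate_dataset(12, schema, cooc, seed=5, out_dir=tmp_path / "b", canvas_size=64)
        assert Path(m1).read_text() == Path(m2).read_text()
        a1 = (Path(m1).parent / "annotations.json").read_text()
        a2 = (Path(m2).parent / "annotations.json").read_text()
        assert a1 == a2

    def test_unwritable_out_dir_raises(self, schema, cooc, tmp_path):
        blocker = tmp_path / "blocker"
        blocker.write_text("a file, not a directory")
        with pytest.raises(OSError):
            generate_dataset(2, schema, cooc, seed=0, out_dir=blocker / "sub")

    def test_invalid_n_rejected(self, schema, cooc, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(0, schema, cooc, seed=0, out_dir=tmp_path)

    def test_category_frequencies_match_configured_marginals(self, schema, cooc):
        """Per-category presence counts track the configured frequencies."""
        rng = np.random.default_rng(31)
        n = 4000
        draws = np.array([cooc.sample_presence(rng) for _ in range(n)])
        obs = draws.mean(axis=0)
        for c in range(8):
            se = np.sqrt(cooc.marginals[c] * (1 - cooc.marginals[c]) / n)
            assert abs(obs[c] - cooc.marginals[c]) <= 4 * se

    def test_manifest_arrays_roundtrip(self, desk_dataset):
        images, labels = manifest_arrays(desk_dataset)
        assert images.shape == (80, 64, 64, 3)
        assert labels.shape == (80, 8)
        assert images.dtype == np.uint8


@pytest.fixture(scope="module")
def thousand(schema, cooc, tmp_path_factory):
    out = tmp_path_factory.mktemp("split_big")
    # labels only matter for splitting; a small canvas keeps rendering fast
    return generate_dataset(1000, schema, cooc, seed=77, out_dir=out, canvas_size=64)


class TestSplitTrainVal:
    def test_exact_ratio_split(self, thousand):
        tr, va = split_train_val(thousand, 0.7, seed=1)
        assert len(load_manifest(tr)["images"]) == 700
        assert len(load_manifest(va)["images"]) == 300

    def test_disjoint_union(self, thousand):
        tr, va = split_train_val(thousand, 0.7, seed=1)
        ids_tr = {r["id"] for r in load_manifest(tr)["images"]}
        ids_va = {r["id"] for r in load_manifest(va)["images"]}
        assert ids_tr.isdisjoint(ids_va)
        assert len(ids_tr | ids_va) == 1000

    def test_prevalence_preserved_within_tolerance(self, thousand):
        tr, va = split_train_val(thousand, 0.7, seed=1)
        ytr = np.array([r["labels"] for r in load_manifest(tr)["images"]])
        yva = np.array([r["labels"] for r in load_manifest(va)["images"]])
        diff = np.abs(ytr.mean(axis=0) - yva.mean(axis=0))
        assert np.all(diff <= 0.05)

    @pytest.mark.parametrize("ratio", [0.0, 1.0, -0.2])
    def test_invalid_ratio_rejected(self, thousand, ratio):
        with pytest.raises(ValueError):
            split_train_val(thousand, ratio, seed=0)

    def test_rare_category_warns(self, desk_dataset, tmp_path):
        manifest = load_manifest(desk_dataset)
        # force one category to appear in exactly one image
        for rec in manifest["images"]:
            rec["labels"][3] = 0
        manifest["images"][0]["labels"][3] = 1
        p = tmp_path / "rare.json"
        p.write_text(json.dumps(manifest))
        with pytest.warns(UserWarning, match="fewer than 2"):
            split_train_val(p, 0.7, seed=0)


class TestHoldoutPairSplit:
    def test_purity_brute_force(self, desk_dataset):
        pairs = [(1, 7)]
        tr, te = holdout_pair_split(desk_dataset, pairs)
        for rec in load_manifest(tr)["images"]:
            assert not (rec["labels"][1] and rec["labels"][7])

    def test_test_count_matches_linear_scan(self, desk_dataset):
        pairs = [(0, 4), (2, 5)]
        tr, te = holdout_pair_split(desk_dataset, pairs)
        records = load_manifest(desk_dataset)["images"]
        expected = sum(
            1 for r in records if any(r["labels"][i] and r["labels"][j] for i, j in pairs)
        )
        assert len(load_manifest(te)["images"]) == expected
        assert len(load_manifest(tr)["images"]) == len(records) - expected

    def test_single_member_images_stay_in_train(self, desk_dataset):
        tr, te = holdout_pair_split(desk_dataset, [(1, 7)])
        ytr = np.array([r["labels"] for r in load_manifest(tr)["images"]])
        assert ytr[:, 1].sum() > 0  # lacewing-only images survive
        assert ytr[:, 7].sum() > 0  # planthopper-only images survive

    def test_empty_pairs_all_train(self, desk_dataset):
        tr, te = holdout_pair_split(desk_dataset, [])
        assert len(load_manifest(te)["images"]) == 0
        assert len(load_manifest(tr)["images"]) == 80

    def test_same_role_pair_warns(self, desk_dataset):
        with pytest.warns(UserWarning, match="allowed but unusual"):
            holdout_pair_split(desk_dataset, [(0, 1)])

    def test_unknown_category_rejected(self, desk_dataset):
        with pytest.raises(ValueError):
            holdout_pair_split(desk_dataset, [(0, 42)])
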