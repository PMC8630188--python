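"""Cell detection, lymphocyte calling, infiltration scoring, masks."""

import numpy as np
import pandas as pd
import pytest

from tilescope.lymphocyte import (
    CellInventory,
    call_objects,
    detect_cells,
    infiltration_score,
    label_objects_by_truth,
    masks_from_inventory,
    train_lymphocyte_classifier,
)


class TestDetectCells:
    def test_blank_tile_empty_inventory(self):
        tile = np.full((64, 64, 3), 255, np.uint8)
        inv = detect_cells(tile)
        assert inv.n_objects == 0

    def test_planted_objects_recovered(self, planted_tile):
        """At least 18 of 20 planted cells found with centroids within
        3 px of the ground truth."""
        tile, objects, _, _ = planted_tile
        inv = detect_cells(tile)
        det = inv.features[["centroid_r", "centroid_c"]].to_numpy()
        truth = objects[["row", "col"]].to_numpy()
        d = np.sqrt(((det[:, None] - truth[None]) ** 2).sum(-1))
        matched = (d.min(axis=0) <= 3.0).sum()
        assert matched >= 18

    def test_deterministic(self, planted_tile):
        tile = planted_tile[0]
        a, b = detect_cells(tile), detect_cells(tile)
        np.testing.assert_array_equal(a.label_map, b.label_map)
        pd.testing.assert_frame_equal(a.features, b.features)

    def test_feature_ranges(self, planted_tile):
        inv = detect_cells(planted_tile[0])
        f = inv.features
        assert (f["circularity"] > 0).all() and (f["circularity"] <= 1).all()
        assert np.isfinite(f[["area", "perimeter", "solidity"]].to_numpy()).all()


@pytest.fixture(scope="module")
def object_training_table():
    """Morphometric features with truth labels pooled over several
    planted tiles."""
    from tilescope.synthetic import render_objects

    rng = np.random.default_rng(3)
    frames = []
    for _ in range(8):
        tile = np.full((224, 224, 3), 246.0)
        coords = [(28 + 42 * i, 28 + 42 * j) for i in range(5) for j in range(4)]
        rng.shuffle(coords)
        rows, cols = zip(*coords)
        n = len(coords)
        n_lymph = n // 2
        objects = pd.DataFrame(
            {
                "row": np.array(rows, float) + rng.uniform(-4, 4, n),
                "col": np.array(cols, float) + rng.uniform(-4, 4, n),
                "cell_type": ["lymphocyte"] * n_lymph
                + ["tumor_nucleus"] * (n - n_lymph),
                "r_major": np.r_[
                    rng.uniform(3, 6, n_lymph), rng.uniform(8, 14, n - n_lymph)
                ],
                "r_minor": np.r_[
                    rng.uniform(3, 6, n_lymph), rng.uniform(8, 14, n - n_lymph)
                ],
                "orientation": rng.uniform(0, np.pi, n),
            }
        )
        render_objects(tile, objects, rng)
        inv = detect_cells(tile.astype(np.uint8))
        labels = label_objects_by_truth(inv, objects)
        frames.append(inv.features.assign(cell_type=labels))
    return pd.concat(frames, ignore_index=True)


class TestLymphocyteClassifier:
    def test_separable_classes_high_balanced_accuracy(self, object_training_table):
        _, bal_acc = train_lymphocyte_classifier(object_training_table, seed=0)
        assert bal_acc >= 0.85

    def test_permuted_labels_near_chance(self, object_training_table):
        rng = np.random.default_rng(0)
        shuffled = object_training_table.copy()
        shuffled["cell_type"] = rng.permutation(shuffled["cell_type"].to_numpy())
        _, bal_acc = train_lymphocyte_classifier(shuffled, seed=0)
        assert abs(bal_acc - 0.5) < 0.15

    def test_seed_deterministic(self, object_training_table):
        f1, a1 = train_lymphocyte_classifier(object_training_table, seed=4)
        f2, a2 = train_lymphocyte_classifier(object_training_table, seed=4)
        assert a1 == a2
        from tilescope.lymphocyte import FEATURE_COLUMNS

        x = object_training_table[FEATURE_COLUMNS].to_numpy()
        np.testing.assert_array_equal(f1.predict(x), f2.predict(x))

    def test_single_class_rejected(self, object_training_table):
        only = object_training_table[
            object_training_table["cell_type"] == "lymphocyte"
        ]
        with pytest.raises(ValueError):
            train_lymphocyte_classifier(only)


def _inventory_with_calls(calls):
    n = len(calls)
    label_map = np.zeros((8, 8), np.int32)
    for i in range(n):
        label_map[i, :2] = i + 1
    features = pd.DataFrame({"label": np.arange(1, n + 1)})
    return CellInventory(
        tile_shape=(8, 8),
        label_map=label_map,
        features=features,
        calls=np.array(calls, dtype=object),
    )


class TestInfiltrationScore:
    def test_mean_of_tile_fractions(self):
        invs = [
            _inventory_with_calls(["lymphocyte", "other", "other", "other", "other"]),
            _inventory_with_calls(["lymphocyte", "lymphocyte", "other", "other", "other"]),
        ]
        score = infiltration_score("p", invs)
        assert score.score == pytest.approx(0.3)

    def test_extremes(self):
        all_lymph = [_inventory_with_calls(["lymphocyte"] * 4)]
        none = [_inventory_with_calls(["other"] * 4)]
        assert infiltration_score("p", all_lymph).score == 1.0
        assert infiltration_score("p", none).score == 0.0

    def test_cell_free_tiles_excluded(self):
        empty = _inventory_with_calls([])
        half = _inventory_with_calls(["lymphocyte", "other"])
        score = infiltration_score("p", [empty, half])
        assert score.score == pytest.approx(0.5)
        assert score.n_tiles == 1

    def test_all_cell_free_rejected(self):
        with pytest.raises(ValueError):
            infiltration_score("p", [_inventory_with_calls([])])

    def test_tile_order_invariant(self):
        invs = [
            _inventory_with_calls(["lymphocyte", "other"]),
            _inventory_with_calls(["other", "other"]),
        ]
        assert (
            infiltration_score("p", invs).score
            == infiltration_score("p", invs[::-1]).score
        )


class TestMasks:
    def test_lymph_mask_subset_of_nuclei(self, planted_tile):
        tile, objects, _, _ = planted_tile
        inv = detect_cells(tile)
        inv.calls = np.array(
            ["lymphocyte" if i % 2 else "other" for i in range(inv.n_objects)],
            dtype=object,
        )
        lymph, nuclei = masks_from_inventory(inv)
        assert not (lymph & ~nuclei).any()

    def test_no_lymph_calls_empty_mask(self):
        inv = _inventory_with_calls(["other", "other"])
        lymph, nuclei = masks_from_inventory(inv)
        assert not lymph.any()
        assert nuclei.sum() == (inv.label_map > 0).sum()

    def test_all_lymph_masks_identical(self):
        inv = _inventory_with_calls(["lymphocyte", "lymphocyte"])
        lymph, nuclei = masks_from_inventory(inv)
        np.testing.assert_array_equal(lymph, nuclei)
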