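"""First-layer activations, thresholding, colocalization, ablation."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from tilescope.classifier import AugmentConfig, TaskSpec, TrainConfig, build_model
from tilescope.interpret import (
    ActivationMap,
    _pearson,
    ablate_filter,
    ablate_filter_and_eval,
    colocalization_profile,
    first_layer_activations,
    threshold_activation,
)


def _model(input_hw=(32, 32), downscale=1, seed=0):
    task = TaskSpec("toy", [0, 1])
    cfg = TrainConfig(
        input_downscale=downscale, seed=seed, augment=AugmentConfig(0, 0, 0, False)
    )
    return build_model(task, cfg, input_hw=input_hw)


def brute_force_first_layer(model, tile):
    """Direct convolution oracle: per-filter valid cross-correlation of
    the preprocessed tile with the first-layer kernel, then ReLU."""
    x = model.preprocess(tile)[0]
    conv = model.first_conv
    maps = []
    for f in range(conv.W.shape[-1]):
        acc = np.zeros(
            (x.shape[0] - conv.kernel + 1, x.shape[1] - conv.kernel + 1)
        )
        for c in range(x.shape[2]):
            acc += correlate2d(
                x[..., c].astype(np.float64),
                conv.W[..., c, f].astype(np.float64),
                mode="valid",
            )
        maps.append(np.maximum(acc + conv.b[f], 0.0))
    return maps


class TestActivations:
    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(0)
        model = _model()
        tile = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        maps = first_layer_activations(model, tile)
        oracle = brute_force_first_layer(model, tile)
        for amap, expected in zip(maps, oracle):
            np.testing.assert_allclose(amap.grid, expected, atol=1e-5)

    def test_zero_kernel_constant_zero_map(self):
        model = _model()
        conv = model.first_conv
        conv.W[..., 0] = 0.0
        conv.b[0] = 0.0
        tile = np.random.default_rng(1).integers(
            0, 256, size=(32, 32, 3), dtype=np.uint8
        )
        maps = first_layer_activations(model, tile)
        assert (maps[0].grid == 0).all()

    def test_center_surround_kernel_peaks_at_dark_disc(self):
        """A hand-set center-surround kernel responds maximally at a
        planted dark disc, matching the brute-force convolution."""
        from skimage.draw import disk

        model = _model()
        conv = model.first_conv
        kernel = -np.ones((5, 5)) / 16.0
        kernel[1:4, 1:4] = 1.0 / 9.0 + 1.0 / 16.0
        conv.W[:] = 0.0
        conv.b[:] = 0.0
        for c in range(3):
            conv.W[..., c, 0] = kernel / 3.0

        tile = np.full((32, 32, 3), 255, dtype=np.uint8)
        rr, cc = disk((20, 11), 2.5)
        tile[rr, cc] = 20
        amap = first_layer_activations(model, tile)[0]
        oracle = brute_force_first_layer(model, tile)[0]
        np.testing.assert_allclose(amap.grid, oracle, atol=1e-5)
        peak = np.unravel_index(amap.grid.argmax(), amap.grid.shape)
        # valid convolution trims 2 px on each side; disc rasterization
        # can shift the extremum by a pixel
        assert abs(peak[0] - 18) <= 1 and abs(peak[1] - 9) <= 1

    def test_identical_tiles_identical_maps(self):
        model = _model()
        tile = np.random.default_rng(2).integers(
            0, 256, size=(32, 32, 3), dtype=np.uint8
        )
        m1 = first_layer_activations(model, tile)
        m2 = first_layer_activations(model, tile)
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.grid, b.grid)


class TestThreshold:
    def test_constant_map_empty_and_flagged(self):
        mask, degenerate = threshold_activation(
            ActivationMap(0, np.full((10, 10), 3.0)), (40, 40)
        )
        assert degenerate and not mask.any()
        assert mask.shape == (40, 40)

    def test_top_decile_keeps_ten_percent(self):
        rng = np.random.default_rng(3)
        grid = rng.permutation(100).reshape(10, 10).astype(float)
        mask, degenerate = threshold_activation(
            ActivationMap(0, grid), (10, 10)
        )
        assert not degenerate
        assert mask.sum() == 10

    def test_upsampled_to_tile_resolution(self):
        rng = np.random.default_rng(4)
        grid = rng.random((52, 52))
        mask, _ = threshold_activation(ActivationMap(0, grid), (224, 224))
        assert mask.shape == (224, 224)

    def test_otsu_alternative(self):
        grid = np.r_[np.zeros(50), np.ones(50)].reshape(10, 10)
        mask, _ = threshold_activation(
            ActivationMap(0, grid), (10, 10), method="otsu"
        )
        assert mask.sum() == 50

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            threshold_activation(
                ActivationMap(0, np.array([[np.nan, 1.0]])), (2, 2)
            )


class TestPearson:
    def test_identical_masks_r_one(self):
        rng = np.random.default_rng(5)
        mask = rng.random((20, 20)) > 0.5
        assert _pearson(mask, mask) == pytest.approx(1.0)

    def test_complement_r_minus_one(self):
        rng = np.random.default_rng(6)
        mask = rng.random((20, 20)) > 0.5
        assert _pearson(mask, ~mask) == pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = rng.random((15, 15)) > 0.4
        b = rng.random((15, 15)) > 0.6
        assert _pearson(a, b) == pytest.approx(_pearson(b, a))

    def test_degenerate_mask_nan(self):
        a = np.zeros((5, 5), bool)
        b = np.ones((5, 5), bool)
        assert np.isnan(_pearson(a, b))


class TestColocalization:
    def test_profile_invariant_to_tile_order(self, planted_tile):
        tile, _, lymph, nuclei = planted_tile
        rng = np.random.default_rng(8)
        tile2 = tile.copy()
        tile2[:50] = 255  # slightly different second tile
        tiles = np.stack([tile, tile2])
        lymphs = [lymph, lymph]
        nucleis = [nuclei, nuclei]
        model = _model(input_hw=(224, 224), downscale=2)
        p1 = colocalization_profile(model, tiles, lymphs, nucleis)
        p2 = colocalization_profile(model, tiles[::-1], lymphs, nucleis)
        f1 = {p.filter_index: p.preferential_fraction for p in p1}
        f2 = {p.filter_index: p.preferential_fraction for p in p2}
        assert f1 == f2

    def test_misaligned_masks_rejected(self, planted_tile):
        tile, _, lymph, nuclei = planted_tile
        model = _model(input_hw=(224, 224), downscale=2)
        with pytest.raises(ValueError):
            colocalization_profile(model, np.stack([tile]), [lymph], [])


@pytest.fixture(scope="module")
def model_and_tiles():
    rng = np.random.default_rng(9)
    model = _model()
    tiles = rng.integers(0, 256, size=(12, 32, 32, 3), dtype=np.uint8)
    labels = rng.integers(0, 2, size=12)
    patients = np.repeat([f"p{i}" for i in range(6)], 2)
    return model, tiles, labels, patients


class TestAblation:
    def test_ablating_zero_filter_changes_nothing(self, model_and_tiles):
        model, tiles, labels, patients = model_and_tiles
        conv = model.first_conv
        conv.W[..., 3] = 0.0
        conv.b[3] = 0.0
        before_probs = model.predict_proba(tiles)
        ablated, before, after = ablate_filter_and_eval(
            model, 3, tiles, labels, patients
        )
        np.testing.assert_array_equal(
            before_probs, ablated.predict_proba(tiles)
        )
        assert before == after

    def test_ablating_all_filters_matches_zero_feature_response(
        self, model_and_tiles
    ):
        model, tiles, _, _ = model_and_tiles
        ablated = model
        for f in range(model.first_conv.W.shape[-1]):
            ablated = ablate_filter(ablated, f)
        probs = ablated.predict_proba(tiles)
        # every tile collapses to the same zero-feature-map response
        assert np.allclose(probs, probs[0:1], atol=1e-6)

    def test_invalid_index_rejected(self, model_and_tiles):
        model = model_and_tiles[0]
        with pytest.raises(IndexError):
            ablate_filter(model, 99)

    def test_other_weights_untouched(self, model_and_tiles):
        model = model_and_tiles[0]
        ablated = ablate_filter(model, 0)
        np.testing.assert_array_equal(
            model.first_conv.W[..., 1:], ablated.first_conv.W[..., 1:]
        )
        assert (ablated.first_conv.W[..., 0] == 0).all()
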