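"""Thresholding preprocessing: grayscale, annotation removal, mask extraction."""

import dataclasses

import numpy as np
import pytest

from thromboseg import (
    SceneConfig,
    ThresholdConfig,
    extract_clot_mask,
    extract_dot_mask,
    generate_scene,
    make_training_pair,
    remove_text_annotations,
    resize_mask,
    to_grayscale,
)
from thromboseg.preprocess import GRAY_WEIGHTS, ClotExtractionError


class TestToGrayscale:
    @pytest.mark.parametrize("v", [0, 17, 128, 255])
    def test_equal_channels_are_a_fixed_point(self, v):
        img = np.full((4, 5, 3), v, dtype=np.uint8)
        np.testing.assert_array_equal(to_grayscale(img), np.full((4, 5), v, np.uint8))

    def test_matches_per_pixel_dot_product_oracle(self, rng):
        img = rng.integers(0, 256, size=(6, 7, 3), dtype=np.uint8)
        got = to_grayscale(img)
        for i in range(6):
            for j in range(7):
                expected = round(sum(float(img[i, j, c]) * GRAY_WEIGHTS[c] for c in range(3)))
                assert got[i, j] == min(255, max(0, expected))

    def test_pure_red_uses_documented_red_weight(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = 255
        assert (to_grayscale(img) == round(GRAY_WEIGHTS[0] * 255)).all()

    def test_gray_input_passes_through(self, rng):
        img = rng.integers(0, 256, size=(5, 5), dtype=np.uint8)
        np.testing.assert_array_equal(to_grayscale(img), img)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 2), dtype=np.uint8))


class TestAnnotationRemoval:
    def test_zero_band_is_identity(self, rng):
        img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        cfg = ThresholdConfig(annotation_band_px=0)
        np.testing.assert_array_equal(remove_text_annotations(img, cfg), img)

    def test_interior_untouched_and_band_filled_with_mode(self, noise_free_config):
        cfg_ann = dataclasses.replace(noise_free_config, annotation_enabled=True)
        scene = generate_scene(cfg_ann, seed=8)
        tcfg = ThresholdConfig(annotation_band_px=12)
        out = remove_text_annotations(scene.image, tcfg)
        b = tcfg.annotation_band_px
        np.testing.assert_array_equal(out[b:-b, b:-b], scene.image[b:-b, b:-b])
        assert (out[:b] == noise_free_config.background_level).all()
        assert not (out == cfg_ann.annotation_level).any()

    def test_matches_annotation_free_render(self, noise_free_config):
        """Removing annotations reproduces the same scene rendered without them."""
        cfg_on = dataclasses.replace(noise_free_config, annotation_enabled=True)
        on = generate_scene(cfg_on, seed=8)
        off = generate_scene(noise_free_config, seed=8)
        tcfg = ThresholdConfig(annotation_band_px=12)
        np.testing.assert_array_equal(
            remove_text_annotations(on.image, tcfg), remove_text_annotations(off.image, tcfg)
        )

    def test_band_too_wide_rejected(self):
        with pytest.raises(ValueError):
            remove_text_annotations(np.zeros((10, 10), np.uint8),
                                    ThresholdConfig(annotation_band_px=5))


class TestDotMask:
    def test_noise_free_extraction_equals_ground_truth(self, noise_free_config):
        for seed in range(5):
            scene = generate_scene(noise_free_config, seed=seed)
            got = extract_dot_mask(scene.image, ThresholdConfig())
            np.testing.assert_array_equal(got, scene.dot_mask)

    def test_distractor_passes_through_to_dot_mask(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, distractor_enabled=True)
        scene = generate_scene(cfg, seed=3)
        got = extract_dot_mask(scene.image, ThresholdConfig())
        expected = scene.dot_mask | scene.distractor_mask
        np.testing.assert_array_equal(got, expected)

    def test_uniform_background_gives_empty_mask(self):
        img = np.full((32, 32), 200, np.uint8)
        assert extract_dot_mask(img, ThresholdConfig()).sum() == 0

    def test_threshold_255_selects_everything(self):
        img = np.full((8, 8), 123, np.uint8)
        cfg = ThresholdConfig(marker_threshold=255, clot_low=255, clot_high=255,
                              annotation_band_px=0)
        assert extract_dot_mask(img, cfg).all()

    @pytest.mark.parametrize("pair", [(30, 50), (50, 70), (10, 200)])
    def test_threshold_monotonicity(self, noise_free_config, pair):
        """Raising the threshold never removes pixels from the dot mask."""
        scene = generate_scene(noise_free_config, seed=1)
        lo, hi = pair
        low = extract_dot_mask(scene.image, ThresholdConfig(marker_threshold=lo,
                                                            clot_low=201, clot_high=255))
        high = extract_dot_mask(scene.image, ThresholdConfig(marker_threshold=hi,
                                                             clot_low=201, clot_high=255))
        assert (high >= low).all()


class TestNormalizeDotMask:
    def test_noise_free_masks_are_a_fixed_point(self, noise_free_config):
        from thromboseg import normalize_dot_mask

        scene = generate_scene(noise_free_config, seed=4)
        np.testing.assert_array_equal(normalize_dot_mask(scene.dot_mask), scene.dot_mask)

    @pytest.mark.parametrize("seed", range(6))
    def test_training_and_test_style_inputs_become_identical(self, seed):
        """Radiopaque rendering must not leak into the network input.

        Blur mixes marker intensity with its surroundings, so raw thresholded
        disks are slightly fatter on top of an opacified clot; normalization
        removes that halo, making paired renders indistinguishable.
        """
        from thromboseg import normalize_dot_mask

        cfg_train = SceneConfig(radiopaque_clot=True)
        cfg_test = SceneConfig(radiopaque_clot=False)
        tcfg = ThresholdConfig()
        a = generate_scene(cfg_train, seed=seed)
        b = generate_scene(cfg_test, seed=seed)
        na = normalize_dot_mask(extract_dot_mask(a.image, tcfg))
        nb = normalize_dot_mask(extract_dot_mask(b.image, tcfg))
        np.testing.assert_array_equal(na, nb)

    def test_component_count_and_size_classes_preserved(self, noise_free_config):
        import dataclasses as dc

        from scipy import ndimage

        from thromboseg import normalize_dot_mask
        from thromboseg.simulate import _FOUR_CONN

        cfg = dc.replace(noise_free_config, distractor_enabled=True)
        scene = generate_scene(cfg, seed=2)
        norm = normalize_dot_mask(extract_dot_mask(scene.image, ThresholdConfig()))
        labels, n = ndimage.label(norm, structure=_FOUR_CONN)
        assert n == 16  # 15 markers + distractor
        sizes = sorted(ndimage.sum_labels(norm, labels, index=np.arange(1, n + 1)))
        assert sizes[-1] > 2 * sizes[0]  # distractor stays recognizably larger


class TestClotMask:
    def test_noise_free_extraction_is_ground_truth_minus_markers(self, noise_free_config):
        """Extraction equals the marker-occluded clot, after the largest-CC rule.

        The oracle is computed from the ground-truth masks alone: the visible
        clot is clot minus markers; a stray pixel 4-disconnected by marker
        disks is dropped by the documented largest-component rule.
        """
        from scipy import ndimage

        from thromboseg.simulate import _FOUR_CONN

        for seed in range(5):
            scene = generate_scene(noise_free_config, seed=seed)
            got = extract_clot_mask(scene.image, ThresholdConfig())
            visible = scene.clot_mask & (1 - scene.dot_mask)
            labels, n = ndimage.label(visible, structure=_FOUR_CONN)
            sizes = [(labels == k).sum() for k in range(1, n + 1)]
            expected = (labels == (int(np.argmax(sizes)) + 1)).astype(np.uint8)
            np.testing.assert_array_equal(got, expected)

    def test_radiolucent_scene_raises(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, radiopaque_clot=False)
        scene = generate_scene(cfg, seed=2)
        with pytest.raises(ClotExtractionError):
            extract_clot_mask(scene.image, ThresholdConfig())

    def test_largest_component_retained(self):
        img = np.full((32, 32), 200, np.uint8)
        img[5:7, 5:7] = 110  # 4 pixels
        img[20:26, 20:26] = 110  # 36 pixels
        got = extract_clot_mask(img, ThresholdConfig(annotation_band_px=0))
        assert got.sum() == 36
        assert got[22, 22] == 1 and got[5, 5] == 0


class TestResizeAndPairs:
    def test_native_size_is_identity(self, rng):
        mask = (rng.random((128, 128)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(resize_mask(mask, 128), mask)

    def test_all_ones_survive_down_and_upscale(self):
        ones = np.ones((908, 908), np.uint8)
        down = resize_mask(ones, 128)
        assert down.all()
        assert resize_mask(down, 908).all()

    def test_downscale_preserves_disk_centroid(self):
        mask = np.zeros((640, 640), np.uint8)
        rr, cc = np.mgrid[:640, :640]
        mask[(rr - 320) ** 2 + (cc - 400) ** 2 <= 60**2] = 1
        small = resize_mask(mask, 128)
        r, c = np.argwhere(small).mean(axis=0)
        assert abs(r - 320 / 5) <= 1.0
        assert abs(c - 400 / 5) <= 1.0

    def test_outputs_strictly_binary(self, noise_free_config):
        scene = generate_scene(dataclasses.replace(noise_free_config, noise_sd=2.0,
                                                   blur_sigma_px=0.5), seed=0)
        cfg = ThresholdConfig(target_size=64)
        pair = make_training_pair(scene, cfg)
        for arr in (pair.dot_mask, pair.clot_mask):
            assert arr.shape == (64, 64)
            assert set(np.unique(arr)) <= {0, 1}

    def test_training_pair_from_radiopaque_render(self, noise_free_config):
        from thromboseg.preprocess import fill_marker_holes

        scene = generate_scene(noise_free_config, seed=5)
        pair = make_training_pair(scene, ThresholdConfig(target_size=128), source_id="s5")
        visible = scene.clot_mask & (1 - scene.dot_mask)
        np.testing.assert_array_equal(pair.clot_mask, fill_marker_holes(visible))
        np.testing.assert_array_equal(pair.dot_mask, scene.dot_mask)
        assert pair.source_id == "s5"
        raw = make_training_pair(scene, ThresholdConfig(target_size=128), fill_holes=False)
        np.testing.assert_array_equal(raw.clot_mask, visible)

    def test_training_pair_falls_back_to_stored_mask(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, radiopaque_clot=False)
        scene = generate_scene(cfg, seed=5)
        pair = make_training_pair(scene, ThresholdConfig(target_size=128))
        np.testing.assert_array_equal(pair.clot_mask, scene.clot_mask)

    def test_invalid_threshold_config_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(marker_threshold=100, clot_low=90).validate()
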