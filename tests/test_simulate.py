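"""Scene generator: geometry, determinism, renderer/mask consistency."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from thromboseg import GenerationError, SceneConfig, generate_dataset, generate_scene
from thromboseg.simulate import _FOUR_CONN, derive_seed, simulate_scenes


def n_components(mask):
    return ndimage.label(mask, structure=_FOUR_CONN)[1]


class TestSceneGeometry:
    def test_dot_mask_has_one_component_per_marker(self, noise_free_config):
        scene = generate_scene(noise_free_config, seed=5)
        assert n_components(scene.dot_mask) == 15  # 5 clusters x 3 markers

    @pytest.mark.parametrize("seed", range(8))
    def test_clot_mask_is_one_4connected_component(self, noise_free_config, seed):
        scene = generate_scene(noise_free_config, seed=seed)
        assert n_components(scene.clot_mask) == 1

    def test_zero_deformation_leaves_markers_at_rest(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, deformation_gain=0.0)
        scene = generate_scene(cfg, seed=2)
        np.testing.assert_array_equal(
            scene.meta.geometry.marker_coords, scene.meta.geometry.undeformed_coords
        )

    def test_markers_outside_clot_span_are_undeformed(self, noise_free_config):
        scene = generate_scene(noise_free_config, seed=7)
        geo = scene.meta.geometry
        outside = (geo.undeformed_coords[:, 1] < scene.meta.clot_x_start) | (
            geo.undeformed_coords[:, 1] > scene.meta.clot_x_end
        )
        assert outside.any()
        np.testing.assert_array_equal(
            geo.marker_coords[outside], geo.undeformed_coords[outside]
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_displacement_monotone_in_clot_thickness(self, noise_free_config, seed):
        """Thicker clots indent the markers at least as much, everywhere."""
        prev = None
        for frac in (0.3, 0.5, 0.7, 0.9):
            cfg = dataclasses.replace(noise_free_config, clot_thickness_range=(frac, frac))
            geo = generate_scene(cfg, seed=seed).meta.geometry
            disp = np.abs(geo.marker_coords[:, 0] - geo.undeformed_coords[:, 0])
            if prev is not None:
                assert (disp >= prev - 1e-9).all()
            prev = disp

    def test_markers_stay_inside_lumen(self, noise_free_config):
        for seed in range(10):
            scene = generate_scene(noise_free_config, seed=seed)
            geo = scene.meta.geometry
            cols = geo.marker_coords[:, 1]
            cl = np.interp(cols, geo.centerline[:, 1], geo.centerline[:, 0])
            r = noise_free_config.vessel_diameter_px / 2
            off = np.abs(geo.marker_coords[:, 0] - cl)
            assert (off + noise_free_config.marker_radius_px <= r + 1e-6).all()

    def test_infeasible_marker_radius_raises(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, marker_radius_px=5.0)
        with pytest.raises(GenerationError, match="lumen"):
            generate_scene(cfg, seed=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_clusters": 1},
            {"markers_per_cluster": 0},
            {"clot_length_range": (0.0, 0.5)},
            {"clot_thickness_range": (0.5, 1.5)},
            {"image_size": 16},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SceneConfig(**kwargs).validate()


class TestRendering:
    def test_deterministic_for_fixed_config_and_seed(self):
        cfg = SceneConfig()
        a = generate_scene(cfg, seed=11)
        b = generate_scene(cfg, seed=11)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.clot_mask, b.clot_mask)
        np.testing.assert_array_equal(a.dot_mask, b.dot_mask)
        c = generate_scene(cfg, seed=12)
        assert not np.array_equal(a.image, c.image)

    def test_marker_intensity_pixels_equal_dot_mask(self, noise_free_config):
        """Renderer/mask consistency: noise-free marker pixels are the dot mask."""
        for seed in range(5):
            scene = generate_scene(noise_free_config, seed=seed)
            at_marker = scene.image == noise_free_config.marker_level
            np.testing.assert_array_equal(at_marker.astype(np.uint8), scene.dot_mask)

    def test_darker_than_background_outside_dots_equals_clot(self, noise_free_config):
        scene = generate_scene(noise_free_config, seed=9)
        dark = (scene.image < noise_free_config.background_level) & (scene.dot_mask == 0)
        visible_clot = scene.clot_mask & (1 - scene.dot_mask)  # markers occlude the clot
        np.testing.assert_array_equal(dark.astype(np.uint8), visible_clot)

    def test_radiolucent_clot_is_invisible(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, radiopaque_clot=False)
        scene = generate_scene(cfg, seed=9)
        visible = (scene.clot_mask == 1) & (scene.dot_mask == 0)  # markers overlap the clot
        assert (scene.image[visible] == cfg.background_level).all()
        assert scene.clot_mask.sum() > 0  # ground truth still recorded

    def test_distractor_rendered_but_not_in_dot_mask(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, distractor_enabled=True)
        scene = generate_scene(cfg, seed=3)
        dmask = scene.distractor_mask
        assert dmask.sum() > 0
        assert (scene.image[dmask == 1] == cfg.marker_level).all()
        assert (scene.dot_mask[dmask == 1] == 0).all()
        assert dmask.sum() > np.pi * cfg.marker_radius_px**2  # larger than a marker

    def test_distractor_toggle_changes_nothing_else(self, noise_free_config):
        cfg_on = dataclasses.replace(noise_free_config, distractor_enabled=True)
        on = generate_scene(cfg_on, seed=4)
        off = generate_scene(noise_free_config, seed=4)
        dmask = on.distractor_mask.astype(bool)
        np.testing.assert_array_equal(on.image[~dmask], off.image[~dmask])
        np.testing.assert_array_equal(on.clot_mask, off.clot_mask)
        np.testing.assert_array_equal(on.dot_mask, off.dot_mask)

    def test_annotations_confined_to_border_band(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, annotation_enabled=True)
        scene = generate_scene(cfg, seed=6)
        band = cfg.annotation_band_px
        glyphs = scene.image == cfg.annotation_level
        assert glyphs.sum() > 0
        interior = glyphs[band:-band, band:-band]
        assert not interior.any()


class TestDatasetGeneration:
    def test_manifest_and_files(self, noise_free_config, tmp_path):
        scenes, manifest = generate_dataset(noise_free_config, 3, seed=1, out_dir=tmp_path)
        assert len(scenes) == 3
        assert len(manifest) == 3
        for row in manifest.itertuples():
            for col in ("image_path", "clot_mask_path", "dot_mask_path"):
                assert (tmp_path / getattr(row, col)).is_file()

    def test_same_master_seed_gives_identical_manifests(self, noise_free_config, tmp_path):
        _, m1 = generate_dataset(noise_free_config, 3, seed=9, out_dir=tmp_path / "a")
        _, m2 = generate_dataset(noise_free_config, 3, seed=9, out_dir=tmp_path / "b")
        assert m1.equals(m2)
        img1 = (tmp_path / "a" / "scene_0000.png").read_bytes()
        img2 = (tmp_path / "b" / "scene_0000.png").read_bytes()
        assert img1 == img2

    def test_n_zero_rejected(self, noise_free_config, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(noise_free_config, 0, seed=1, out_dir=tmp_path)

    def test_round_trip_through_disk_is_lossless(self, noise_free_config, tmp_path):
        from thromboseg import io as tio

        scenes, manifest = generate_dataset(noise_free_config, 1, seed=4, out_dir=tmp_path)
        row = manifest.iloc[0]
        np.testing.assert_array_equal(
            tio.read_image_png(tmp_path / row.image_path), scenes[0].image
        )
        np.testing.assert_array_equal(
            tio.read_mask_png(tmp_path / row.clot_mask_path), scenes[0].clot_mask
        )

    def test_derived_seeds_are_stable_and_31bit(self):
        seeds = [derive_seed(42, i) for i in range(100)]
        assert seeds == [derive_seed(42, i) for i in range(100)]
        assert all(0 <= s < 2**31 for s in seeds)
        assert len(set(seeds)) == len(seeds)

    def test_scene_seeds_are_order_independent(self, noise_free_config):
        few = simulate_scenes(noise_free_config, 2, seed=7)
        many = simulate_scenes(noise_free_config, 5, seed=7)
        np.testing.assert_array_equal(few[1].image, many[1].image)
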