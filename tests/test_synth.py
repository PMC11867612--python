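import numpy as np
import pandas as pd
import pytest

from boutonmap import synth
from boutonmap.atlas import Transform2D, fit_transform
from boutonmap.quantify import VoxelGrid

VOXEL2D = (0.3611, 0.3611)


class TestGenerateRegionMap:
    def test_single_full_frame_region(self):
        rm = synth.generate_region_map(
            [(1, (0.0, 0.0, 64 * 0.3611, 64 * 0.3611))], (64, 64), VOXEL2D
        )
        assert (rm.label_image == 1).all()
        assert rm.id_to_area_um2[1] == pytest.approx(64 * 64 * 0.3611**2)

    def test_two_disjoint_rectangles_area_ratio(self):
        rm = synth.generate_region_map(
            [(1, (0.0, 0.0, 100.0, 100.0)), (2, (110.0, 0.0, 50.0, 50.0))],
            (512, 512),
            VOXEL2D,
        )
        # areas come straight from labeled-pixel counts
        px_area = 0.3611**2
        n1 = int((rm.label_image == 1).sum())
        n2 = int((rm.label_image == 2).sum())
        assert rm.id_to_area_um2[1] == pytest.approx(n1 * px_area)
        assert rm.id_to_area_um2[2] == pytest.approx(n2 * px_area)
        assert rm.id_to_area_um2[1] / rm.id_to_area_um2[2] == pytest.approx(4.0, rel=0.02)

    def test_empty_layout_all_background(self):
        rm = synth.generate_region_map([], (32, 32), VOXEL2D)
        assert (rm.label_image == 0).all()
        assert rm.region_ids == []

    def test_overlapping_rectangles_error_names_both_ids(self):
        with pytest.raises(ValueError, match="3 and 7"):
            synth.generate_region_map(
                [(3, (0.0, 0.0, 50.0, 50.0)), (7, (40.0, 40.0, 50.0, 50.0))],
                (512, 512),
                VOXEL2D,
            )

    def test_nonpositive_region_id_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            synth.generate_region_map([(0, (0, 0, 10, 10))], (64, 64), VOXEL2D)


class TestRenderScene:
    def test_zero_densities_yield_empty_truth_and_flat_channels(self):
        cfg = synth.default_scene_config(seed=3)
        cfg.shape_voxels = (128, 128, 5)
        w, h, _ = cfg.extent_um()
        cfg.region_layout = [(1, (0.0, 0.0, w, h))]
        cfg.vgat_density_per_region = {1: 0.0}
        cfg.pc_fraction_per_region = {1: 0.0}
        cfg.axon_clutter_density = 0.0
        stack, truth = synth.render_scene(cfg)
        assert len(truth.boutons) == 0
        for ci in range(2):
            mean = stack.voxels[ci].mean()
            assert mean == pytest.approx(cfg.illumination_amplitude, rel=0.05)

    def test_poisson_expected_count(self):
        # one region of area A = 10,000 µm² at density 0.01/µm² -> E[n] = 100
        side = 100.0
        nxy = int(np.ceil(side / 0.3611))
        counts = []
        for seed in range(20):
            cfg = synth.SceneConfig(shape_voxels=(nxy, nxy, 3), seed=seed)
            cfg.region_layout = [(1, (0.0, 0.0, side, side))]
            cfg.vgat_density_per_region = {1: 0.01}
            cfg.pc_fraction_per_region = {1: 0.5}
            cfg.illumination_amplitude = 0.0
            cfg.axon_clutter_density = 0.0
            _, truth = synth.render_scene(cfg)
            counts.append(len(truth.boutons))
        assert abs(np.mean(counts) - 100.0) < 3 * np.sqrt(100.0) / np.sqrt(20)

    def test_pc_fraction_binomial(self):
        cfg = synth.default_scene_config(seed=11)
        w, h, _ = cfg.extent_um()
        cfg.region_layout = [(1, (0.0, 0.0, w, h))]
        cfg.vgat_density_per_region = {1: 0.02}
        cfg.pc_fraction_per_region = {1: 0.5}
        _, truth = synth.render_scene(cfg)
        n = len(truth.boutons)
        assert n >= 200
        frac = truth.boutons["is_pc"].mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_reproducibility_bit_identical(self):
        cfg1 = synth.default_scene_config(seed=5)
        cfg2 = synth.default_scene_config(seed=5)
        s1, t1 = synth.render_scene(cfg1)
        s2, t2 = synth.render_scene(cfg2)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)
        pd.testing.assert_frame_equal(t1.boutons, t2.boutons)

    def test_count_conservation(self, default_scene):
        _, _, truth, _ = default_scene
        assert truth.per_region_counts["n_vgat"].sum() == len(truth.boutons)
        assert (truth.per_region_counts["n_pc"] <= truth.per_region_counts["n_vgat"]).all()

    def test_centroids_inside_bounds(self, default_scene):
        cfg, _, truth, _ = default_scene
        w, h, d = cfg.extent_um()
        b = truth.boutons
        assert ((b["x_um"] >= 0) & (b["x_um"] <= w)).all()
        assert ((b["y_um"] >= 0) & (b["y_um"] <= h)).all()
        assert ((b["z_um"] >= 0) & (b["z_um"] <= d)).all()

    def test_tdt_mode_separation(self, default_scene):
        # PC vs non-PC true reporter amplitudes overlap < 2%
        _, _, truth, _ = default_scene
        pc = truth.boutons.loc[truth.boutons["is_pc"], "tdt_amp"]
        non = truth.boutons.loc[~truth.boutons["is_pc"], "tdt_amp"]
        cut = np.sqrt(10.0 * 100.0)  # geometric midpoint of the mode medians
        overlap = (pc <= cut).sum() + (non > cut).sum()
        assert overlap / len(truth.boutons) < 0.02

    def test_desk_scale_guard(self):
        cfg = synth.default_scene_config(seed=0)
        cfg.vgat_density_per_region = {1: 1e5, 2: 1e5, 3: 1e5}
        with pytest.raises(ValueError, match="desk-scale"):
            synth.render_scene(cfg)

    def test_invalid_fraction_rejected(self):
        cfg = synth.default_scene_config(seed=0)
        cfg.pc_fraction_per_region[1] = 1.5
        with pytest.raises(ValueError, match="pc fraction"):
            cfg.validate()

    def test_mode_ordering_enforced(self):
        cfg = synth.default_scene_config(seed=0)
        cfg.tdt_signal_dist = (np.log(5.0), 0.25)  # below the noise mode
        with pytest.raises(ValueError, match="signal mode"):
            cfg.validate()


class TestGenerateEphysCells:
    @staticmethod
    def _flat_grid(value=0.0, shape=(4, 4, 1)):
        counts = np.full(shape, value * 144.0 * 144.0)
        return VoxelGrid((0.0, 0.0, 0.0), (144.0, 144.0, 4.0), counts)

    def test_symmetric_link_gives_half_responding(self):
        params = synth.EphysLinkParams(beta0=0.0, beta1=0.0, n_cells=2000, seed=4)
        cells = synth.generate_ephys_cells(self._flat_grid(), params)
        se = np.sqrt(0.25 / 2000)
        assert abs(cells["responded"].mean() - 0.5) < 3 * se

    def test_positive_slope_monotone_across_terciles(self):
        rng = np.random.default_rng(9)
        counts = rng.uniform(0, 0.03, size=(6, 6, 1)) * 144.0**2
        grid = VoxelGrid((0.0, 0.0, 0.0), (144.0, 144.0, 4.0), counts)
        params = synth.EphysLinkParams(beta0=-2.0, beta1=300.0, n_cells=2000, seed=4)
        cells = synth.generate_ephys_cells(grid, params)
        from boutonmap.ephys import local_density

        dens = local_density(cells, grid)
        edges = np.quantile(dens, [0, 1 / 3, 2 / 3, 1.0])
        edges[-1] += 1e-9
        which = np.digitize(dens, edges) - 1
        fracs = [cells["responded"][which == t].mean() for t in range(3)]
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_nonresponders_have_zero_amplitude(self):
        params = synth.EphysLinkParams(beta0=0.0, beta1=0.0, n_cells=500, seed=0)
        cells = synth.generate_ephys_cells(self._flat_grid(), params)
        non = cells[~cells["responded"]]
        assert (non["amplitude_pa"] == 0.0).all()
        resp = cells[cells["responded"]]
        assert (resp["amplitude_pa"] > 0.0).all()

    def test_negative_density_rejected(self):
        grid = VoxelGrid((0, 0, 0), (144, 144, 4), -np.ones((2, 2, 1)))
        with pytest.raises(ValueError, match="non-negative"):
            synth.generate_ephys_cells(grid, synth.EphysLinkParams())


class TestPerturbLandmarks:
    def test_zero_noise_round_trip(self):
        theta = np.deg2rad(12.0)
        true = Transform2D(
            1.1 * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]),
            [40.0, -25.0],
        )
        fixed, moving = synth.perturb_landmarks(true, n_pairs=20, noise_sd_um=0.0, seed=2)
        fit = fit_transform(fixed, moving, model="similarity")
        assert fit.residual_rms_um < 1e-6
        np.testing.assert_allclose(fit.matrix, true.matrix, atol=1e-8)
        np.testing.assert_allclose(fit.translation, true.translation, atol=1e-6)

    def test_noisy_residual_rms_range(self):
        true = Transform2D(np.eye(2), [100.0, 50.0])
        rms = []
        for seed in range(20):
            fixed, moving = synth.perturb_landmarks(true, 60, noise_sd_um=5.0, seed=seed)
            fit = fit_transform(fixed, moving, model="similarity")
            rms.append(fit.residual_rms_um)
        assert all(2.5 <= r <= 7.5 for r in rms)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            synth.perturb_landmarks(Transform2D.identity(), 2, 0.0)
        # and an affine fit downstream with only 2 pairs must also fail
        with pytest.raises(ValueError, match="affine"):
            fit_transform(np.zeros((2, 2)), np.zeros((2, 2)), model="affine")
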