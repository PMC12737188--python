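import dataclasses

import numpy as np
import pytest

from holoquant.errors import ConfigError
from holoquant.synthetic import (
    SceneConfig,
    generate_scene,
    induce_uptake_association,
    lognormal_moments,
    lognormal_params_from_moments,
)
from holoquant.volume_io import VoxelSpacing

from conftest import tiny_scene_config


class TestLognormalHelpers:
    def test_moments_from_default_params(self):
        # independent closed form: mean = exp(mu + s^2/2), SD = mean*sqrt(e^{s^2}-1)
        mean, sd = lognormal_moments(-0.90, 0.78)
        assert mean == pytest.approx(0.5509, abs=2e-3)
        assert sd == pytest.approx(0.5042, abs=2e-3)

    def test_params_from_moments_round_trip(self):
        mu, sigma = lognormal_params_from_moments(0.55, 0.50)
        assert mu == pytest.approx(-0.8990, abs=1e-3)
        assert sigma == pytest.approx(0.7761, abs=1e-3)
        mean, sd = lognormal_moments(mu, sigma)
        assert (mean, sd) == (pytest.approx(0.55), pytest.approx(0.50))

    def test_sampled_moments_match(self, rng):
        draws = rng.lognormal(-0.90, 0.78, size=10_000)
        assert draws.mean() == pytest.approx(0.551, rel=0.05)
        assert draws.std() == pytest.approx(0.504, rel=0.10)


class TestSceneDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = tiny_scene_config(noise_sd_ri=0.002, droplets_per_cell=1.0)
        t1, f1, g1 = generate_scene(cfg)
        t2, f2, g2 = generate_scene(cfg)
        np.testing.assert_array_equal(t1.grid, t2.grid)
        np.testing.assert_array_equal(f1.grid, f2.grid)
        np.testing.assert_array_equal(g1.cell_labels, g2.cell_labels)
        np.testing.assert_array_equal(g1.aggregate_labels, g2.aggregate_labels)
        assert g1.per_aggregate.equals(g2.per_aggregate)
        assert g1.per_cell.equals(g2.per_cell)

    def test_different_seeds_differ(self):
        t1, _, _ = generate_scene(tiny_scene_config(seed=1))
        t2, _, _ = generate_scene(tiny_scene_config(seed=2))
        assert not np.array_equal(t1.grid, t2.grid)


class TestEmptyScene:
    def test_zero_cells_uniform_background(self):
        cfg = tiny_scene_config(n_cells=0, noise_sd_ri=0.0)
        tomo, fluor, truth = generate_scene(cfg)
        assert np.all(tomo.grid == cfg.ri_background)
        assert not fluor.grid.any()
        assert truth.per_aggregate.empty
        assert truth.per_cell.empty
        assert not truth.cell_labels.any()

    def test_zero_cells_with_noise(self):
        cfg = tiny_scene_config(n_cells=0, noise_sd_ri=0.002)
        tomo, _, _ = generate_scene(cfg)
        assert tomo.grid.std() == pytest.approx(0.002, rel=0.1)


class TestSceneInvariants:
    def test_cell_volume_conservation_exact(self, tiny_scene):
        cfg, tomo, fluor, truth = tiny_scene
        vv = cfg.spacing.voxel_volume
        assert np.count_nonzero(truth.cell_labels) * vv == pytest.approx(
            truth.per_cell["true_volume_um3"].sum(), rel=1e-12
        )

    def test_aggregate_volumes_match_labels(self, tiny_scene):
        cfg, _, _, truth = tiny_scene
        vv = cfg.spacing.voxel_volume
        counts = np.bincount(truth.aggregate_labels.ravel())
        for row in truth.per_aggregate.itertuples():
            assert counts[row.id] * vv == pytest.approx(row.true_volume_um3)

    def test_aggregates_inside_exactly_one_cell(self, tiny_scene):
        _, _, _, truth = tiny_scene
        for row in truth.per_aggregate.itertuples():
            owner = truth.cell_labels[truth.aggregate_labels == row.id]
            assert (owner == row.cell_id).all()

    def test_thresholds_recover_truth_exactly_without_noise(self, tiny_scene):
        _, tomo, _, truth = tiny_scene
        np.testing.assert_array_equal(tomo.grid >= 1.34, truth.cell_labels > 0)
        np.testing.assert_array_equal(
            tomo.grid > 1.36,
            (truth.aggregate_labels > 0) | (truth.droplet_labels > 0),
        )

    def test_cytoplasm_strictly_below_high_threshold(self, tiny_scene):
        _, tomo, _, truth = tiny_scene
        cyto = (truth.cell_labels > 0) & (truth.aggregate_labels == 0)
        assert tomo.grid[cyto].max() < 1.36

    def test_fluorescence_only_on_fluorescent_aggregates(self, tiny_scene):
        _, _, fluor, truth = tiny_scene
        # sub_threshold_fluor_fraction = 0 here: support must be exactly the
        # fluorescent aggregates' voxels
        fluorescent_ids = set(
            truth.per_aggregate.loc[truth.per_aggregate["fluorescent"], "id"]
        )
        expected = np.isin(truth.aggregate_labels, sorted(fluorescent_ids))
        np.testing.assert_array_equal(fluor.grid > 0, expected)

    def test_dispersed_fluorescence_is_sub_threshold(self):
        cfg = tiny_scene_config(sub_threshold_fluor_fraction=0.08)
        tomo, fluor, truth = generate_scene(cfg)
        dispersed = (fluor.grid > 0) & (truth.aggregate_labels == 0)
        assert dispersed.any()
        assert tomo.grid[dispersed].max() < 1.36
        n_agg_fluor = int(((fluor.grid > 0) & (truth.aggregate_labels > 0)).sum())
        n_disp = int(dispersed.sum())
        assert n_disp == round(0.08 / 0.92 * n_agg_fluor)

    def test_droplets_never_fluoresce(self):
        cfg = tiny_scene_config(droplets_per_cell=3.0, seed=5)
        _, fluor, truth = generate_scene(cfg)
        assert not (fluor.grid[truth.droplet_labels > 0] > 0).any()


class TestConfigValidation:
    def test_overfull_grid_rejected(self):
        cfg = tiny_scene_config(n_cells=50)
        with pytest.raises(ConfigError, match="60%"):
            generate_scene(cfg)

    def test_bad_background(self):
        with pytest.raises(ConfigError):
            generate_scene(tiny_scene_config(ri_background=1.35))

    def test_cytoplasm_must_stay_below_high_threshold(self):
        with pytest.raises(ConfigError):
            generate_scene(tiny_scene_config(ri_cytoplasm=(1.34, 1.37)))

    def test_aggregate_ri_must_exceed_high_threshold(self):
        with pytest.raises(ConfigError):
            generate_scene(tiny_scene_config(ri_aggregate=(1.35, 1.40)))

    def test_association_out_of_range(self):
        with pytest.raises(ConfigError):
            generate_scene(tiny_scene_config(uptake_association=1.0))


class TestUptakeAssociation:
    def _simulate_r(self, target, n, seed, reps=1):
        """Count-level simulation: multipliers -> counts -> total volumes."""
        rng = np.random.default_rng(seed)
        rs = []
        for rep in range(reps):
            vols = rng.lognormal(6.0, 0.35, size=n)
            m = induce_uptake_association(vols, target, seed=rng.integers(2**31))
            counts = np.round(50.0 * m).astype(int)
            totals = np.array(
                [rng.lognormal(-0.90, 0.78, size=c).sum() for c in counts]
            )
            rs.append(np.corrcoef(vols, totals)[0, 1])
        return np.mean(rs)

    def test_zero_target_independent(self):
        rng = np.random.default_rng(0)
        n = 2000
        vols = rng.lognormal(6.0, 0.35, size=n)
        m = induce_uptake_association(vols, 0.0, seed=1)
        r = np.corrcoef(vols, m)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(n)

    def test_high_target_strong_correlation(self):
        assert self._simulate_r(0.99, 1000, seed=2) > 0.9

    def test_target_recovered_in_expectation(self):
        # 20 replicates of 500 cells; mean sample r within +-0.05 of target
        mean_r = self._simulate_r(0.35, 500, seed=3, reps=20)
        assert mean_r == pytest.approx(0.35, abs=0.05)

    def test_degenerate_volumes_warn(self):
        with pytest.warns(UserWarning, match="equal"):
            m = induce_uptake_association(np.ones(10), 0.5, seed=0)
        assert m.shape == (10,)

    def test_too_few_cells(self):
        from holoquant.errors import DataError

        with pytest.raises(DataError):
            induce_uptake_association([1.0, 2.0], 0.5, seed=0)


class TestScaledDownRecoveryLoop:
    def test_noise_free_pipeline_recovers_counts_and_volumes(self, tiny_scene):
        from holoquant.aggregates import AggregateParams, detect_aggregates
        from holoquant.segmentation import (
            SegmentationParams,
            foreground_mask,
            segment_cells,
        )

        cfg, tomo, _, truth = tiny_scene
        seg = SegmentationParams(min_cell_volume_um3=50.0)
        mask = foreground_mask(tomo, seg)
        labels, cells = segment_cells(mask, seg, cfg.spacing, tomogram=tomo)
        assert len(cells) == cfg.n_cells
        aggs = detect_aggregates(
            tomo, labels, AggregateParams(min_aggregate_voxels=1), cfg.spacing
        )
        assert len(aggs) == len(truth.per_aggregate)
        det = sorted(round(a.volume_um3, 9) for a in aggs)
        true = sorted(round(v, 9) for v in truth.per_aggregate["true_volume_um3"])
        assert det == true
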