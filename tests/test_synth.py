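import numpy as np
import pytest

from dyncore.errors import ConfigError
from dyncore.netbuild import build_tensor, modwt_scale, scale_band
from dyncore.synth import (
    SyntheticConfig,
    generate_adjacency_tensor,
    generate_community_tensor,
    generate_learning_cohort,
    generate_timeseries,
)


class TestConfig:
    def test_too_many_communities(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_regions=5, n_communities=10)

    def test_fractions_must_fit(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(core_fraction=0.7, periphery_fraction=0.5)

    def test_single_layer_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_layers=1)

    def test_probability_range(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(periphery_switch_prob=1.2)

    def test_bulk_default_is_geometric_mean(self):
        cfg = SyntheticConfig(periphery_switch_prob=0.5)
        assert cfg.effective_bulk_switch_prob == pytest.approx(np.sqrt(0.02 * 0.5))


class TestTimeseries:
    def test_determinism(self):
        cfg = SyntheticConfig(n_regions=10, n_layers=3, window_len=40, seed=9)
        ts1, gt1 = generate_timeseries(cfg)
        ts2, gt2 = generate_timeseries(cfg)
        np.testing.assert_array_equal(ts1.values, ts2.values)
        np.testing.assert_array_equal(gt1.planted_partition, gt2.planted_partition)

    def test_shapes_and_blocks(self):
        cfg = SyntheticConfig(n_regions=12, n_layers=4, window_len=50)
        ts, gt = generate_timeseries(cfg)
        assert ts.values.shape == (12, 200)
        assert ts.blocks == [(0, 50), (50, 100), (100, 150), (150, 200)]
        assert gt.planted_partition.shape == (12, 4)

    def test_core_labels_constant(self):
        cfg = SyntheticConfig(n_regions=20, n_layers=6, core_fraction=0.4,
                              periphery_fraction=0.3, seed=2)
        _, gt = generate_timeseries(cfg)
        core_labels = gt.planted_partition[gt.planted_core_nodes]
        assert np.all(core_labels == core_labels[:, [0]])

    def test_strata_disjoint_and_complete(self):
        cfg = SyntheticConfig(n_regions=20, core_fraction=0.3, periphery_fraction=0.3)
        _, gt = generate_timeseries(cfg)
        allnodes = np.concatenate([gt.planted_core_nodes, gt.planted_bulk_nodes,
                                   gt.planted_periphery_nodes])
        assert sorted(allnodes.tolist()) == list(range(20))

    def test_zero_coupling_independent_noise_level(self):
        # no shared signal: mean coherence near the estimator's bias level
        from dyncore.netbuild import band_coherence

        cfg = SyntheticConfig(n_regions=8, n_layers=2, window_len=64,
                              coupling_strength=0.0, n_communities=2,
                              core_fraction=1.0, periphery_fraction=0.0, seed=0)
        ts, _ = generate_timeseries(cfg)
        tensor = build_tensor(ts)
        off = tensor.weights[:, :, 0][~np.eye(8, dtype=bool)]
        # bias for 2 half-overlapping Hann segments is ~0.5; just require it
        # is far below the coupled-signal level
        assert off.mean() < 0.75

    def test_high_coupling_within_exceeds_between_each_layer(self):
        cfg = SyntheticConfig(n_regions=20, n_layers=3, window_len=60,
                              n_communities=2, core_fraction=1.0,
                              periphery_fraction=0.0, coupling_strength=0.9, seed=3)
        ts, gt = generate_timeseries(cfg)
        tensor = build_tensor(ts)
        for l in range(3):
            lab = gt.planted_partition[:, l]
            W = tensor.weights[:, :, l]
            same = lab[:, None] == lab[None, :]
            np.fill_diagonal(same, False)
            assert W[same].mean() > W[~(lab[:, None] == lab[None, :])].mean()

    def test_contrast_monotone_in_coupling(self):
        # within/between coherence gap grows with coupling strength
        gaps = []
        for c in (0.2, 0.9):
            gap = 0.0
            for seed in range(3):
                cfg = SyntheticConfig(n_regions=16, n_layers=2, window_len=60,
                                      n_communities=2, core_fraction=1.0,
                                      periphery_fraction=0.0, coupling_strength=c,
                                      seed=seed)
                ts, gt = generate_timeseries(cfg)
                tensor = build_tensor(ts)
                lab = gt.planted_partition[:, 0]
                W = tensor.weights[:, :, 0]
                same = lab[:, None] == lab[None, :]
                np.fill_diagonal(same, False)
                gap += W[same].mean() - W[~(lab[:, None] == lab[None, :])].mean()
            gaps.append(gap / 3)
        assert gaps[1] > gaps[0]

    def test_latent_band_limited(self):
        # community signal energy concentrates in the scale-2 band
        cfg = SyntheticConfig(n_regions=6, n_layers=2, window_len=256,
                              coupling_strength=1.0, n_communities=1,
                              core_fraction=1.0, periphery_fraction=0.0, seed=1)
        ts, _ = generate_timeseries(cfg)
        x = ts.values[0, :256]
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(256, d=2.0)
        lo, hi = scale_band(2, 2.0)
        inband = spec[(freqs >= lo) & (freqs <= hi)].sum()
        assert inband / spec.sum() > 0.95


class TestAdjacencyTensor:
    def test_block_mean_ordering(self):
        cfg = SyntheticConfig(n_regions=30, n_layers=2, core_fraction=0.3,
                              periphery_fraction=0.7, seed=0)
        tensor, gt = generate_adjacency_tensor(cfg, block_params=(0.9, 0.5, 0.1))
        W = tensor.weights[:, :, 0]
        core = gt.planted_core_nodes
        other = np.concatenate([gt.planted_bulk_nodes, gt.planted_periphery_nodes])
        cc = W[np.ix_(core, core)][~np.eye(len(core), dtype=bool)]
        oo = W[np.ix_(other, other)][~np.eye(len(other), dtype=bool)]
        assert cc.mean() > oo.mean()

    def test_shape_112_by_10(self):
        cfg = SyntheticConfig(n_regions=112, n_layers=10, seed=0)
        tensor, _ = generate_adjacency_tensor(cfg)
        assert tensor.weights.shape == (112, 112, 10)
        tensor.validate()

    def test_symmetric_zero_diagonal_in_range(self):
        cfg = SyntheticConfig(n_regions=20, n_layers=3, seed=4)
        tensor, _ = generate_adjacency_tensor(cfg)
        tensor.validate()

    def test_unordered_means_rejected(self):
        cfg = SyntheticConfig(n_regions=10, n_layers=2)
        with pytest.raises(ConfigError):
            generate_adjacency_tensor(cfg, block_params=(0.1, 0.5, 0.9))

    def test_means_out_of_range_rejected(self):
        cfg = SyntheticConfig(n_regions=10, n_layers=2)
        with pytest.raises(ConfigError):
            generate_adjacency_tensor(cfg, block_params=(1.2, 0.5, 0.1))

    def test_degenerate_equal_means_no_recoverable_core(self):
        # with zero contrast the annealer's "core" is arbitrary: recovery at
        # chance level over seeds
        from dyncore.geomcore import AnnealSchedule, TransitionParams, anneal_assignment

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SyntheticConfig(n_regions=20, n_layers=2, core_fraction=0.2,
                                  periphery_fraction=0.8, seed=seed)
            tensor, gt = generate_adjacency_tensor(cfg, block_params=(0.5, 0.5, 0.5))
            a = anneal_assignment(tensor.weights[:, :, 0], TransitionParams(0.5, 0.8),
                                  AnnealSchedule.fast(), n_restarts=1, seed=seed)
            top = set(a.permutation[-4:].tolist())
            hits += top == set(gt.planted_core_nodes.tolist())
        assert hits <= 2  # chance is 1/C(20,4) ~ 2e-4

    def test_determinism(self):
        cfg = SyntheticConfig(n_regions=15, n_layers=3, seed=7)
        t1, _ = generate_adjacency_tensor(cfg)
        t2, _ = generate_adjacency_tensor(cfg)
        np.testing.assert_array_equal(t1.weights, t2.weights)


class TestCommunityTensor:
    def test_within_exceeds_between(self):
        cfg = SyntheticConfig(n_regions=24, n_layers=3, n_communities=3, seed=1)
        tensor, gt = generate_community_tensor(cfg, within_mean=0.7, between_mean=0.1)
        lab = gt.planted_partition[:, 1]
        W = tensor.weights[:, :, 1]
        same = lab[:, None] == lab[None, :]
        np.fill_diagonal(same, False)
        assert W[same].mean() > 0.5 > W[~(lab[:, None] == lab[None, :])].mean()

    def test_invalid_means(self):
        cfg = SyntheticConfig(n_regions=10, n_layers=2)
        with pytest.raises(ConfigError):
            generate_community_tensor(cfg, within_mean=0.2, between_mean=0.5)


class TestLearningCohort:
    def test_noiseless_recovery(self):
        from dyncore.behavior import fit_learning_curve

        tables, _, truth = generate_learning_cohort(
            n_subjects=4, effect_size=1.0, noise_scale=0.0, outlier_rate=0.0,
            n_trials=80, seed=0)
        for table, kappa in zip(tables, truth.subject_kappa):
            fit = fit_learning_curve(table)
            assert fit.kappa == pytest.approx(kappa, abs=1e-4)

    def test_determinism(self):
        t1, c1, g1 = generate_learning_cohort(n_subjects=5, seed=3)
        t2, c2, g2 = generate_learning_cohort(n_subjects=5, seed=3)
        np.testing.assert_array_equal(g1.subject_kappa, g2.subject_kappa)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a["MT_s"].to_numpy(), b["MT_s"].to_numpy())

    def test_zero_effect_size_no_kappa_trait_link(self):
        _, _, truth = generate_learning_cohort(n_subjects=50, effect_size=0.0, seed=1)
        trait = np.array(truth.extras["trait"])
        r = np.corrcoef(trait, truth.subject_kappa)[0, 1]
        assert abs(r) < 0.5  # only jitter remains

    def test_minimum_subjects(self):
        with pytest.raises(ConfigError):
            generate_learning_cohort(n_subjects=2)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ConfigError):
            generate_learning_cohort(n_subjects=4, A=-1.0)

    def test_movement_times_positive(self):
        tables, _, _ = generate_learning_cohort(n_subjects=5, noise_scale=0.3,
                                                outlier_rate=0.2, seed=2)
        for table in tables:
            assert (table["MT_s"] > 0).all()
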