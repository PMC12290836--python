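"""Two-step permutation scheme, FDR and replication overlap."""

import itertools

import numpy as np
import pytest

from emodecode.datasets import VoxelMask
from emodecode.decoding import DecodingSpec, decode
from emodecode.errors import ConfigError, GridMismatchError
from emodecode.inference import (
    InferenceConfig,
    NullDistribution,
    ReplicationConfig,
    fdr_correct,
    group_bootstrap_p,
    permutation_label_sets,
    replication_overlap,
    roi_group_analysis,
    subject_null,
)
from emodecode.searchlight import AccuracyMap
from emodecode.simulate import SyntheticConfig, cuboid_roi, generate_cohort, generate_subject


class _IdentityRng:
    """Stand-in generator whose 'permutations' leave everything in place."""

    def permutation(self, x):
        return x

    def integers(self, *args, **kwargs):
        return 0


class TestSubjectNull:
    def test_identity_permutation_reproduces_observed(self, tiny_config, roi_mask):
        ds = generate_subject(tiny_config, 0)
        spec = DecodingSpec.within_modality("execution")
        observed = decode(ds, roi_mask, spec).mean_accuracy
        sel = spec.train.mask(ds.trials.table)
        sub = ds.trials.table[sel].reset_index(drop=True)
        y = np.where(sub["emotion"] == "fear", 1.0, -1.0)
        sets = permutation_label_sets(sub, y, len(sub), 3, _IdentityRng())
        assert np.array_equal(sets, np.tile(y, (3, 1)))
        from emodecode.decoding import build_split_caches, accuracy_from_caches
        from emodecode.decoding import extract_features, leave_one_block_out_folds
        X, _ = extract_features(ds, roi_mask, spec.train)
        caches = build_split_caches(X, leave_one_block_out_folds(ds.trials, spec.train))
        acc, _, _ = accuracy_from_caches(caches, sets[0], 1.0)
        assert acc.mean() == observed

    def test_permutations_preserve_block_balance(self, tiny_config):
        ds = generate_subject(tiny_config, 0)
        sel = ds.trials.table.modality == "execution"
        sub = ds.trials.table[sel].reset_index(drop=True)
        y = np.where(sub["emotion"] == "fear", 1.0, -1.0)
        rng = np.random.default_rng(0)
        sets = permutation_label_sets(sub, y, len(sub), 25, rng)
        for p in range(25):
            for _, idx in sub.groupby("block").indices.items():
                assert sets[p, idx].sum() == 0  # 2 fear vs 2 anger per block

    def test_strong_signal_beats_every_permutation(self, tiny_config, roi_mask):
        ds = generate_subject(tiny_config, 0)
        spec = DecodingSpec.within_modality("execution")
        observed = decode(ds, roi_mask, spec).mean_accuracy
        null = subject_null(ds, roi_mask, spec,
                            InferenceConfig(n_perm=100, seed=4), stream=0)
        assert null.shape == (100,)
        assert np.all(null < observed)

    def test_cross_modal_null_leaves_test_labels_alone(self, tiny_config, roi_mask):
        ds = generate_subject(tiny_config, 0)
        spec = DecodingSpec.cross_modal("execution", "imitation")
        null = subject_null(ds, roi_mask, spec,
                            InferenceConfig(n_perm=30, seed=4), stream=1)
        # permuted training labels destroy the transfer: chance on average
        assert abs(null.mean() - 50.0) < 12.0

    def test_deterministic_given_seed(self, tiny_config, roi_mask):
        ds = generate_subject(tiny_config, 0)
        spec = DecodingSpec.within_modality("imitation")
        cfg = InferenceConfig(n_perm=10, seed=8)
        a = subject_null(ds, roi_mask, spec, cfg, stream="s")
        b = subject_null(ds, roi_mask, spec, cfg, stream="s")
        assert np.array_equal(a, b)


class TestGroupBootstrap:
    def test_observed_above_all_draws_gives_minimal_p(self):
        perm = np.full((5, 10), 40.0)
        cfg = InferenceConfig(n_perm=10, n_draws=1000, seed=0)
        res = group_bootstrap_p(60.0, perm, cfg)
        assert res.p == pytest.approx(1 / 1001)
        assert res.significant

    def test_all_ties_give_p_one(self):
        perm = np.full((4, 6), 55.0)
        cfg = InferenceConfig(n_perm=6, n_draws=500, seed=0)
        res = group_bootstrap_p(55.0, perm, cfg)
        assert res.p == 1.0
        assert not res.significant

    def test_two_subject_enumeration(self):
        # each subject's draw is 40 or 60 -> means {40, 50, 50, 60};
        # P(mean >= 60) = 1/4 exactly
        perm = np.array([[40.0, 60.0], [40.0, 60.0]])
        cfg = InferenceConfig(n_perm=2, n_draws=20_000, seed=3)
        res = group_bootstrap_p(60.0, perm, cfg)
        se = np.sqrt(0.25 * 0.75 / cfg.n_draws)
        assert abs(res.p - 0.25) < 3 * se + 1e-4

    @pytest.mark.parametrize("subjects,n_perm", [(2, 3), (4, 2), (1, 16)])
    def test_matches_exact_enumeration_on_small_instances(self, subjects, n_perm):
        """Monte-Carlo p converges to the exhaustive-enumeration value."""
        rng = np.random.default_rng(subjects * 10 + n_perm)
        perm = rng.integers(30, 70, size=(subjects, n_perm)).astype(float)
        observed = float(rng.integers(40, 60))
        means = [
            np.mean(combo)
            for combo in itertools.product(*perm)
        ]
        exact = np.mean([m >= observed for m in means])
        cfg = InferenceConfig(n_perm=n_perm, n_draws=40_000, seed=1)
        res = group_bootstrap_p(observed, perm, cfg)
        expected = (1 + cfg.n_draws * exact) / (cfg.n_draws + 1)
        se = np.sqrt(max(exact * (1 - exact), 1e-12) / cfg.n_draws)
        assert abs(res.p - expected) < 3 * se + 1e-4

    def test_p_monotone_in_observed_mean(self):
        rng = np.random.default_rng(0)
        perm = rng.uniform(30, 70, size=(6, 20))
        cfg = InferenceConfig(n_perm=20, n_draws=5000, seed=2)
        ps = [group_bootstrap_p(obs, perm, cfg).p for obs in (45.0, 50.0, 55.0, 60.0)]
        assert ps == sorted(ps, reverse=True)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ConfigError):
            group_bootstrap_p(50.0, np.empty((0, 0)),
                              InferenceConfig(n_draws=10, seed=0))

    def test_null_distribution_invariants(self):
        with pytest.raises(ConfigError):
            NullDistribution(np.array([[120.0]]))


class TestEmpiricalCalibration:
    def test_p_uniform_under_null(self):
        """Empirical p over null cohorts is uniform (KS test)."""
        from scipy.stats import kstest

        config = SyntheticConfig(
            grid_dims=(6, 6, 6),
            roi_specs=(cuboid_roi("roi", (1, 1, 1), (3, 3, 2)),),
            effect_amplitude=0.0,
            n_subjects=5,
            seed=0,
        )
        mask = VoxelMask("roi", config.roi_specs[0].grid(config.grid_dims))
        spec = DecodingSpec.within_modality("imitation")
        ps = []
        for rep in range(150):
            cohort = generate_cohort(config.with_(seed=1000 + rep))
            icfg = InferenceConfig(n_perm=15, n_draws=2000, seed=rep)
            group, _, _ = roi_group_analysis(cohort, mask, spec, icfg, stream=rep)
            ps.append(group.p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestFDR:
    def test_single_test_uses_raw_threshold(self):
        q, sig = fdr_correct(np.array([0.04]), alpha=0.05)
        assert sig[0] and q[0] == pytest.approx(0.04)

    def test_all_tiny_p_all_significant(self):
        q, sig = fdr_correct(np.full(100, 0.001), alpha=0.05)
        assert sig.all() and np.allclose(q, 0.001)

    def test_matches_manual_step_up(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=37)
        q, sig = fdr_correct(p, alpha=0.05)
        # independent step-up oracle
        order = np.argsort(p)
        m = len(p)
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        q_manual = np.empty(m)
        q_manual[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(q, q_manual, atol=1e-12)

    def test_invariant_to_voxel_ordering(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        shuffle = rng.permutation(50)
        q1, _ = fdr_correct(p)
        q2, _ = fdr_correct(p[shuffle])
        np.testing.assert_allclose(q1[shuffle], q2, atol=1e-12)

    def test_nan_entries_stay_out_of_family(self):
        p = np.array([0.01, np.nan, 0.5])
        q, sig = fdr_correct(p)
        assert np.isnan(q[1]) and not sig[1]

    def test_false_positive_proportion_controlled_under_null(self):
        """Across many global-null families, mean FDP stays near alpha."""
        rng = np.random.default_rng(11)
        fdp = []
        for _ in range(500):
            p = rng.uniform(size=50)
            _, sig = fdr_correct(p, alpha=0.05)
            fdp.append(1.0 if sig.any() else 0.0)
        assert np.mean(fdp) < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 500)


def _map_from(grid, mask=None):
    grid = np.asarray(grid, dtype=float)
    if mask is None:
        mask = np.isfinite(grid)
    return AccuracyMap(grid, VoxelMask("m", mask))


class TestReplicationOverlap:
    def _maps(self):
        a = np.full((4, 4, 4), 50.0)
        b = np.full((4, 4, 4), 50.0)
        a[0, :2, 0] = 75.0
        b[0, :2, 0] = 70.0
        b[3, 3, 3] = 80.0
        return _map_from(a), _map_from(b)

    def test_conjunction_thresholds_both_maps(self):
        ma, mb = self._maps()
        overlap = replication_overlap(ma, mb, ReplicationConfig(require_significance=False))
        assert overlap.provenance["n_replicated"] == 2
        assert overlap.grid[0, 0, 0] == 1.0 and overlap.grid[3, 3, 3] == 0.0

    def test_self_overlap_is_own_thresholded_mask(self):
        ma, _ = self._maps()
        overlap = replication_overlap(ma, ma, ReplicationConfig(require_significance=False))
        np.testing.assert_array_equal(overlap.grid == 1.0, ma.grid >= 60.0)

    def test_disjoint_suprathreshold_sets_empty_overlap(self):
        a = np.full((3, 3, 3), 50.0)
        b = np.full((3, 3, 3), 50.0)
        a[0, 0, 0] = 90.0
        b[2, 2, 2] = 90.0
        overlap = replication_overlap(_map_from(a), _map_from(b),
                                      ReplicationConfig(require_significance=False))
        assert overlap.provenance["n_replicated"] == 0

    def test_symmetric(self):
        ma, mb = self._maps()
        cfg = ReplicationConfig(require_significance=False)
        ab = replication_overlap(ma, mb, cfg)
        ba = replication_overlap(mb, ma, cfg)
        np.testing.assert_array_equal(ab.grid, ba.grid)

    def test_significance_masks_required_and_applied(self):
        ma, mb = self._maps()
        with pytest.raises(ConfigError):
            replication_overlap(ma, mb, ReplicationConfig())
        sig = np.zeros((4, 4, 4), dtype=bool)
        overlap = replication_overlap(ma, mb, ReplicationConfig(),
                                      sig_a=sig, sig_b=sig)
        assert overlap.provenance["n_replicated"] == 0

    def test_grid_mismatch_rejected(self):
        a = _map_from(np.full((3, 3, 3), 50.0))
        b = _map_from(np.full((4, 4, 4), 50.0))
        with pytest.raises(GridMismatchError):
            replication_overlap(a, b, ReplicationConfig(require_significance=False))

    def test_threshold_validation(self):
        with pytest.raises(ConfigError):
            ReplicationConfig(accuracy_threshold=45.0)
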