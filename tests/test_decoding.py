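"""Classifier correctness, fold construction, metrics and leakage guards."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from emodecode._svm import fit_linear_svm
from emodecode.datasets import ClassifierSpec, TrialTable, VoxelMask
from emodecode.decoding import (
    DecodingSpec,
    TrialSelection,
    compute_auc,
    decode,
    decode_matrix,
    extract_features,
    leave_one_block_out_folds,
)
from emodecode.errors import ConfigError, CrossValidationError, MaskError
from emodecode.simulate import SyntheticConfig, cuboid_roi, generate_subject, make_design

from conftest import dataset_from_table, toy_trial_table


# ---------------------------------------------------------------------------
# solver cross-check: our SMO solves the same dual as libsvm
# ---------------------------------------------------------------------------

class TestLinearSVM:
    def test_agrees_with_libsvm_on_random_problems(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n, p = int(rng.integers(8, 30)), int(rng.integers(2, 60))
            X = rng.normal(size=(n, p))
            y = np.ones(n)
            y[: n // 2] = -1
            rng.shuffle(y)
            w, b = fit_linear_svm(X, y, C=1.0)
            ref = SVC(kernel="linear", C=1.0).fit(X, y)
            Xt = rng.normal(size=(15, p))
            np.testing.assert_allclose(
                Xt @ w + b, ref.decision_function(Xt), atol=0.02, rtol=0.02
            )

    def test_constant_features_give_zero_rule(self):
        X = np.zeros((8, 5))
        y = np.array([1.0, -1.0] * 4)
        w, b = fit_linear_svm(X, y)
        assert np.all(w == 0) and b == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(16, 20))
        y = np.array([1.0, -1.0] * 8)
        w1, b1 = fit_linear_svm(X, y)
        w2, b2 = fit_linear_svm(X, y)
        assert np.array_equal(w1, w2) and b1 == b2


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

class TestFolds:
    def test_study1_execution_gives_5_folds_16_4(self):
        trials = make_design("study1")
        folds = leave_one_block_out_folds(trials, TrialSelection.modality("execution"))
        assert len(folds) == 5
        for train, test in folds:
            assert len(train) == 16 and len(test) == 4

    def test_folds_partition_selection(self):
        trials = make_design("study1")
        folds = leave_one_block_out_folds(trials, TrialSelection.modality("imitation"))
        all_test = np.sort(np.concatenate([t for _, t in folds]))
        assert np.array_equal(all_test, np.arange(20))
        for train, test in folds:
            assert len(np.intersect1d(train, test)) == 0

    def test_toy_two_blocks(self):
        trials = toy_trial_table(n_blocks=2, trials_per_block=2)
        folds = leave_one_block_out_folds(trials)
        assert len(folds) == 2
        for train, test in folds:
            assert len(train) == 2 and len(test) == 2

    def test_single_block_cannot_cross_validate(self):
        trials = toy_trial_table(n_blocks=1, trials_per_block=4)
        with pytest.raises(CrossValidationError, match="cannot cross-validate"):
            leave_one_block_out_folds(trials)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def test_shape_and_canonical_order(self):
        trials = toy_trial_table(n_blocks=2, trials_per_block=2)
        rng = np.random.default_rng(0)
        betas = rng.normal(size=(4, 3, 3, 3))
        ds = dataset_from_table(trials, betas)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[2, 1, 0] = mask[0, 0, 1] = mask[1, 2, 2] = True
        X, sub = extract_features(ds, VoxelMask("m", mask))
        assert X.shape == (4, 3)
        # columns follow lexicographic voxel order regardless of construction
        expected = np.stack(
            [betas[:, 0, 0, 1], betas[:, 1, 2, 2], betas[:, 2, 1, 0]], axis=1
        )
        np.testing.assert_array_equal(X, expected)

    def test_mask_outside_brain_rejected(self):
        trials = toy_trial_table()
        betas = np.zeros((4, 3, 3, 3))
        brain = np.zeros((3, 3, 3), dtype=bool)
        brain[0] = True
        ds = dataset_from_table(trials, betas, brain)
        roi = np.zeros((3, 3, 3), dtype=bool)
        roi[2] = True
        with pytest.raises(MaskError, match="empty mask"):
            extract_features(ds, VoxelMask("roi", roi))

    def test_empty_selection_rejected(self):
        trials = toy_trial_table(modality="execution")
        ds = dataset_from_table(trials, np.zeros((4, 3, 3, 3)))
        with pytest.raises(MaskError, match="empty selection"):
            extract_features(ds, VoxelMask("m", np.ones((3, 3, 3), dtype=bool)),
                             TrialSelection.modality("imitation"))


# ---------------------------------------------------------------------------
# decode
# ---------------------------------------------------------------------------

def _two_modality_dataset(flip_test_sign: bool):
    """Execution + imitation trials carrying the same (or sign-flipped) pattern."""
    rows = []
    idx = 0
    for mod in ("execution", "imitation"):
        for b in (1, 2):
            for emo in ("fear", "fear", "anger", "anger"):
                rows.append({"modality": mod, "emotion": emo, "block": b,
                             "trial_index": idx})
                idx += 1
    trials = TrialTable("toy", pd.DataFrame(rows))
    pattern = np.array([1.0, -0.5, 0.25])
    betas = np.zeros((16, 3, 1, 1))
    for i, row in trials.table.iterrows():
        s = 1.0 if row.emotion == "fear" else -1.0
        if row.modality == "imitation" and flip_test_sign:
            s = -s
        betas[i, :, 0, 0] = s * pattern
    return dataset_from_table(trials, betas)


class TestDecode:
    def test_noiseless_planted_pattern_is_perfect(self):
        ds = _two_modality_dataset(flip_test_sign=False)
        mask = VoxelMask("all", np.ones((3, 1, 1), dtype=bool))
        res = decode(ds, mask, DecodingSpec.within_modality("execution"))
        assert res.mean_accuracy == 100.0
        assert res.auc == 1.0
        assert res.n_folds == 2

    def test_sign_swapped_test_patterns_invert_accuracy(self):
        ds = _two_modality_dataset(flip_test_sign=True)
        mask = VoxelMask("all", np.ones((3, 1, 1), dtype=bool))
        res = decode(ds, mask, DecodingSpec.cross_modal("execution", "imitation"))
        assert res.mean_accuracy == 0.0

    def test_swapping_test_labels_inverts_accuracy_and_auc(self, tiny_config, roi_mask):
        """With a fixed trained rule, relabeling the balanced test set
        maps accuracy a -> 100 - a and AUC u -> 1 - u."""
        ds = generate_subject(tiny_config, 1)
        spec = DecodingSpec.cross_modal("execution", "imitation")
        res = decode(ds, roi_mask, spec)
        swapped_table = ds.trials.table.copy()
        test_rows = swapped_table["modality"] == "imitation"
        swapped_table.loc[test_rows, "emotion"] = swapped_table.loc[
            test_rows, "emotion"].map({"fear": "anger", "anger": "fear"})
        ds_swapped = dataset_from_table(
            TrialTable(ds.subject_id, swapped_table), ds.betas, ds.brain_mask)
        res_swapped = decode(ds_swapped, roi_mask, spec)
        assert res.mean_accuracy + res_swapped.mean_accuracy == pytest.approx(100.0)
        assert res.auc + res_swapped.auc == pytest.approx(1.0)

    def test_cv_none_with_overlapping_selections_is_leakage(self, tiny_config, roi_mask):
        ds = generate_subject(tiny_config, 0)
        spec = DecodingSpec(
            train=TrialSelection.modality("execution"),
            test=TrialSelection.modality("execution", "imitation"),
            cv="none",
        )
        with pytest.raises(ConfigError, match="leakage"):
            decode(ds, roi_mask, spec)

    def test_lobo_requires_matching_selections(self):
        with pytest.raises(ConfigError):
            DecodingSpec(
                train=TrialSelection.modality("execution"),
                test=TrialSelection.modality("imitation"),
                cv="leave_one_block_out",
            )

    def test_modality_labels_use_same_engine(self, tiny_config):
        ds = generate_subject(tiny_config, 0)
        mask = VoxelMask("brain", np.ones(tiny_config.grid_dims, dtype=bool))
        spec = DecodingSpec(
            label_column="modality",
            train=TrialSelection.modality("execution", "imitation"),
        )
        res = decode(ds, mask, spec)
        assert set(res.classes) == {"execution", "imitation"}
        assert 0.0 <= res.mean_accuracy <= 100.0

    def test_null_labels_decode_at_chance_over_many_runs(self):
        """Random relabelings of pure noise center at 50% accuracy."""
        rng = np.random.default_rng(99)
        accs = []
        blocks = np.repeat(np.arange(1, 6), 4)
        labels = np.array((["fear", "anger"] * 2) * 5)
        # 500 runs: per-run sd ~13.7 -> standard error ~0.6, so the +-2
        # band is a >3 sigma check
        for _ in range(500):
            X = rng.normal(size=(20, 10))
            accs.append(decode_matrix(X, labels, blocks=blocks).mean_accuracy)
        assert abs(np.mean(accs) - 50.0) < 2.0

    def test_zscore_train_scaling_recorded_and_works(self, tiny_config, roi_mask):
        ds = generate_subject(tiny_config, 0)
        spec = DecodingSpec.within_modality(
            "execution", classifier=ClassifierSpec(scaling="zscore_train"))
        res = decode(ds, roi_mask, spec)
        assert res.provenance["scaling"] == "zscore_train"
        assert res.mean_accuracy > 60.0


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

class TestAUC:
    def test_perfect_ranking(self):
        scores = [-2.0, -1.0, 1.0, 2.0]
        labels = ["anger", "anger", "fear", "fear"]
        assert compute_auc(scores, labels) == 1.0

    def test_tied_pairs_enumeration(self):
        # fear {0.2, 0.8} vs anger {0.5, 0.5}: of the 4 pairs, fear wins 2
        # and loses 2 -> AUC 0.5 by exhaustive enumeration
        scores = [0.2, 0.8, 0.5, 0.5]
        labels = ["fear", "fear", "anger", "anger"]
        assert compute_auc(scores, labels, positive_label="fear") == 0.5

    def test_matches_sklearn_on_random_scores(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(4, 40))
            scores = rng.normal(size=n).round(1)  # rounding forces ties
            labels = np.where(rng.random(n) < 0.5, "fear", "anger")
            if len(set(labels)) < 2:
                continue
            ours = compute_auc(scores, labels, positive_label="fear")
            ref = roc_auc_score((labels == "fear").astype(int), scores)
            assert ours == pytest.approx(ref, abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(
        scores=st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=12),
        shift=st.floats(0.1, 3.0),
    )
    def test_invariant_under_strictly_increasing_transform(self, scores, shift):
        n = len(scores)
        labels = ["fear" if i % 2 else "anger" for i in range(n)]
        scores = np.asarray(scores)
        before = compute_auc(scores, labels)
        # polynomial with positive derivative: strictly increasing and,
        # unlike exp, float-exact enough to preserve every ordering
        after = compute_auc(scores ** 3 + (2.0 + shift) * scores, labels)
        assert before == pytest.approx(after, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(Exception):
            compute_auc([0.1, 0.2], ["fear", "fear"])

    def test_undefined_auc_marker_for_single_class_test_set(self):
        X = np.array([[1.0], [-1.0], [2.0], [-2.0], [1.5]])
        labels = np.array(["fear", "anger", "fear", "anger", "fear"])
        splits = [(np.array([0, 1, 2, 3]), np.array([4]))]
        res = decode_matrix(X, labels, splits=splits)
        assert np.isnan(res.auc)
        assert res.mean_accuracy in (0.0, 100.0)
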