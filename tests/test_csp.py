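"""CSP decomposition, shrinkage LDA, SMOTE, both CV schemes and the
block-permutation null."""

import numpy as np
import pytest

from alphadec.csp import (
    ShrinkageLDA,
    _stratified_folds,
    block_permutation_test,
    csp_decompose,
    csp_features,
    permute_blocks,
    randomized_cv,
    smote_oversample,
    subblocked_cv,
    subblocked_folds,
)
from alphadec.spoc import EpochCovariances


def _epochs_with_variance(n_epochs, variances, n_samp=48):
    """Deterministic epochs with exact, diagonal channel covariance:
    channel c carries an orthogonal +/-1 square wave scaled to variance
    variances[c] (Hadamard rows are mutually orthogonal and mean-free)."""
    from scipy.linalg import hadamard

    m = 4
    while m < len(variances) + 1:
        m *= 2
    assert n_samp % m == 0
    H = hadamard(m)
    out = np.empty((n_epochs, n_samp, len(variances)))
    for c, v in enumerate(variances):
        out[:, :, c] = np.sqrt(v) * np.tile(H[c + 1], n_samp // m)
    return out


class TestDecompose:
    def test_identical_class_covariances_all_half(self, rng):
        tensor = rng.standard_normal((20, 30, 4))
        both = np.concatenate([tensor, tensor])
        labels = np.r_[np.ones(20), -np.ones(20)].astype(int)
        _, _, evals = csp_decompose(both, labels)
        np.testing.assert_allclose(evals, 0.5, atol=1e-8)

    def test_planted_variance_ratio_four_to_one(self):
        """Class variance ratio 4:1 in one channel -> top eigenvalue 4/5."""
        hi = _epochs_with_variance(10, [4.0, 1.0])
        lo = _epochs_with_variance(10, [1.0, 1.0])
        tensor = np.concatenate([hi, lo])
        labels = np.r_[np.ones(10), -np.ones(10)].astype(int)
        _, _, evals = csp_decompose(tensor, labels)
        assert evals[0] == pytest.approx(0.8, abs=1e-9)
        assert evals[1] == pytest.approx(0.5, abs=1e-9)

    def test_label_swap_symmetry(self, rng):
        tensor = rng.standard_normal((40, 30, 5))
        labels = np.where(rng.random(40) < 0.5, 1, -1)
        labels[:2] = [1, -1]  # ensure both classes
        _, _, ev = csp_decompose(tensor, labels)
        _, _, ev_swapped = csp_decompose(tensor, -labels)
        np.testing.assert_allclose(ev_swapped, (1 - ev)[::-1], atol=1e-10)

    def test_single_class_errors(self, rng):
        tensor = rng.standard_normal((10, 20, 3))
        with pytest.raises(ValueError):
            csp_decompose(tensor, np.ones(10, dtype=int))


class TestFeatures:
    def test_unit_variance_square_wave_gives_zero(self):
        tensor = _epochs_with_variance(3, [1.0, 1.0])
        feats = csp_features(tensor, np.eye(2), np.array([0, 1]))
        np.testing.assert_allclose(feats, 0.0, atol=1e-12)

    def test_scaling_adds_two_log_c(self, rng):
        tensor = rng.standard_normal((5, 40, 4))
        W = np.eye(4)
        idx = np.array([0, 1, 2, 3])
        base = csp_features(tensor, W, idx)
        scaled = csp_features(3.0 * tensor, W, idx)
        np.testing.assert_allclose(scaled - base, 2 * np.log(3.0), atol=1e-10)

    def test_default_shape_four_components(self, rng):
        tensor = rng.standard_normal((7, 40, 6))
        W, _, _ = csp_decompose(tensor, np.r_[np.ones(4), -np.ones(3)].astype(int))
        feats = csp_features(tensor, W)
        assert feats.shape == (7, 4)


class TestShrinkageLDA:
    def test_separable_1d(self, rng):
        X = np.r_[rng.normal(-1, 0.01, 50), rng.normal(1, 0.01, 50)][:, None]
        y = np.r_[-np.ones(50), np.ones(50)].astype(int)
        clf = ShrinkageLDA().fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_identical_means_chance_level(self):
        accs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 3))
            y = rng.permutation(np.r_[-np.ones(30), np.ones(30)].astype(int))
            clf = ShrinkageLDA().fit(X[:40], y[:40])
            accs.append(np.mean(clf.predict(X[40:]) == y[40:]))
        assert abs(np.mean(accs) - 0.5) < 0.07

    def test_shrinkage_intensity_bounded(self, rng):
        for _ in range(10):
            X = rng.standard_normal((30, 4)) * rng.uniform(0.1, 10)
            y = np.where(rng.random(30) < 0.5, 1, -1)
            y[:2] = [1, -1]
            clf = ShrinkageLDA().fit(X, y)
            assert 0.0 <= clf.shrinkage_ <= 1.0

    def test_rejects_multiclass(self, rng):
        with pytest.raises(ValueError):
            ShrinkageLDA().fit(rng.standard_normal((9, 2)), np.array([0, 1, 2] * 3))


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.r_[np.ones(5), -np.ones(5)].astype(int)
        X2, y2 = smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_counts_balanced(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.r_[np.ones(10), -np.ones(20)].astype(int)
        _, y2 = smote_oversample(X, y, seed=0)
        assert (y2 == 1).sum() == (y2 == -1).sum() == 20

    def test_synthetic_points_on_minority_segments(self, rng):
        X = rng.standard_normal((24, 2))
        y = np.r_[np.ones(8), -np.ones(16)].astype(int)
        X2, y2 = smote_oversample(X, y, seed=1)
        minority = X[:8]
        for s in X2[24:]:
            on_segment = False
            for i in range(8):
                for j in range(8):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    t = (s - minority[i]) @ d / (d @ d)
                    if -1e-9 <= t <= 1 + 1e-9 and np.allclose(
                        minority[i] + t * d, s, atol=1e-9
                    ):
                        on_segment = True
            assert on_segment

    def test_single_minority_duplicates(self, rng):
        X = rng.standard_normal((5, 2))
        y = np.array([1, -1, -1, -1, -1])
        X2, y2 = smote_oversample(X, y, seed=0)
        assert (y2 == 1).sum() == 4
        np.testing.assert_array_equal(X2[5:], np.repeat(X[:1], 3, axis=0))


class TestRandomizedCV:
    def test_planted_subject_decodes(self, planted_binary):
        res = randomized_cv(planted_binary["covs"], planted_binary["labels"], seed=0)
        assert res.mean_metric >= 0.70
        assert res.per_fold_metric.size == 10
        assert res.predictions.size == planted_binary["labels"].size

    def test_shuffled_labels_chance(self, planted_binary):
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(planted_binary["labels"])
        res = randomized_cv(planted_binary["covs"], shuffled, seed=0)
        assert 0.35 <= res.mean_metric <= 0.65

    def test_more_folds_than_epochs_errors(self, rng):
        with pytest.raises(ValueError):
            randomized_cv(rng.standard_normal((5, 20, 2)),
                          np.array([1, -1, 1, -1, 1]), k=10)

    def test_no_test_set_leakage(self, planted_binary):
        """Perturbing a test epoch never changes the training-fold filters."""
        covs = planted_binary["covs"].covs.copy()
        labels = planted_binary["labels"]
        folds = _stratified_folds(labels, 10, np.random.default_rng(0))
        test = folds[0]
        train = np.setdiff1d(np.arange(labels.size), test)
        W1, _, _ = csp_decompose(EpochCovariances(covs=covs[train]), labels[train])
        covs[test[0]] *= 7.3
        W2, _, _ = csp_decompose(EpochCovariances(covs=covs[train]), labels[train])
        np.testing.assert_array_equal(W1, W2)


class TestSubblockedCV:
    def test_fold_arithmetic_180(self):
        folds = subblocked_folds(180, k=10, n_subblocks=3)
        assert all(len(f) == 18 for f in folds)
        # each fold draws 6 consecutive epochs from each of the 3 sub-blocks
        first = folds[0]
        assert list(first[:6]) == list(range(0, 6))
        assert list(first[6:12]) == list(range(60, 66))
        assert list(first[12:]) == list(range(120, 126))

    def test_folds_partition_epochs(self):
        for n in (180, 187):
            folds = subblocked_folds(n, 10, 3)
            allidx = np.concatenate(folds)
            assert allidx.size == n
            assert np.array_equal(np.sort(allidx), np.arange(n))

    def test_too_few_epochs_errors(self):
        with pytest.raises(ValueError):
            subblocked_folds(20, 10, 3)

    def test_planted_subject_auc(self, planted_binary):
        res = subblocked_cv(planted_binary["covs"], planted_binary["labels"], seed=0)
        assert res.mean_metric >= 0.65

    def test_null_subject_auc_near_chance(self, null_subject):
        from alphadec.preprocess import tertile_labels
        from alphadec.spoc import epoch_covariances

        labels = tertile_labels(null_subject["trace"])
        covs = epoch_covariances(null_subject["tensor"][labels.binary_mask])
        res = subblocked_cv(covs, labels.binary_labels, seed=0)
        assert 0.2 <= res.mean_metric <= 0.8


class TestBlockPermutation:
    def test_blocks_stay_intact(self, rng):
        labels = np.arange(50)
        permuted = permute_blocks(labels, 10, rng)
        blocks = permuted.reshape(10, 5)
        # every block of 5 is one of the original consecutive runs
        starts = blocks[:, 0]
        for b, s in zip(blocks, starts):
            np.testing.assert_array_equal(b, np.arange(s, s + 5))
        assert sorted(starts) == list(range(0, 50, 5))

    def test_constant_metric_gives_p_one(self, planted_binary):
        obs, p, null = block_permutation_test(
            planted_binary["covs"], planted_binary["labels"],
            lambda c, l: 0.5, n_perm=20, seed=0,
        )
        assert obs == 0.5 and p == 1.0

    def test_planted_signal_significant(self, planted_binary):
        def acc(c, l):
            return randomized_cv(c, l, seed=99).mean_metric

        obs, p, null = block_permutation_test(
            planted_binary["covs"], planted_binary["labels"], acc, n_perm=100, seed=0
        )
        assert obs > np.max(null) - 1e-12
        assert p == pytest.approx(1 / 101)

    def test_more_blocks_than_epochs_errors(self, rng):
        with pytest.raises(ValueError):
            block_permutation_test(
                rng.standard_normal((5, 10, 2)), np.array([1, -1, 1, -1, 1]),
                lambda c, l: 0.5, n_blocks=10, n_perm=5,
            )
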