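"""LSTM decoder: gradient correctness, contracts of the dataset builder,
regularization, prediction rule and the two-step random search."""

import numpy as np
import pytest

from alphadec.lstm import (
    HPConfig,
    HPSpace,
    LSTMDataset,
    LSTMNet,
    build_dataset,
    evaluate_cv,
    predict,
    random_search,
    sample_hp,
    train,
)
from alphadec.preprocess import EpochedData, tertile_labels


class TestHPConfig:
    def test_bottleneck_violation_rejected(self):
        with pytest.raises(ValueError):
            HPConfig(lstm_sizes=(10,), fc_sizes=(25,))
        with pytest.raises(ValueError):
            HPConfig(lstm_sizes=(20, 40), fc_sizes=(10,))

    def test_off_grid_values_rejected(self):
        with pytest.raises(ValueError):
            HPConfig(lstm_sizes=(23,))
        with pytest.raises(ValueError):
            HPConfig(reg_strength=0.5)
        with pytest.raises(ValueError):
            HPConfig(learning_rate=3e-4)
        with pytest.raises(ValueError):
            HPConfig(n_components=11)

    def test_valid_config(self):
        hp = HPConfig(lstm_sizes=(40, 20), fc_sizes=(20, 10), activation="elu",
                      regularizer="l1", reg_strength=0.18, learning_rate=1e-2)
        assert hp.batch_size == 9 and hp.n_epochs_train == 20


class TestGradients:
    @pytest.mark.parametrize(
        "hp",
        [
            HPConfig(lstm_sizes=(10,), fc_sizes=(10,), activation="relu"),
            HPConfig(lstm_sizes=(15, 10), fc_sizes=(10, 10), activation="elu"),
        ],
        ids=["one-layer-relu", "two-layer-elu"],
    )
    def test_backprop_matches_finite_differences(self, hp):
        rng = np.random.default_rng(0)
        net = LSTMNet(hp, input_dim=3, rng=rng)
        X = rng.standard_normal((2, 6, 3))
        y = np.array([1.0, -1.0])

        def loss():
            out = net.forward(X)
            return float(np.mean((out - y) ** 2))

        out, cache = net.forward(X, want_cache=True)
        grads = net.backward(cache, 2 * (out - y) / y.size)
        check_rng = np.random.default_rng(1)
        for key, param in net.params.items():
            flat = check_rng.choice(param.size, size=min(5, param.size), replace=False)
            for fi in flat:
                idx = np.unravel_index(fi, param.shape)
                eps, orig = 1e-6, param[idx]
                param[idx] = orig + eps
                lp = loss()
                param[idx] = orig - eps
                lm = loss()
                param[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(numeric) + abs(grads[key][idx]))
                assert abs(numeric - grads[key][idx]) / denom < 1e-4, key


class TestDataset:
    @pytest.fixture()
    def epoched(self, rng):
        # 30 epochs, 25 samples, 7 available components
        return EpochedData(tensor=rng.standard_normal((30, 25, 7)), fs=25.0)

    def test_zero_padding_beyond_available(self, epoched, rng):
        labels = tertile_labels(rng.standard_normal(30))
        ds = build_dataset(epoched, labels, n_components=10)
        assert ds.tensor.shape[2] == 10
        assert np.all(ds.tensor[:, :, 7:] == 0)
        assert np.any(ds.tensor[:, :, :7] != 0)

    def test_mid_tertile_dropped(self, epoched, rng):
        labels = tertile_labels(rng.standard_normal(30))
        ds = build_dataset(epoched, labels)
        assert ds.n_epochs == 20
        assert set(np.unique(ds.labels)) == {-1, 1}

    def test_270_epochs_yield_180(self, rng):
        epoched = EpochedData(tensor=rng.standard_normal((270, 25, 4)), fs=25.0)
        labels = tertile_labels(rng.standard_normal(270))
        assert build_dataset(epoched, labels).n_epochs == 180

    def test_component_slot_cap(self, epoched, rng):
        labels = tertile_labels(rng.standard_normal(30))
        with pytest.raises(ValueError):
            build_dataset(epoched, labels, n_components=11)

    def test_standardization(self, epoched, rng):
        labels = tertile_labels(rng.standard_normal(30))
        ds = build_dataset(epoched, labels, n_components=7)
        # roughly unit scale per used slot (mid-tertile rows were dropped)
        sds = ds.tensor[:, :, :7].std(axis=(0, 1))
        assert np.all((sds > 0.7) & (sds < 1.3))


class TestTraining:
    def _toy(self, rng, n=36, t=20):
        """Separable toy data: label +1 epochs have 3x the amplitude."""
        y = np.resize([1, -1], n)
        X = rng.standard_normal((n, t, 10))
        X[y == 1] *= 3.0
        return LSTMDataset(tensor=X, labels=y)

    def test_output_in_tanh_range(self, rng):
        ds = self._toy(rng)
        model, _ = train(ds, HPConfig(seed=0, n_epochs_train=2))
        _, scores = predict(model, ds.tensor)
        assert np.all(np.abs(scores) < 1.0)

    def test_loss_decreases(self, rng):
        drops = []
        for seed in range(3):
            ds = self._toy(np.random.default_rng(seed))
            _, curve = train(ds, HPConfig(seed=seed, n_epochs_train=5))
            drops.append(curve[4] < curve[0])
        assert np.median(drops) == 1

    def test_l2_shrinks_weight_norm(self, rng):
        ds = self._toy(rng)
        hp0 = HPConfig(seed=5, reg_strength=0.0, n_epochs_train=5)
        hp2 = HPConfig(seed=5, reg_strength=1.44, n_epochs_train=5)
        m0, _ = train(ds, hp0)
        m2, _ = train(ds, hp2)
        assert m2.weight_norm() < m0.weight_norm()

    def test_empty_dataset_errors(self):
        ds = LSTMDataset(tensor=np.zeros((0, 5, 10)), labels=np.zeros(0, dtype=int))
        with pytest.raises(ValueError):
            train(ds, HPConfig(seed=0))

    def test_prediction_sign_rule(self, rng):
        ds = self._toy(rng)
        model, _ = train(ds, HPConfig(seed=1, n_epochs_train=2))
        labels, scores = predict(model, ds.tensor)
        np.testing.assert_array_equal(labels, np.where(scores >= 0, 1, -1))

    def test_constant_input_chance_level(self):
        """No signal in, chance out: constant-zero input with balanced
        labels gives 0.5 CV accuracy (constant model output)."""
        accs = []
        for seed in range(3):
            ds = LSTMDataset(
                tensor=np.zeros((40, 20, 10)),
                labels=np.resize([1, -1], 40),
            )
            acc, _ = evaluate_cv(ds, HPConfig(seed=seed, n_epochs_train=3), k=4, seed=seed)
            accs.append(acc)
        assert abs(np.median(accs) - 0.5) < 0.1


class TestRandomSearch:
    def _datasets(self, rng, n_subjects=4):
        return {
            sid: LSTMDataset(
                tensor=rng.standard_normal((20, 10, 10)), labels=np.resize([1, -1], 20)
            )
            for sid in range(n_subjects)
        }

    @staticmethod
    def _score(hp: HPConfig) -> float:
        # deterministic pseudo-score from the configuration itself
        return (hash((hp.lstm_sizes, hp.fc_sizes, hp.learning_rate)) % 997) / 997

    def test_single_draw_is_best(self, rng):
        subjects = self._datasets(rng)
        best = random_search(subjects, n_draws=1, seed=0,
                             eval_fn=lambda ds, hp: self._score(hp))
        assert len(set(best.values())) == 1

    def test_deterministic_given_seed(self, rng):
        subjects = self._datasets(rng)
        fn = lambda ds, hp: self._score(hp)  # noqa: E731
        a = random_search(subjects, n_draws=5, seed=3, eval_fn=fn)
        b = random_search(subjects, n_draws=5, seed=3, eval_fn=fn)
        assert a == b

    def test_selection_is_argmax_over_candidates(self, rng):
        subjects = self._datasets(rng)
        best = random_search(subjects, n_draws=6, seed=1,
                             eval_fn=lambda ds, hp: self._score(hp))
        # with a subject-independent score every subject gets the same winner
        scores = {self._score(hp) for hp in best.values()}
        assert len(scores) == 1

    def test_sampled_configs_respect_bottleneck(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            hp = sample_hp(HPSpace(), rng)  # __post_init__ validates
            sizes = hp.lstm_sizes + hp.fc_sizes
            assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_no_draws_errors(self, rng):
        with pytest.raises(ValueError):
            random_search(self._datasets(rng), n_draws=0, seed=0)
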