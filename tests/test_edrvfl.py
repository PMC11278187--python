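import numpy as np
import pytest

from ctstroke.edrvfl import (
    EdRVFLConfig,
    fit,
    hidden_stack,
    init_model,
    load_model,
    predict,
    predict_scores,
    save_model,
)

from oracles import ridge_normal_equations


def _blobs(rng, n_per=50, gap=6.0):
    """Two linearly separable Gaussian blobs (gap ≫ spread)."""
    a = rng.normal(0, 1, size=(n_per, 2))
    b = rng.normal(gap, 1, size=(n_per, 2))
    X = np.vstack([a, b])
    y = np.array(["neg"] * n_per + ["pos"] * n_per, dtype=object)
    return X, y


class TestInitModel:
    def test_same_seed_gives_identical_weights(self):
        cfg = EdRVFLConfig(seed=42)
        a, b = init_model(5, 2, cfg), init_model(5, 2, cfg)
        for la, lb in zip(a.layers, b.layers):
            assert np.array_equal(la.W, lb.W) and np.array_equal(la.b, lb.b)

    def test_layer_count_and_shapes(self):
        model = init_model(7, 3, EdRVFLConfig(n_layers=10, n_nodes=10))
        assert len(model.layers) == 10
        assert model.layers[0].W.shape == (7, 10)
        assert model.layers[1].W.shape == (17, 10)  # [hidden | input] feeds deeper layers

    def test_weights_supported_on_unit_interval(self):
        model = init_model(50, 2, EdRVFLConfig(n_nodes=100, n_layers=2, seed=0))
        W = np.concatenate([l.W.ravel() for l in model.layers])
        assert W.size >= 10_000 and W.min() >= -1.0 and W.max() <= 1.0

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            init_model(3, 1, EdRVFLConfig())


class TestHiddenStack:
    def test_zero_nodes_reduces_to_direct_links_only(self, rng):
        X = rng.normal(size=(5, 3))
        model = init_model(3, 2, EdRVFLConfig(n_nodes=0, n_layers=4))
        for D in hidden_stack(model, X):
            assert np.array_equal(D, np.hstack([X, np.ones((5, 1))]))

    def test_tanh_activations_bounded(self, rng):
        X = rng.normal(size=(20, 4))
        model = init_model(4, 2, EdRVFLConfig(n_nodes=8, n_layers=3))
        for D in hidden_stack(model, X):
            H = D[:, :8]
            assert np.all(np.abs(H) < 1.0)

    def test_single_layer_matches_hand_computed_product(self):
        model = init_model(2, 2, EdRVFLConfig(n_nodes=2, n_layers=1, seed=0))
        X = np.array([[1.0, 2.0], [0.5, -1.0], [0.0, 0.0]])
        expected = np.tanh(X @ model.layers[0].W + model.layers[0].b)
        D = hidden_stack(model, X)[0]
        assert np.allclose(D[:, :2], expected, atol=1e-12)
        assert np.allclose(D[:, 2:4], X) and np.all(D[:, 4] == 1.0)


class TestFit:
    @pytest.mark.parametrize("convention", ["inverse_c", "direct_lambda"])
    def test_degenerate_model_is_plain_ridge(self, rng, convention):
        # L=1, zero hidden nodes: the head must solve ridge regression of
        # one-hot targets on [standardized X | 1] exactly
        for _ in range(5):
            X = rng.normal(size=(10, 3))
            y = rng.choice(["a", "b", "c"], size=10)
            while len(np.unique(y)) < 3:
                y = rng.choice(["a", "b", "c"], size=10)
            cfg = EdRVFLConfig(n_nodes=0, n_layers=1, reg_c=100.0, ridge_convention=convention)
            model = fit(init_model(3, 3, cfg), X, y)
            Xs = (X - model.feat_mean) / model.feat_std
            D = np.hstack([Xs, np.ones((10, 1))])
            Y = np.zeros((10, 3))
            for i, c in enumerate(sorted(np.unique(y))):
                Y[np.asarray(y) == c, i] = 1.0
            lam = 1.0 / 100.0 if convention == "inverse_c" else 100.0
            expected = ridge_normal_equations(D, Y, lam)
            assert np.max(np.abs(model.heads[0] - expected)) <= 1e-8

    def test_vanishing_reg_c_drives_heads_to_zero(self, rng):
        X, y = _blobs(rng)
        cfg = EdRVFLConfig(reg_c=1e-12, ridge_convention="inverse_c", seed=0)
        model = fit(init_model(2, 2, cfg), X, y)
        assert all(np.max(np.abs(W)) < 1e-6 for W in model.heads)
        assert np.max(np.abs(predict_scores(model, X))) < 1e-6

    def test_separable_blobs_reach_perfect_training_accuracy(self, rng):
        X, y = _blobs(rng)
        # separability sanity: the midpoint hyperplane splits them
        assert np.all(X[y == "neg"].sum(axis=1) < 6.0) and np.all(X[y == "pos"].sum(axis=1) > 6.0)
        model = fit(init_model(2, 2, EdRVFLConfig(seed=1)), X, y)
        assert np.mean(predict(model, X) == y) == 1.0

    def test_single_class_labels_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit(init_model(2, 2, EdRVFLConfig()), X, np.array(["a"] * 10))

    def test_row_permutation_leaves_heads_unchanged(self, rng):
        X, y = _blobs(rng, n_per=30)
        perm = rng.permutation(len(y))
        cfg = EdRVFLConfig(seed=3)
        m1 = fit(init_model(2, 2, cfg), X, y)
        m2 = fit(init_model(2, 2, cfg), X[perm], y[perm])
        for a, b in zip(m1.heads, m2.heads):
            assert np.max(np.abs(a - b)) <= 1e-10

    def test_fit_predict_bit_stable(self, rng):
        X, y = _blobs(rng)
        cfg = EdRVFLConfig(seed=9)
        s1 = predict_scores(fit(init_model(2, 2, cfg), X, y), X)
        s2 = predict_scores(fit(init_model(2, 2, cfg), X, y), X)
        assert np.array_equal(s1, s2)


class TestAggregation:
    def test_mean_of_identical_layers_equals_single_layer(self, rng):
        # with zero hidden nodes every layer's design block is identical,
        # so the ensemble mean must equal any single head's output
        X, y = _blobs(rng, n_per=20)
        cfg = EdRVFLConfig(n_nodes=0, n_layers=5, seed=2)
        model = fit(init_model(2, 2, cfg), X, y)
        Xs = (X - model.feat_mean) / model.feat_std
        single = np.hstack([Xs, np.ones((len(X), 1))]) @ model.heads[0]
        assert np.allclose(predict_scores(model, X), single, atol=1e-10)

    def test_mean_lies_in_per_layer_envelope(self, rng):
        X, y = _blobs(rng, n_per=20)
        model = fit(init_model(2, 2, EdRVFLConfig(seed=4)), X, y)
        Xs = (X - model.feat_mean) / model.feat_std
        per_layer = np.stack([D @ W for D, W in zip(hidden_stack(model, Xs), model.heads)])
        agg = predict_scores(model, X)
        assert np.all(agg >= per_layer.min(axis=0) - 1e-12)
        assert np.all(agg <= per_layer.max(axis=0) + 1e-12)

    def test_two_layer_hand_set_heads_average_exactly(self, rng):
        X, y = _blobs(rng, n_per=5)
        cfg = EdRVFLConfig(n_nodes=0, n_layers=2, seed=0)
        model = fit(init_model(2, 2, cfg), X, y)
        model.heads[0] = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        model.heads[1] = np.array([[3.0, 0.0], [0.0, -1.0], [1.0, 1.0]])
        Xs = (X - model.feat_mean) / model.feat_std
        D = np.hstack([Xs, np.ones((len(X), 1))])
        expected = (D @ model.heads[0] + D @ model.heads[1]) / 2.0
        assert np.allclose(predict_scores(model, X), expected, atol=1e-12)

    def test_majority_vote_shares_sum_to_one(self, rng):
        X, y = _blobs(rng)
        cfg = EdRVFLConfig(aggregation="majority_vote", seed=5)
        model = fit(init_model(2, 2, cfg), X, y)
        votes = predict_scores(model, X)
        assert np.allclose(votes.sum(axis=1), 1.0)

    def test_scores_always_finite(self, rng):
        X, y = _blobs(rng)
        model = fit(init_model(2, 2, EdRVFLConfig(seed=6)), X, y)
        assert np.all(np.isfinite(predict_scores(model, X * 100)))


class TestPredict:
    def test_argmax_and_tie_break_toward_first_class(self, rng):
        X, y = _blobs(rng, n_per=10)
        cfg = EdRVFLConfig(n_nodes=0, n_layers=1, seed=0)
        model = fit(init_model(2, 2, cfg), X, y)
        model.heads[0] = np.zeros_like(model.heads[0])  # all scores tie at 0
        assert list(predict(model, X)) == [model.classes[0]] * len(X)

    def test_unfitted_model_raises_state_error(self):
        model = init_model(2, 2, EdRVFLConfig())
        with pytest.raises(RuntimeError):
            predict(model, np.zeros((1, 2)))

    def test_nonlinear_task_benefits_from_enhancement_nodes(self):
        # concentric classes are not linearly separable: random hidden
        # features must beat the pure direct-link model on average
        def ring_data(seed, n=200):
            r = np.random.default_rng(seed)
            radius = np.concatenate([r.uniform(0, 1, n // 2), r.uniform(2, 3, n // 2)])
            theta = r.uniform(0, 2 * np.pi, n)
            X = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
            y = np.array(["in"] * (n // 2) + ["out"] * (n // 2), dtype=object)
            return X, y

        from ctstroke.pipeline import kfold_split

        def cv_acc(n_nodes, seed):
            X, y = ring_data(seed)
            accs = []
            for train, test in kfold_split(len(y), 5, seed, y):
                cfg = EdRVFLConfig(n_nodes=n_nodes, seed=seed)
                m = fit(init_model(2, 2, cfg), X[train], y[train])
                accs.append(np.mean(predict(m, X[test]) == y[test]))
            return np.mean(accs)

        with_nodes = np.mean([cv_acc(10, s) for s in range(5)])
        without = np.mean([cv_acc(0, s) for s in range(5)])
        assert with_nodes >= without


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        X, y = _blobs(rng)
        model = fit(init_model(2, 2, EdRVFLConfig(seed=7)), X, y)
        path = tmp_path / "model.npz"
        save_model(model, path)
        restored = load_model(path)
        assert restored.classes == model.classes
        assert np.array_equal(predict_scores(restored, X), predict_scores(model, X))
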