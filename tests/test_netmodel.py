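"""Network forward pass, cost, training, cross-validation, persistence."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from oudup.netmodel import (
    CVResult,
    NetworkConfig,
    TrainedModel,
    classify,
    cost,
    cross_validate,
    forward,
    load_model,
    make_stratified_folds,
    predict_parameters,
    save_model,
    train,
)


def toy_model(task="classify", n_hidden=0, p=4, k=3, **kw) -> TrainedModel:
    cfg = NetworkConfig(task=task, input_dim=p, output_dim=k, n_hidden=n_hidden,
                        standardize=False, **kw)
    dims = cfg.layer_dims
    weights = [np.zeros((dims[i], dims[i + 1]), dtype=np.float32)
               for i in range(len(dims) - 1)]
    biases = [np.zeros(dims[i + 1], dtype=np.float32) for i in range(len(dims) - 1)]
    return TrainedModel(config=cfg, weights=weights, biases=biases,
                        feature_mean=np.zeros(p), feature_sd=np.ones(p))


def blobs(n_per, centers, sd, seed):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for i, c in enumerate(centers):
        xs.append(rng.normal(loc=c, scale=sd, size=(n_per, len(c))))
        ys.append(np.full(n_per, i))
    return np.vstack(xs), np.concatenate(ys)


class TestForward:
    def test_zero_weights_give_uniform_softmax(self):
        model = toy_model()
        out = forward(model, np.ones(4))
        assert np.allclose(out, 1 / 3)
        five = toy_model(k=5)
        assert np.allclose(forward(five, np.ones(4)), 0.2)

    def test_softmax_rows_sum_to_one(self):
        model = toy_model(n_hidden=2)
        rng = np.random.default_rng(0)
        model.weights = [rng.normal(scale=0.05, size=w.shape).astype(np.float32)
                         for w in model.weights]
        out = forward(model, rng.normal(size=(10, 4)))
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(out > 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            forward(toy_model(), np.ones(5))

    def test_hidden_widths_halve(self):
        cfg = NetworkConfig(task="classify", input_dim=108, output_dim=5, n_hidden=3)
        assert cfg.hidden_widths == [256, 128, 64]


class TestCost:
    def test_no_penalty_equals_mean_loss(self):
        model = toy_model()
        x = np.ones((6, 4))
        y = np.array([0, 1, 2, 0, 1, 2])
        assert np.isclose(cost(model, x, y, lambda_=0.0, gamma=0.5), np.log(3))

    def test_perfect_prediction_has_zero_loss(self):
        model = toy_model(task="predict", k=2)
        x = np.zeros((3, 4))
        y = np.zeros((3, 2))
        assert cost(model, x, y, lambda_=0.0, gamma=0.0) == 0.0

    def test_elastic_net_penalty_single_weight(self):
        model = toy_model(task="predict", p=1, k=1)
        w = 0.7
        model.weights[0] = np.array([[w]], dtype=np.float32)
        # J = loss + lambda [(1-gamma) w^2 + gamma |w|] with x=0 so loss = 0
        got = cost(model, np.zeros((2, 1)), np.zeros((2, 1)), lambda_=1.0, gamma=0.5)
        assert np.isclose(got, 0.5 * w**2 + 0.5 * w, atol=1e-6)


class TestTrain:
    def test_separable_toy_reaches_high_accuracy(self):
        x, y = blobs(100, [(-3.0, 0.0), (3.0, 0.0)], 0.5, seed=1)
        cfg = NetworkConfig(task="classify", input_dim=2, output_dim=2, n_hidden=0,
                            epochs=300, batch_size=200, learning_rate=0.05)
        model = train(x, y, cfg, rng_seed=2)
        _, called = classify(model, x)
        assert (called == y).mean() >= 0.99

    def test_seed_reproducibility(self):
        x, y = blobs(50, [(-1.0, 0.0), (1.0, 0.0)], 1.0, seed=3)
        cfg = NetworkConfig(task="classify", input_dim=2, output_dim=2, n_hidden=1,
                            epochs=5, batch_size=32)
        a = train(x, y, cfg, rng_seed=9)
        b = train(x, y, cfg, rng_seed=9)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_l0_matches_sklearn_multinomial_regression(self):
        # dual route: our Adam-trained softmax regression vs sklearn's LBFGS MLE
        x, y = blobs(200, [(0.0, 0.0), (2.0, 0.0), (0.0, 2.0)], 1.0, seed=4)
        cfg = NetworkConfig(task="classify", input_dim=2, output_dim=3, n_hidden=0,
                            epochs=2000, batch_size=600, learning_rate=0.02,
                            standardize=False, dtype="float64")
        model = train(x, y, cfg, rng_seed=5)
        ref = LogisticRegression(C=1e6, max_iter=2000).fit(x, y)
        ours = forward(model, x)
        theirs = ref.predict_proba(x)
        assert np.abs(ours - theirs).max() < 0.02
        assert (ours.argmax(1) == theirs.argmax(1)).mean() > 0.995

    def test_huge_lambda_collapses_to_class_priors(self):
        x, y = blobs(60, [(-2.0, 0.0), (2.0, 0.0)], 0.5, seed=6)
        # unbalance the classes: priors 2:1
        keep = np.concatenate([np.arange(60), 60 + np.arange(30)])
        cfg = NetworkConfig(task="classify", input_dim=2, output_dim=2, n_hidden=0,
                            epochs=500, batch_size=90, lambda_=100.0, gamma=0.0,
                            learning_rate=0.05)
        model = train(x[keep], y[keep], cfg, rng_seed=7)
        probs = forward(model, x[keep])
        assert np.allclose(probs.mean(axis=0), [2 / 3, 1 / 3], atol=0.03)
        assert probs.std(axis=0).max() < 0.02  # bias-only model

    def test_predictor_learns_linear_map(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(500, 3))
        w_true = np.array([[1.0, -2.0], [0.5, 0.0], [0.0, 3.0]])
        y = x @ w_true + 0.5
        cfg = NetworkConfig(task="predict", input_dim=3, output_dim=2, n_hidden=0,
                            epochs=800, batch_size=500, learning_rate=0.05,
                            standardize=False, dtype="float64")
        model = train(x, y, cfg, rng_seed=9)
        assert np.allclose(model.weights[0], w_true, atol=0.02)
        assert np.allclose(model.biases[0], 0.5, atol=0.02)

    def test_task_mismatch_errors(self):
        model = toy_model(task="classify")
        with pytest.raises(ValueError):
            predict_parameters(model, np.ones(4))
        with pytest.raises(ValueError):
            classify(toy_model(task="predict"), np.ones(4))


class TestCrossValidation:
    def test_fold_sizes_and_balance(self):
        labels = np.repeat(np.arange(5), 1000)
        folds = make_stratified_folds(labels, 5, rng=0)
        for tr, val in folds:
            assert len(tr) == 4000 and len(val) == 1000
            assert all((labels[val] == k).sum() == 200 for k in range(5))
            assert len(np.intersect1d(tr, val)) == 0

    def test_duplicated_grid_points_score_identically(self):
        x, y = blobs(60, [(-1.0, 0.0), (1.0, 0.0)], 1.0, seed=10)
        cfg = NetworkConfig(task="classify", input_dim=2, output_dim=2, n_hidden=0,
                            epochs=20, batch_size=40)
        grid = [{"lambda_": 1e-4, "gamma": 0.5}, {"lambda_": 1e-4, "gamma": 0.5}]
        res = cross_validate(x, y, grid, cfg, rng_seed=11)
        assert res.grid[0]["mean_loss"] == res.grid[1]["mean_loss"]

    def test_selected_point_is_argmin(self):
        x, y = blobs(60, [(-2.0, 0.0), (2.0, 0.0)], 0.8, seed=12)
        cfg = NetworkConfig(task="classify", input_dim=2, output_dim=2, n_hidden=0,
                            epochs=30, batch_size=40)
        grid = [{"lambda_": 0.0, "gamma": 0.0}, {"lambda_": 10.0, "gamma": 0.0}]
        res = cross_validate(x, y, grid, cfg, rng_seed=13)
        assert res.selected["mean_loss"] <= min(g["mean_loss"] for g in res.grid)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(np.ones((4, 2)), np.array([0, 1, 0, 1]), [],
                           NetworkConfig(task="classify", input_dim=2, output_dim=2))


class TestPersistence:
    def test_round_trip(self, tmp_path):
        x, y = blobs(40, [(-1.0, 0.0), (1.0, 0.0)], 1.0, seed=14)
        cfg = NetworkConfig(task="classify", input_dim=2, output_dim=2, n_hidden=1,
                            epochs=10, batch_size=40)
        model = train(x, y, cfg, rng_seed=15)
        path = str(tmp_path / "model.npz")
        save_model(model, path)
        loaded = load_model(path)
        assert np.array_equal(forward(model, x), forward(loaded, x))

    def test_feature_version_guard(self, tmp_path):
        model = toy_model()
        path = str(tmp_path / "model.npz")
        save_model(model, path)
        with pytest.raises(ValueError, match="feature layout"):
            load_model(path, expected_feature_version="other-layout-v9")
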