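"""Fourier features, standardization, training, evaluation, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.neural_network import MLPRegressor

from needleflex.dataset import EncodedDataset
from needleflex.surrogate import (
    FourierMap,
    Standardizer,
    SurrogateModel,
    evaluate,
    fourier_features,
    grid_search,
    load_model,
    save_model,
    train_ffnn,
    train_mlp,
    train_ols,
)


def make_dataset(X: np.ndarray, Y: np.ndarray, samples_per_traj: int = 4) -> EncodedDataset:
    ids = np.arange(X.shape[0]) // samples_per_traj
    return EncodedDataset(X, Y, ids)


def random_dataset(n: int, seed: int = 0) -> EncodedDataset:
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 0.2, size=(n, 126))
    X[:, -1] = rng.integers(1, 125, size=n)
    Y = rng.normal(size=(n, 48))
    return make_dataset(X, Y)


class TestFourierFeatures:
    def test_zero_matrix_maps_to_sin_zero_cos_one(self):
        B = np.zeros((126, 126))
        fmap = FourierMap(B=B, scale=0.1, seed=0)
        out = fourier_features(np.ones(126), fmap)
        np.testing.assert_array_equal(out[:126], 0.0)
        np.testing.assert_array_equal(out[126:], 1.0)

    def test_zero_input_maps_to_sin_zero_cos_one_for_any_map(self):
        fmap = FourierMap.create(126, scale=0.7, seed=3)
        out = fourier_features(np.zeros(126), fmap)
        np.testing.assert_array_equal(out[:126], 0.0)
        np.testing.assert_array_equal(out[126:], 1.0)

    @given(
        x=arrays(np.float64, 7, elements=st.floats(-1e4, 1e4)),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=40, deadline=None)
    def test_bounded_and_pythagorean(self, x, seed):
        """sin^2 + cos^2 = 1 per projection dim; output always in [-1, 1]."""
        fmap = FourierMap.create(7, scale=2.0, seed=seed)
        out = fourier_features(x, fmap)
        assert np.all(np.abs(out) <= 1.0)
        np.testing.assert_allclose(out[:7] ** 2 + out[7:] ** 2, 1.0, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        fmap = FourierMap.create(126, scale=0.2, seed=0)
        with pytest.raises(ValueError, match="features"):
            fourier_features(np.zeros(10), fmap)

    def test_map_frozen_and_seeded(self):
        a = FourierMap.create(5, scale=0.3, seed=9)
        b = FourierMap.create(5, scale=0.3, seed=9)
        np.testing.assert_array_equal(a.B, b.B)
        with pytest.raises(ValueError):
            a.B[0, 0] = 1.0


class TestStandardizer:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 8)) * rng.uniform(0.1, 10, 8)
        s = Standardizer.fit(X)
        np.testing.assert_allclose(s.inverse(s.transform(X)), X, atol=1e-12)

    def test_zero_variance_dimension_passes_through(self):
        X = np.column_stack([np.full(20, 3.0), np.arange(20.0)])
        s = Standardizer.fit(X)
        Z = s.transform(X)
        np.testing.assert_array_equal(Z[:, 0], 0.0)
        np.testing.assert_allclose(s.inverse(Z), X, atol=1e-12)


class TestTrainOLS:
    def test_recovers_exact_linear_map(self):
        """Noise-free y = Ax + b is recovered to 1e-8."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 126))
        A = rng.normal(size=(126, 48))
        b = rng.normal(size=48)
        data = make_dataset(X, X @ A + b)
        model = train_ols(data)
        np.testing.assert_allclose(model.predict(X), X @ A + b, atol=1e-8)

    def test_zero_targets_predict_zero(self):
        data = make_dataset(np.random.default_rng(0).normal(size=(200, 126)), np.zeros((200, 48)))
        model = train_ols(data)
        np.testing.assert_allclose(model.predict(data.X), 0.0, atol=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            train_ols(random_dataset(50))

    def test_rank_deficient_design_warns_and_solves(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 126))
        X[:, 1] = X[:, 0]  # duplicated feature
        data = make_dataset(X, rng.normal(size=(200, 48)))
        with pytest.warns(UserWarning, match="rank"):
            model = train_ols(data)
        assert np.all(np.isfinite(model.predict(X)))


class TestNetworks:
    def test_mlp_zero_targets_near_zero_predictions(self):
        data = make_dataset(np.random.default_rng(0).uniform(size=(150, 126)), np.zeros((150, 48)))
        model = train_mlp(data, seed=0)
        assert np.abs(model.predict(data.X)).mean() < 1e-3

    def test_ffnn_zero_targets_near_zero_predictions(self):
        data = make_dataset(np.random.default_rng(0).uniform(size=(150, 126)), np.zeros((150, 48)))
        model = train_ffnn(data, seed=0, epochs=50)
        assert np.abs(model.predict(data.X)).mean() < 1e-3

    def test_mlp_forward_pass_matches_sklearn(self):
        """Extracted weights reproduce MLPRegressor.predict bit-for-bit."""
        data = random_dataset(300, seed=6)
        model = train_mlp(data, seed=7)
        xs, ys = model.x_standardizer, model.y_standardizer
        net = MLPRegressor(hidden_layer_sizes=(48, 48), random_state=7)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net.fit(xs.transform(data.X), ys.transform(data.Y))
        np.testing.assert_allclose(
            model.predict(data.X), ys.inverse(net.predict(xs.transform(data.X))), atol=1e-12
        )

    def test_training_determinism(self):
        data = random_dataset(200, seed=8)
        a = train_ffnn(data, seed=3, epochs=20)
        b = train_ffnn(data, seed=3, epochs=20)
        for (Wa, ba), (Wb, bb) in zip(a.layers, b.layers):
            np.testing.assert_array_equal(Wa, Wb)
            np.testing.assert_array_equal(ba, bb)

    def test_ffnn_input_not_zscored_and_mlp_is(self):
        data = random_dataset(200, seed=9)
        ff = train_ffnn(data, seed=0, epochs=5)
        mlp = train_mlp(data, seed=0)
        assert ff.x_standardizer is None and ff.fourier_map is not None
        assert mlp.x_standardizer is not None and mlp.fourier_map is None

    @pytest.mark.parametrize("bad", [{"learning_rate": 0.0}, {"scale": -0.5}])
    def test_invalid_hyperparameters_rejected(self, bad):
        with pytest.raises(ValueError):
            train_ffnn(random_dataset(140), **bad)


class TestGridSearch:
    def test_single_cell_grid_returns_that_point(self):
        data = random_dataset(240, seed=10)
        best, table = grid_search([0.01], [0.3], data, seed=0, epochs=5)
        assert best == (0.01, 0.3)
        assert len(table) == 1

    def test_table_has_one_row_per_cell(self):
        data = random_dataset(240, seed=11)
        best, table = grid_search([0.01, 0.001], [0.1, 0.5], data, seed=0, epochs=3)
        assert len(table) == 4
        assert (best[0], best[1]) in {(lr, s) for lr in (0.01, 0.001) for s in (0.1, 0.5)}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search([], [0.1], random_dataset(240), seed=0)


class _GroundTruth:
    """Stub surrogate that returns the dataset's own targets."""

    kind = "oracle"

    def __init__(self, data: EncodedDataset):
        self._lookup = {tuple(x): y for x, y in zip(data.X, data.Y)}

    def predict(self, X):
        return np.stack([self._lookup[tuple(x)] for x in np.atleast_2d(X)])


class TestEvaluate:
    def test_perfect_model_has_zero_mae(self, tiny_split):
        model = _GroundTruth(tiny_split.validation)
        report = evaluate(model, tiny_split.validation, depth=65.0)
        assert report.mae == 0.0 and report.tip_mae == 0.0

    def test_sample_order_invariance(self, tiny_split):
        data = tiny_split.validation
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n_samples)
        shuffled = EncodedDataset(data.X[perm], data.Y[perm], data.trajectory_id[perm])
        model = train_ols(tiny_split.train) if tiny_split.train.n_samples > 127 else None
        assert model is not None
        a = evaluate(model, data, depth=65.0)
        b = evaluate(model, shuffled, depth=65.0)
        assert a.mae == pytest.approx(b.mae, rel=1e-12)
        assert a.tip_mae == pytest.approx(b.tip_mae, rel=1e-12)

    def test_tip_scope_scores_tip_node_only(self, tiny_split):
        model = train_ols(tiny_split.train)
        r = evaluate(model, tiny_split.validation, depth=65.0, node_scope="tip")
        assert r.mae == pytest.approx(r.tip_mae, rel=1e-12)

    def test_missing_depth_raises_naming_depth(self, tiny_split):
        model = train_ols(tiny_split.train)
        with pytest.raises(ValueError, match="999"):
            evaluate(model, tiny_split.validation, depth=999.0)

    def test_error_histogram_shape_and_clipping(self, tiny_split):
        model = train_ols(tiny_split.train)
        r = evaluate(model, tiny_split.validation, depth=65.0)
        edges, counts = r.error_histogram(bin_width=0.01, clip_count=5)
        assert counts.shape[0] == 48
        assert counts.shape[1] == edges.size - 1
        assert counts.max() <= 5
        assert np.isclose(edges[1] - edges[0], 0.01)


class TestSerialization:
    @pytest.mark.parametrize("kind", ["ols", "mlp", "ffnn"])
    def test_save_load_round_trip_predictions_identical(self, kind, tmp_path):
        data = random_dataset(200, seed=12)
        if kind == "ols":
            model = train_ols(data)
        elif kind == "mlp":
            model = train_mlp(data, seed=1)
        else:
            model = train_ffnn(data, seed=1, epochs=5)
        path = tmp_path / f"{kind}.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.kind == kind
        np.testing.assert_array_equal(loaded.predict(data.X), model.predict(data.X))
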