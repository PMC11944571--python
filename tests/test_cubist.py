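import numpy as np
import pytest

from chlorospec import (
    TreeConfig,
    fit_committees,
    fit_cubist,
    fit_model_tree,
    grid_search_cubist,
    nn_correct,
    predict_committees,
    predict_tree,
)


def piecewise(rng, n=200, noise=0.0):
    """Slope +1 below x = 0, slope -1 above; the canonical kink."""
    x = rng.uniform(-1, 1, (n, 1))
    y = np.where(x.ravel() < 0, x.ravel(), -x.ravel())
    if noise:
        y = y + noise * rng.normal(size=n)
    return x, y


class TestModelTree:
    def test_too_few_rows_yield_single_leaf_ols(self, rng):
        X = rng.normal(size=(12, 3))
        y = X @ [1.0, -2.0, 0.5] + 3.0
        tree = fit_model_tree(X, y, TreeConfig(min_leaf=10))
        assert tree.is_leaf
        A = np.column_stack([np.ones(12), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(predict_tree(tree, X), A @ beta, atol=1e-8)

    def test_kink_found_and_fitted_accurately(self, rng):
        X, y = piecewise(rng)
        tree = fit_model_tree(X, y)
        assert not tree.is_leaf
        assert abs(tree.threshold) < 0.1
        Xt, yt = piecewise(np.random.default_rng(99))
        pred = predict_tree(tree, Xt)
        assert np.sqrt(np.mean((pred - yt) ** 2)) < 0.05

    def test_pure_noise_target_stays_depth_zero(self, rng):
        X = rng.uniform(-1, 1, (200, 3))
        y = rng.normal(size=200)
        assert fit_model_tree(X, y).depth() == 0

    def test_identical_rows_yield_single_leaf(self):
        X = np.ones((30, 4))
        y = np.linspace(0, 1, 30)
        tree = fit_model_tree(X, y)
        assert tree.is_leaf

    def test_constant_target_yields_single_leaf_predicting_it(self, rng):
        X = rng.normal(size=(30, 2))
        tree = fit_model_tree(X, np.full(30, 2.5))
        assert tree.is_leaf
        np.testing.assert_allclose(predict_tree(tree, X), 2.5, atol=1e-12)


class TestCommittees:
    def test_single_committee_equals_single_tree(self, rng):
        X, y = piecewise(rng, noise=0.05)
        trees = fit_committees(X, y, c=1)
        assert len(trees) == 1
        np.testing.assert_array_equal(
            predict_committees(trees, X), predict_tree(trees[0], X)
        )

    def test_ensemble_prediction_is_member_mean(self, rng):
        X, y = piecewise(rng, noise=0.05)
        trees = fit_committees(X, y, c=4)
        members = np.stack([predict_tree(t, X) for t in trees])
        np.testing.assert_allclose(
            predict_committees(trees, X), members.mean(axis=0), atol=1e-12
        )

    def test_more_committees_do_not_hurt_training_error(self, rng):
        X, y = piecewise(rng, noise=0.05)
        e = {}
        for c in (1, 4):
            trees = fit_committees(X, y, c)
            e[c] = np.sqrt(np.mean((predict_committees(trees, X) - y) ** 2))
        assert e[4] <= e[1] + 1e-9

    def test_committee_prefix_property(self, rng):
        X, y = piecewise(rng, noise=0.05)
        all_trees = fit_committees(X, y, c=4)
        first_two = fit_committees(X, y, c=2)
        np.testing.assert_array_equal(
            predict_tree(all_trees[1], X), predict_tree(first_two[1], X)
        )

    def test_nonpositive_committee_count_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_committees(rng.normal(size=(20, 2)), rng.normal(size=20), 0)


class TestNeighborCorrection:
    def test_zero_neighbors_leaves_prediction_unchanged(self, rng):
        X, y = piecewise(rng, noise=0.05)
        model = fit_cubist(X, y, committees=1, neighbors=0)
        Xq = rng.uniform(-1, 1, (10, 1))
        raw = predict_committees(model.trees, Xq, model.tree_config.smooth_k)
        np.testing.assert_array_equal(model.predict(Xq), raw)

    def test_training_row_query_with_full_weight_returns_its_target(self, rng):
        X, y = piecewise(rng, noise=0.05)
        model = fit_cubist(X, y, committees=1, neighbors=1, w_nn=1.0)
        pred = nn_correct(model, X[3:4], k=1)
        assert pred[0] == pytest.approx(y[3], abs=1e-10)

    def test_correction_helps_on_smooth_curvature(self, rng):
        """A coarse tree underfits y = x^2; neighbors carry the local
        residual and correct it."""
        X = rng.uniform(-1, 1, (300, 1))
        y = X.ravel() ** 2
        cfg = TreeConfig(min_leaf=60, max_depth=1)
        model = fit_cubist(X, y, committees=1, neighbors=0, cfg=cfg)
        Xt = rng.uniform(-1, 1, (200, 1))
        yt = Xt.ravel() ** 2
        raw_rmse = np.sqrt(np.mean((model.predict(Xt) - yt) ** 2))
        nn_rmse = np.sqrt(np.mean((model.predict(Xt, neighbors=10) - yt) ** 2))
        assert nn_rmse < raw_rmse

    def test_invalid_neighbor_counts_rejected(self, rng):
        X, y = piecewise(rng, n=40, noise=0.05)
        model = fit_cubist(X, y, committees=1, neighbors=0)
        for k in (-1, 41):
            with pytest.raises(ValueError):
                nn_correct(model, X[:2], k)


@pytest.fixture(scope="module")
def searched():
    rng = np.random.default_rng(7)
    X, y = piecewise(rng, n=120, noise=0.05)
    return grid_search_cubist(X, y, folds=5, seed=11), X, y


class TestGridSearch:
    def test_all_sixteen_cells_evaluated(self, searched):
        model, _, _ = searched
        assert len(model.cv_table) == 16
        assert set(model.cv_table) == {
            (c, k) for c in (2, 4, 6, 8) for k in (10, 20, 30, 40)
        }

    def test_chosen_cell_minimises_cv_rmse(self, searched):
        model, _, _ = searched
        best = model.cv_table[(model.committees, model.neighbors)]
        assert best == min(model.cv_table.values())

    def test_fold_partition_recorded_and_reproducible(self, searched):
        model, X, y = searched
        again = grid_search_cubist(X, y, folds=5, seed=11)
        assert again.cv_fold_hash == model.cv_fold_hash
        assert again.cv_table == model.cv_table
        assert (again.committees, again.neighbors) == (
            model.committees, model.neighbors,
        )

    def test_too_few_samples_rejected(self, rng):
        X, y = piecewise(rng, n=15)
        with pytest.raises(ValueError):
            grid_search_cubist(X, y, folds=10)


class TestSerialization:
    def test_model_round_trips_to_plain_json_types(self, rng):
        import json

        X, y = piecewise(rng, n=60, noise=0.05)
        model = fit_cubist(X, y, committees=2, neighbors=5)
        blob = json.dumps(model.to_dict())
        decoded = json.loads(blob)
        assert decoded["committees"] == 2
        assert len(decoded["trees"]) == 2
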