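"""Shapley attributions, permutation/Gini importance, top-k sweep."""

from itertools import combinations
from math import factorial

import numpy as np
import pytest

import stridelab as sl
from stridelab.core import GaitError
from stridelab.explain import _score_fn

# ---------------------------------------------------------------------------
# independent exhaustive Shapley oracle (naive subset enumeration)
# ---------------------------------------------------------------------------

def oracle_shapley(predict, x, background):
    """phi_j = sum_S |S|!(k-|S|-1)!/k! [v(S+j) - v(S)] with interventional v."""
    k = x.size

    def v(S):
        rows = background.copy()
        for j in S:
            rows[:, j] = x[j]
        return float(np.mean(predict(rows)))

    phi = np.zeros(k)
    for j in range(k):
        others = [i for i in range(k) if i != j]
        for r in range(k):
            for S in combinations(others, r):
                w = factorial(r) * factorial(k - r - 1) / factorial(k)
                phi[j] += w * (v(S + (j,)) - v(S))
    return phi


class _SymmetricAnd:
    """Symmetric AND-like score: f = x0 * x1 on binary features."""

    def predict_proba(self, X):
        p = np.asarray(X)[:, 0] * np.asarray(X)[:, 1]
        return np.column_stack([1 - p, p])


def _toy_tree_model(n_features=6, n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
    model = sl.fit(sl.ModelSpec("rf", seed=0, params={"n_estimators": 10}), X, y)
    return model, X


class TestShapValues:
    def test_exact_matches_exhaustive_oracle(self):
        model, X = _toy_tree_model(n_features=6)
        bg = X[:8]
        phi, base = sl.shap_values(model, X[:5], background=bg, method="exact")
        f = _score_fn(model, "auto")
        for i in range(5):
            ref = oracle_shapley(f, X[i], bg.copy())
            assert np.allclose(phi[i], ref, atol=1e-6)
        assert base == pytest.approx(float(np.mean(f(bg))), abs=1e-12)

    @pytest.mark.parametrize("method", ["exact", "sampling"])
    def test_local_accuracy_every_sample(self, method):
        model, X = _toy_tree_model(n_features=6)
        bg = X[:8]
        phi, base = sl.shap_values(model, X[:10], background=bg, method=method,
                                   n_permutations=4, seed=1)
        f = _score_fn(model, "auto")
        assert np.allclose(phi.sum(axis=1) + base, f(X[:10]), atol=1e-9)

    def test_tree_engine_local_accuracy(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        y = (X[:, 0] > 0).astype(int)
        model = sl.fit(sl.ModelSpec("xgboost", seed=0,
                                    params={"n_estimators": 20}), X, y)
        phi, base = sl.shap_values(model, X, method="tree")
        margin = model.predict(X, output_margin=True)
        assert np.allclose(phi.sum(axis=1) + base, margin, atol=1e-5)

    def test_constant_feature_zero_attribution(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        X[:, 2] = 1.7  # dummy feature
        y = (X[:, 0] > 0).astype(int)
        model = sl.fit(sl.ModelSpec("rf", seed=0, params={"n_estimators": 10}),
                       X, y)
        phi, _ = sl.shap_values(model, X[:6], background=X[:10], method="exact")
        assert np.allclose(phi[:, 2], 0.0, atol=1e-12)

    def test_symmetric_model_equal_attributions(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        phi, _ = sl.shap_values(_SymmetricAnd(), X, background=X,
                                method="exact")
        mean_abs = np.abs(phi).mean(axis=0)
        assert mean_abs[0] == pytest.approx(mean_abs[1], abs=1e-12)

    def test_sampling_deterministic_under_seed(self):
        model, X = _toy_tree_model()
        p1, _ = sl.shap_values(model, X[:3], method="sampling",
                               n_permutations=4, seed=7)
        p2, _ = sl.shap_values(model, X[:3], method="sampling",
                               n_permutations=4, seed=7)
        assert np.array_equal(p1, p2)


class TestPermutationImportance:
    def test_ignored_feature_zero_drop(self):
        class OnlyFirst:
            def predict(self, X):
                return (np.asarray(X)[:, 0] > 0).astype(int)

        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        drops = sl.permutation_importance(OnlyFirst(), X, y, n_repeats=5, seed=0)
        assert drops[1] == 0.0 and drops[2] == 0.0
        assert drops[0] == pytest.approx(0.5, abs=0.1)

    def test_deterministic_under_seed(self):
        model, X = _toy_tree_model()
        y = model.predict(X)
        d1 = sl.permutation_importance(model, X, y, n_repeats=3, seed=2)
        d2 = sl.permutation_importance(model, X, y, n_repeats=3, seed=2)
        assert np.array_equal(d1, d2)

    def test_invalid_repeats_rejected(self):
        model, X = _toy_tree_model()
        with pytest.raises(GaitError):
            sl.permutation_importance(model, X, model.predict(X), n_repeats=0)


def _dominant_dataset(seed, n_per_class=12, n_features=8):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    X[y == 1, 0] += 3.0          # dominant feature
    X[y == 1, 1:] += 0.5         # weak background effects
    return X, y


class TestFoldAveragedRanking:
    def test_dominant_feature_ranks_first(self):
        first = 0
        for seed in range(10):
            X, y = _dominant_dataset(seed)
            cv = sl.lopo_cv(X, y, sl.ModelSpec("rf", seed=0), select_k=6)
            rank = sl.fold_averaged_ranking(cv, X, y, method="shap",
                                            n_permutations=4)
            first += rank.index[0] == 0
        assert first >= 9

    def test_methods_agree_on_dominant_feature(self):
        X, y = _dominant_dataset(1)
        cv = sl.lopo_cv(X, y, sl.ModelSpec("rf", seed=0), select_k=6)
        tops = {m: sl.fold_averaged_ranking(cv, X, y, method=m,
                                            n_permutations=4).index[0]
                for m in ("gini", "permutation", "shap")}
        assert set(tops.values()) == {0}

    def test_equal_scores_rank_by_index(self):
        X, y = _dominant_dataset(2)
        cv = sl.lopo_cv(X, y, sl.ModelSpec("rf", seed=0), select_k=4)

        # force equal (zero) scores: permutation importance of a model that
        # ignores every feature
        class Ignore:
            def predict(self, X_):
                return np.zeros(len(X_), dtype=int)

        for i in range(cv.n_folds):
            cv.fold_models[i] = Ignore()
        rank = sl.fold_averaged_ranking(cv, X, y, method="permutation")
        assert list(rank.index) == sorted(rank.index)

    def test_efficiency_links_accuracy_and_attribution(self):
        """Total attribution mass is positive whenever CV beats chance."""
        X, y = _dominant_dataset(3)
        cv = sl.lopo_cv(X, y, sl.ModelSpec("rf", seed=0), select_k=6)
        se = 0.5 / np.sqrt(len(y))
        if cv.accuracy > 0.5 + 2 * se:
            rank = sl.fold_averaged_ranking(cv, X, y, method="shap",
                                            n_permutations=4)
            assert rank["score"].sum() > 0


class TestTopKSweep:
    def test_full_k_reproduces_full_feature_accuracy(self):
        X, y = _dominant_dataset(4)
        spec = sl.ModelSpec("rf", seed=0)
        full = sl.lopo_cv(X, y, spec, select_k=None)
        sweep = sl.topk_sweep(X, y, np.arange(X.shape[1]), (X.shape[1],),
                              (spec,))
        assert sweep.accuracy("rf", X.shape[1]) == pytest.approx(full.accuracy)

    def test_dominant_feature_alone_is_sufficient(self):
        X, y = _dominant_dataset(5)
        spec = sl.ModelSpec("rf", seed=0)
        cv = sl.lopo_cv(X, y, spec, select_k=8)
        rank = sl.fold_averaged_ranking(cv, X, y, method="shap",
                                        n_permutations=4)
        sweep = sl.topk_sweep(X, y, rank.index.to_numpy(), (1, 8), (spec,))
        assert sweep.accuracy("rf", 1) >= sweep.accuracy("rf", 8) - 0.05

    def test_table_shape(self):
        X, y = _dominant_dataset(6)
        specs = (sl.ModelSpec("rf", seed=0), sl.ModelSpec("svm-linear", seed=0))
        sweep = sl.topk_sweep(X, y, np.arange(X.shape[1]), (2, 3), specs)
        assert sweep.table.shape == (2, 2)

    def test_k_beyond_ranking_rejected(self):
        X, y = _dominant_dataset(7)
        with pytest.raises(GaitError):
            sl.topk_sweep(X, y, np.arange(3), (4,), (sl.ModelSpec("rf"),))


class TestDependence:
    def test_monotone_model_monotone_attributions(self):
        class Linear:
            def predict_proba(self, X):
                p = 1 / (1 + np.exp(-np.asarray(X)[:, 0]))
                return np.column_stack([1 - p, p])

        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 3))
        phi, _ = sl.shap_values(Linear(), X, background=X, method="exact")
        table = sl.dependence_table(0, X, phi)
        assert (np.diff(table["attribution"].to_numpy()) >= -1e-9).all()
        thr = sl.sign_change_threshold(table)
        assert thr is not None and abs(thr) < 1.0

    def test_constant_feature_no_threshold(self):
        X = np.ones((10, 2))
        phi = np.zeros((10, 2))
        table = sl.dependence_table(1, X, phi)
        assert (table["attribution"] == 0).all()
        assert sl.sign_change_threshold(table) is None

    def test_unknown_feature_rejected(self):
        with pytest.raises(GaitError):
            sl.dependence_table(5, np.ones((4, 2)), np.zeros((4, 2)))
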