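"""Model explanation: Gini, permutation, and Shapley feature importance.

Shapley attributions are computed against an interventional value function:
the payoff of a coalition S for a sample x is the model score with the
features in S taken from x and the rest marginalised over a background
sample, ``v_x(S) = mean_z f(x_S, z_{~S})``.  Three engines are available:

``exact``
    Full subset enumeration; exponential in the number of features, used up
    to ``max_exact`` features.  Satisfies all Shapley axioms exactly.
``sampling``
    Antithetic permutation sampling.  Each permutation's contributions
    telescope, so the efficiency (local-accuracy) identity
    ``sum_j phi_ij + base = f(x_i)`` holds exactly for any number of draws;
    individual attributions converge with the number of permutations.
``tree``
    XGBoost's native TreeSHAP contributions (margin / log-odds scale),
    used automatically for boosted-tree models.

Gini importance is the impurity-decrease importance built into the tree
ensembles; permutation importance is the mean accuracy drop over seeded
shuffles of one feature column at a time.  Per-fold importances from
leave-one-pair-out CV are averaged into a single ranking; retraining on the
top-k ranked features over a grid of k reproduces the accuracy-versus-k
sweep used to pick compact marker panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .classify import CVResult, ModelSpec, lopo_cv
from .core import GaitError

__all__ = ["shap_values", "permutation_importance", "fold_averaged_ranking",
           "importance_report", "topk_sweep", "TopKSweep", "dependence_table",
           "sign_change_threshold"]


def _score_fn(model, scale: str = "auto"):
    """A callable mapping (n, k) feature rows to 1-d model scores.

    ``scale='margin'`` uses the decision function / log-odds where the model
    provides one; ``'probability'`` uses the positive-class probability;
    ``'auto'`` prefers probability and falls back to the margin.
    """
    is_xgb = isinstance(model, XGBClassifier)
    if scale == "margin":
        if is_xgb:
            return lambda X: model.predict(np.asarray(X), output_margin=True)
        if hasattr(model, "decision_function"):
            return lambda X: np.asarray(model.decision_function(X), dtype=float)
        scale = "probability"
    if hasattr(model, "predict_proba"):
        return lambda X: model.predict_proba(np.asarray(X))[:, 1]
    if hasattr(model, "decision_function"):
        return lambda X: np.asarray(model.decision_function(X), dtype=float)
    raise GaitError("model exposes neither predict_proba nor decision_function")


def _coalition_values(f, x: np.ndarray, background: np.ndarray,
                      subsets: list[tuple]) -> np.ndarray:
    """v_x(S) for every subset in one batched model call."""
    k = x.size
    B = background.shape[0]
    rows = np.tile(background, (len(subsets), 1))
    for si, S in enumerate(subsets):
        if S:
            rows[si * B:(si + 1) * B, list(S)] = x[list(S)]
    scores = f(rows)
    return scores.reshape(len(subsets), B).mean(axis=1)


def _shap_exact(f, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    n, k = X.shape
    feats = range(k)
    subsets = [S for r in range(k + 1) for S in combinations(feats, r)]
    pos = {S: i for i, S in enumerate(subsets)}
    weights = {r: 1.0 / (k * comb(k - 1, r)) for r in range(k)}
    phi = np.zeros((n, k))
    for i in range(n):
        v = _coalition_values(f, X[i], background, subsets)
        for j in feats:
            for S in subsets:
                if j in S:
                    continue
                w = weights[len(S)]
                phi[i, j] += w * (v[pos[tuple(sorted(S + (j,)))]] - v[pos[S]])
    return phi

def _shap_sampling(f, X: np.ndarray, background: np.ndarray,
                   n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    n, k = X.shape
    phi = np.zeros((n, k))
    perms = []
    for _ in range(max(n_permutations // 2, 1)):
        p = rng.permutation(k)
        perms.extend([p, p[::-1]])  # antithetic pair
    for i in range(n):
        acc = np.zeros(k)
        for p in perms:
            prefixes = [tuple()] + [tuple(p[:r + 1]) for r in range(k)]
            v = _coalition_values(f, X[i], background, prefixes)
            acc[p] += np.diff(v)
        phi[i] = acc / len(perms)
    return phi


def shap_values(model, X: np.ndarray, background: np.ndarray | None = None,
                scale: str = "auto", method: str = "auto", max_exact: int = 12,
                n_permutations: int = 16, seed: int = 0
                ) -> tuple[np.ndarray, float]:
    """Per-sample, per-feature Shapley attributions and the base value.

    Returns ``(phi, base)`` with ``phi`` of shape ``(n_samples, n_features)``
    such that ``phi[i].sum() + base`` equals the model score of sample i on
    the chosen scale (exactly for the exact and sampling engines, to within
    float tolerance for the tree engine).

    Parameters
    ----------
    model
        Fitted classifier with ``predict_proba`` or ``decision_function``.
    X
        Samples to explain.
    background
        Reference sample the withheld features are drawn from; defaults to
        ``X`` itself.
    scale : {"auto", "probability", "margin"}
    method : {"auto", "exact", "sampling", "tree"}
        "auto" picks TreeSHAP for XGBoost models, exact enumeration up to
        ``max_exact`` features and permutation sampling beyond.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if method == "auto":
        if isinstance(model, XGBClassifier) and scale in ("auto", "margin"):
            method = "tree"
        else:
            method = "exact" if k <= max_exact else "sampling"

    if method == "tree":
        if not isinstance(model, XGBClassifier):
            raise GaitError("tree engine supports XGBoost models only")
        import xgboost as xgb
        booster = model.get_booster()
        contrib = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        return contrib[:, :-1], float(contrib[0, -1])

    background = X if background is None else np.atleast_2d(
        np.asarray(background, dtype=float))
    f = _score_fn(model, scale)
    base = float(np.mean(f(background)))
    if method == "exact":
        if k > max_exact:
            raise GaitError(f"exact enumeration limited to {max_exact} features")
        phi = _shap_exact(f, X, background)
    elif method == "sampling":
        rng = np.random.default_rng(seed)
        phi = _shap_sampling(f, X, background, n_permutations, rng)
    else:
        raise GaitError(f"unknown shap method {method!r}")
    return phi, base


def permutation_importance(model, X: np.ndarray, y: np.ndarray,
                           n_repeats: int = 10, seed: int = 0) -> np.ndarray:
    """Mean accuracy drop per feature over seeded column shuffles."""
    if n_repeats < 1:
        raise GaitError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    baseline = np.mean(model.predict(X) == y)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        accs = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            accs.append(np.mean(model.predict(Xp) == y))
        drops[j] = baseline - np.mean(accs)
    return drops


def _fold_importance(model, X_tr: np.ndarray, y_tr: np.ndarray, method: str,
                     seed: int, shap_kwargs: dict) -> np.ndarray:
    if method == "gini":
        if not hasattr(model, "feature_importances_"):
            raise GaitError("Gini importance needs a tree-ensemble model")
        return np.asarray(model.feature_importances_, dtype=float)
    if method == "permutation":
        return permutation_importance(model, X_tr, y_tr, seed=seed)
    if method == "shap":
        phi, _ = shap_values(model, X_tr, seed=seed, **shap_kwargs)
        return np.abs(phi).mean(axis=0)
    raise GaitError(f"unknown importance method {method!r}")


def fold_averaged_ranking(cv: CVResult, X: np.ndarray, y: np.ndarray,
                          method: str = "shap", seed: int = 0,
                          **shap_kwargs) -> pd.DataFrame:
    """Importance scores averaged over CV folds, as a ranked table.

    Each fold's importance is computed on that fold's training subjects and
    selected features; a feature's mean is taken over the folds in which it
    was evaluated.  The result is sorted by descending mean score with ties
    broken by ascending feature index.

    Returns
    -------
    DataFrame indexed by (0-based) feature column index with columns
    ``score`` and ``n_folds``.
    """
    if cv.n_folds == 0:
        raise GaitError("CV result has no folds")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    total = np.zeros(X.shape[1])
    count = np.zeros(X.shape[1])
    for (test_idx, _, _), feat, model in zip(cv.fold_predictions,
                                             cv.fold_features, cv.fold_models):
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        scores = _fold_importance(model, X[train_idx][:, feat], y[train_idx],
                                  method, seed, shap_kwargs)
        total[feat] += scores
        count[feat] += 1
    evaluated = count > 0
    mean = np.full(X.shape[1], np.nan)
    mean[evaluated] = total[evaluated] / count[evaluated]
    df = pd.DataFrame({"score": mean, "n_folds": count.astype(int)})
    df = df[evaluated]
    order = np.lexsort((df.index.to_numpy(), -df["score"].to_numpy()))
    return df.iloc[order]


def importance_report(cv: CVResult, X: np.ndarray, y: np.ndarray,
                      methods: tuple = ("gini", "permutation", "shap"),
                      seed: int = 0, **shap_kwargs) -> pd.DataFrame:
    """Fold-averaged Gini/permutation/Shapley scores side by side."""
    frames = {}
    for m in methods:
        r = fold_averaged_ranking(cv, X, y, method=m, seed=seed,
                                  **(shap_kwargs if m == "shap" else {}))
        frames[m] = r["score"]
    return pd.DataFrame(frames).sort_index()


@dataclass
class TopKSweep:
    """Mean LOPO-CV accuracy over a (model family, k) grid."""

    table: pd.DataFrame  # index: k, columns: model family

    def accuracy(self, family: str, k: int) -> float:
        return float(self.table.loc[k, family])


def topk_sweep(X: np.ndarray, y: np.ndarray, ranking: np.ndarray,
               ks: tuple, specs: tuple) -> TopKSweep:
    """Retrain on the top-k ranked features for each k and model family.

    ``ranking`` is an ordered array of feature column indices (most
    important first); each cell of the result is the mean LOPO-CV accuracy
    of that model family using exactly the top-k features (no further
    selection inside folds).
    """
    ranking = np.asarray(ranking, dtype=int)
    if max(ks) > ranking.size:
        raise GaitError(f"k={max(ks)} exceeds the ranking length {ranking.size}")
    X = np.asarray(X, dtype=float)
    cols = {}
    for spec in specs:
        accs = []
        for k in ks:
            cv = lopo_cv(X[:, ranking[:k]], y, spec, select_k=None)
            accs.append(cv.accuracy)
        cols[spec.family] = accs
    return TopKSweep(pd.DataFrame(cols, index=pd.Index(list(ks), name="k")))


def dependence_table(feature: int, X: np.ndarray,
                     phi: np.ndarray) -> pd.DataFrame:
    """(feature value, attribution) pairs sorted by feature value."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if not 0 <= feature < X.shape[1]:
        raise GaitError(f"unknown feature column {feature}")
    order = np.argsort(X[:, feature], kind="stable")
    return pd.DataFrame({"value": X[order, feature],
                         "attribution": phi[order, feature]})


def sign_change_threshold(table: pd.DataFrame) -> float | None:
    """Feature value where attributions cross zero, or None.

    Reported as the midpoint of the first adjacent pair of samples (sorted
    by feature value) whose attributions have strictly opposite signs.
    """
    att = table["attribution"].to_numpy()
    val = table["value"].to_numpy()
    sign = np.sign(att)
    nz = sign != 0
    s, v = sign[nz], val[nz]
    crossings = np.flatnonzero(s[:-1] * s[1:] < 0)
    if crossings.size == 0:
        return None
    i = crossings[0]
    return float(0.5 * (v[i] + v[i + 1]))
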