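"""Shapley additive attributions for fitted regressors.

Three routes, all additive (per-row attributions plus the base value equal
the model prediction):

- sklearn decision-tree ensembles: exact *interventional* Shapley values
  computed in closed form against a background sample.  For a single tree
  leaf, the features on its root-to-leaf path split into those whose
  constraints only the explained row satisfies (set U, size u) and those
  only the background row satisfies (set V, size v); the leaf is reached by
  a feature coalition S iff U ⊆ S and S ∩ V = ∅, which gives the classical
  closed-form weights ``(u-1)! v! / (u+v)!`` for members of U and
  ``-u! (v-1)! / (u+v)!`` for members of V.  Summing leaf contributions
  over trees and averaging over the background yields exact Shapley values
  of the interventional game.
- xgboost / lightgbm: the libraries' native per-feature contribution
  predictions (``pred_contribs`` / ``pred_contrib``).
- anything else: seeded permutation-sampling estimate (exact in the limit;
  additivity holds by telescoping for every sampled permutation).
"""

from __future__ import annotations

from math import factorial

import numpy as np

from .errors import ValidationError

try:  # optional gradient-boosting backends
    import xgboost as _xgb
except ImportError:  # pragma: no cover
    _xgb = None
try:
    import lightgbm as _lgb
except ImportError:  # pragma: no cover
    _lgb = None


# ---------------------------------------------------------------------------
# tree route

def _leaf_paths(tree):
    """Per-leaf path constraints of one sklearn tree, padded to equal depth.

    Returns (feat, low, high, value, is_real) where ``feat`` is (L, d) with
    -1 padding and each distinct feature appears once per path with its
    interval (low, high]; ``value`` is the leaf prediction.
    """
    t = tree.tree_
    leaves = []

    def walk(node, constraints):
        f = t.feature[node]
        if f < 0:  # leaf
            leaves.append((dict(constraints), float(t.value[node, 0, 0])))
            return
        thr = t.threshold[node]
        low, high = constraints.get(f, (-np.inf, np.inf))
        constraints[f] = (low, min(high, thr))
        walk(t.children_left[node], constraints)
        constraints[f] = (max(low, thr), high)
        walk(t.children_right[node], constraints)
        if low == -np.inf and high == np.inf:
            del constraints[f]
        else:
            constraints[f] = (low, high)

    walk(0, {})
    d_max = max(1, max(len(c) for c, _ in leaves))
    L = len(leaves)
    feat = np.full((L, d_max), -1, dtype=np.int64)
    low = np.full((L, d_max), -np.inf)
    high = np.full((L, d_max), np.inf)
    value = np.empty(L)
    for li, (constraints, val) in enumerate(leaves):
        for k, (f, (lo, hi)) in enumerate(constraints.items()):
            feat[li, k] = f
            low[li, k] = lo
            high[li, k] = hi
        value[li] = val
    return feat, low, high, value


def _weight_tables(d_max: int):
    """W+[u, v] = (u-1)! v! / (u+v)!  and  W-[u, v] = u! (v-1)! / (u+v)!."""
    wpos = np.zeros((d_max + 2, d_max + 2))
    wneg = np.zeros((d_max + 2, d_max + 2))
    for u in range(d_max + 2):
        for v in range(d_max + 2):
            if u >= 1:
                wpos[u, v] = factorial(u - 1) * factorial(v) / factorial(u + v)
            if v >= 1:
                wneg[u, v] = factorial(u) * factorial(v - 1) / factorial(u + v)
    return wpos, wneg


def _iter_trees(model):
    """Yield (tree, weight) pairs so the weighted sum equals the prediction."""
    if hasattr(model, "estimators_"):  # forest: prediction = mean of trees
        trees = list(model.estimators_)
        return [(t, 1.0 / len(trees)) for t in trees]
    if hasattr(model, "tree_"):
        return [(model, 1.0)]
    raise ValidationError(f"not an sklearn tree model: {type(model).__name__}")


def tree_shap_values(model, X, background) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values for an sklearn tree/forest.

    Returns ``(phi, base)`` with ``phi`` of shape (n_rows, n_features) and
    ``base`` the mean model prediction over the background sample, so that
    ``phi.sum(1) + base == model.predict(X)`` up to float round-off.
    """
    X = np.asarray(X, dtype=float)
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    if X.ndim == 1:
        X = X[None, :]
    n, p = X.shape
    m = len(Z)
    phi = np.zeros((n, p))

    for tree, weight in _iter_trees(model):
        feat, low, high, value = _leaf_paths(tree)
        L, d = feat.shape
        wpos, wneg = _weight_tables(d)
        padded = feat < 0
        feat_safe = np.where(padded, 0, feat)
        # background satisfaction per (z, leaf, path slot); pads always pass
        z_ok = (Z[:, feat_safe] > low[None]) & (Z[:, feat_safe] <= high[None])
        z_ok |= padded[None]
        for i in range(n):
            x_ok = (X[i, feat_safe] > low) & (X[i, feat_safe] <= high) | padded
            only_x = x_ok[None] & ~z_ok          # (m, L, d)
            only_z = ~x_ok[None] & z_ok
            dead = ~x_ok[None] & ~z_ok
            valid = ~dead.any(axis=2)            # (m, L)
            u = only_x.sum(axis=2)
            v = only_z.sum(axis=2)
            coef = np.where(valid, value[None, :], 0.0)
            contrib = (
                only_x * (coef * wpos[u, v])[:, :, None]
                - only_z * (coef * wneg[u, v])[:, :, None]
            ).sum(axis=0) / m                    # (L, d)
            contrib[padded] = 0.0
            np.add.at(phi[i], feat_safe.ravel(), weight * contrib.ravel())

    base = float(np.mean(model.predict(Z)))
    return phi, base


# ---------------------------------------------------------------------------
# sampling route

def sampling_shap_values(predict_fn, X, background, n_permutations: int = 256,
                         seed: int = 0) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley estimate for arbitrary regressors.

    For each sampled permutation a background row is drawn and features are
    switched from background to explained values in permutation order; the
    marginal prediction changes are credited to the switched feature.
    Additivity to the empirical base value is exact by telescoping.
    """
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    n, p = X.shape
    phi = np.zeros((n, p))
    base_acc = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(p)
        z = Z[rng.integers(len(Z))]
        hybrids = np.empty((p + 1, n, p))
        hybrids[0] = np.broadcast_to(z, (n, p))
        current = np.broadcast_to(z, (n, p)).copy()
        for step, f in enumerate(order, start=1):
            current = current.copy()
            current[:, f] = X[:, f]
            hybrids[step] = current
        preds = predict_fn(hybrids.reshape(-1, p)).reshape(p + 1, n)
        base_acc += preds[0]
        for step, f in enumerate(order, start=1):
            phi[:, f] += preds[step] - preds[step - 1]
    phi /= n_permutations
    base = float(np.mean(base_acc / n_permutations))
    return phi, base


# ---------------------------------------------------------------------------
# dispatch

def shap_values(model, X, background=None, seed: int = 0,
                n_permutations: int = 256) -> tuple[np.ndarray, float]:
    """Attribution matrix and base value for any supported regressor.

    ``background`` defaults to ``X`` itself (global explanations on the
    data being explained); pass the training sample for out-of-sample
    explanations.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(X) == 0:
        raise ValidationError("cannot explain an empty data matrix")
    Z = X if background is None else np.atleast_2d(np.asarray(background, dtype=float))

    if _xgb is not None and isinstance(model, _xgb.XGBRegressor):
        contrib = model.get_booster().predict(_xgb.DMatrix(X), pred_contribs=True)
        return contrib[:, :-1], float(contrib[0, -1])
    if _lgb is not None and isinstance(model, _lgb.LGBMRegressor):
        contrib = model.predict(X, pred_contrib=True)
        return contrib[:, :-1], float(contrib[0, -1])
    if hasattr(model, "tree_") or (
        hasattr(model, "estimators_")
        and len(getattr(model, "estimators_", []))
        and hasattr(model.estimators_[0], "tree_")
    ):
        return tree_shap_values(model, X, Z)
    return sampling_shap_values(model.predict, X, Z, n_permutations=n_permutations, seed=seed)
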