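"""Exact Shapley attributions for tree-ensemble and linear classifiers.

For sklearn random forests the per-tree game is decomposed leaf by leaf:
conditioning a feature subset S fixes the path splits on S (indicators) and
marginalises the rest by training cover fractions, so each leaf contributes
a product game whose Shapley values follow from a symmetric-polynomial
recursion over the distinct features on its root-to-leaf path (the
path-dependent treatment). Attributions are on the probability scale and
satisfy local accuracy exactly: base value + row sum = predict_proba.

LightGBM models delegate to the booster's built-in per-prediction
contributions (raw log-odds scale); elastic-net logistic models use the
closed form ``phi_i = w_i (x_i - E[x_i])`` on the decision-function scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression


@dataclass
class AttributionMatrix:
    """Per-dyad, per-feature Shapley values plus the model's base value.

    ``output_scale`` names the space the attributions live in:
    ``probability`` (random forest), ``log_odds`` (LightGBM raw score) or
    ``margin`` (logistic decision function).
    """

    values: pd.DataFrame  # rows = dyads, columns = features
    base_value: float
    output_scale: str
    model_output: np.ndarray  # f(x) per row, on the same scale

    def local_accuracy_gap(self) -> np.ndarray:
        """Per-row |base + sum(attributions) - model output|."""
        recon = self.base_value + self.values.to_numpy().sum(axis=1)
        return np.abs(recon - self.model_output)


def _leaf_paths(tree):
    """DFS over one sklearn tree: yield (leaf_id, steps).

    Each step is ``(feature, threshold, go_left, cover_fraction)`` with the
    cover fraction taken from weighted training sample counts.
    """
    left, right = tree.children_left, tree.children_right
    feat, thr = tree.feature, tree.threshold
    w = tree.weighted_n_node_samples
    out = []
    stack = [(0, [])]
    while stack:
        node, steps = stack.pop()
        if left[node] == -1:
            out.append((node, steps))
            continue
        for child, go_left in ((left[node], True), (right[node], False)):
            frac = w[child] / w[node]
            stack.append((child, steps + [(feat[node], thr[node], go_left, frac)]))
    return out


def _tree_shapley(tree, X: np.ndarray, class_index: int) -> tuple[np.ndarray, float]:
    """Shapley values of one tree's class probability for every row of X."""
    n, m = X.shape
    phi = np.zeros((n, m))
    base = 0.0
    values = tree.value  # (n_nodes, 1, n_classes), normalized per node
    for leaf, steps in _leaf_paths(tree):
        v = values[leaf][0]
        v = v[class_index] / v.sum()
        if not steps:  # stump: constant tree
            base += v
            continue
        # group path steps by feature: a_f per-sample indicator product,
        # b_f scalar cover product
        a_by_f: dict[int, np.ndarray] = {}
        b_by_f: dict[int, float] = {}
        for f, t, go_left, frac in steps:
            ind = (X[:, f] <= t) if go_left else (X[:, f] > t)
            ind = ind.astype(float)
            if f in a_by_f:
                a_by_f[f] *= ind
                b_by_f[f] *= frac
            else:
                a_by_f[f] = ind
                b_by_f[f] = frac
        feats = list(a_by_f)
        p = len(feats)
        base += v * float(np.prod(list(b_by_f.values())))
        # E_k: elementary symmetric polynomial over (a_f x + b_f) factors,
        # coefficient vectors over samples
        E = [np.ones(n)] + [np.zeros(n) for _ in range(p)]
        for f in feats:
            a, b = a_by_f[f], b_by_f[f]
            for k in range(len(E) - 1, 0, -1):
                E[k] = E[k - 1] * a + E[k] * b
            E[0] = E[0] * b
        # per feature: unwind (polynomial division), then weighted sum
        coefs = np.array([1.0 / (comb(p - 1, k) * p) for k in range(p)])
        for f in feats:
            a, b = a_by_f[f], b_by_f[f]
            e_prev = E[0] / b
            acc = coefs[0] * e_prev
            for k in range(1, p):
                e_prev = (E[k] - e_prev * a) / b
                acc = acc + coefs[k] * e_prev
            phi[:, f] += v * (a - b) * acc
    return phi, base


def forest_shapley(model: RandomForestClassifier, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Average exact per-tree Shapley values over a fitted forest."""
    phi = np.zeros_like(X, dtype=float)
    base = 0.0
    for est in model.estimators_:
        p, b = _tree_shapley(est.tree_, X, class_index=1)
        phi += p
        base += b
    k = len(model.estimators_)
    return phi / k, base / k


def shapley_attributions(
    model,
    X: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray | None = None,
) -> AttributionMatrix:
    """Exact per-prediction Shapley attributions for a supported model.

    ``background`` (linear models only) supplies the reference distribution
    whose mean defines the base value; it defaults to ``X`` itself. Tree
    models carry their background implicitly in training-cover fractions.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(Xv.shape[1])]

    if isinstance(model, RandomForestClassifier):
        phi, base = forest_shapley(model, Xv)
        output = model.predict_proba(Xv)[:, 1]
        scale = "probability"
    elif isinstance(model, LGBMClassifier):
        contrib = model.predict(Xv, pred_contrib=True)
        phi, base_col = contrib[:, :-1], contrib[:, -1]
        base = float(base_col[0])
        output = model.predict(Xv, raw_score=True)
        scale = "log_odds"
    elif isinstance(model, LogisticRegression):
        bg = Xv if background is None else np.asarray(background, dtype=float)
        mean = bg.mean(axis=0)
        w = model.coef_[0]
        phi = w * (Xv - mean)
        base = float(w @ mean + model.intercept_[0])
        output = model.decision_function(Xv)
        scale = "margin"
    else:
        raise TypeError(
            f"unsupported model family {type(model).__name__}; "
            "exact attributions cover random forest, LightGBM and logistic models"
        )
    return AttributionMatrix(
        values=pd.DataFrame(phi, columns=names),
        base_value=float(base),
        output_scale=scale,
        model_output=np.asarray(output, dtype=float),
    )
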