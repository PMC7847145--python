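"""Exact path-dependent Shapley values for sklearn tree ensembles.

For each tree and each feature subset S, the conditional expectation
E[f(x) | x_S] is evaluated by walking the tree: at a split on a feature in
S the branch chosen by x is followed; at a split on any other feature both
children are taken, weighted by their training-sample fractions.  Shapley
attributions then follow from the classic weighted sum over all subsets not
containing the feature,

    phi_j(x) = sum_S |S|! (m - |S| - 1)! / m!  [ v(S u {j}) - v(S) ].

Subset enumeration is exponential in the number of features, which is exact
and fast for the small SNP panels this pipeline analyses (a guard rejects
m > 14).  The model output attributed is the predicted probability of the
positive class; attributions per sample satisfy local additivity
(sum_j phi_j + E[f] = f(x)), which the test suite checks directly.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np

from .errors import InvalidArgumentError

_MAX_EXACT_FEATURES = 14


def _tree_arrays(decision_tree):
    t = decision_tree.tree_
    value = t.value.reshape(t.node_count, -1)
    # classifier: value rows are per-class sample (or weighted) counts
    totals = value.sum(axis=1, keepdims=True)
    prob1 = np.where(totals > 0, value[:, -1:] / np.where(totals > 0, totals, 1), 0.0)
    return (
        t.feature,
        t.threshold,
        t.children_left,
        t.children_right,
        t.weighted_n_node_samples,
        prob1.ravel(),
    )


def _conditional_expectation(arrays, X: np.ndarray, in_subset: np.ndarray) -> np.ndarray:
    """E[f(x) | x_S] for every row of X, one sklearn tree."""
    feature, threshold, left, right, weight, prob1 = arrays
    n = X.shape[0]
    out = np.zeros(n)

    # iterative stack of (node, row-index array, path weight array)
    stack = [(0, np.arange(n), np.ones(n))]
    while stack:
        node, rows, w = stack.pop()
        f = feature[node]
        if f < 0:  # leaf
            np.add.at(out, rows, w * prob1[node])
            continue
        if in_subset[f]:
            go_left = X[rows, f] <= threshold[node]
            if go_left.any():
                stack.append((left[node], rows[go_left], w[go_left]))
            if (~go_left).any():
                stack.append((right[node], rows[~go_left], w[~go_left]))
        else:
            wl = weight[left[node]] / weight[node]
            stack.append((left[node], rows, w * wl))
            stack.append((right[node], rows, w * (1.0 - wl)))
    return out


def tree_shap_values(model, X: np.ndarray) -> np.ndarray:
    """Per-sample, per-feature Shapley attributions for a fitted forest.

    Returns an ``(n, m)`` array; the attributed output is the mean over
    trees of the positive-class probability, matching
    ``model.predict_proba(X)[:, 1]`` for sklearn random forests.
    """
    if not hasattr(model, "estimators_"):
        if hasattr(model, "tree_"):
            estimators = [model]
        else:
            raise InvalidArgumentError(
                f"{type(model).__name__} is not a fitted tree model/ensemble"
            )
    else:
        estimators = model.estimators_
    X = np.asarray(X, dtype=np.float64)
    n, m = X.shape
    if m > _MAX_EXACT_FEATURES:
        raise InvalidArgumentError(
            f"exact Shapley enumeration limited to {_MAX_EXACT_FEATURES} features, got {m}"
        )
    phi = np.zeros((n, m))
    for est in estimators:
        arrays = _tree_arrays(est)
        used = set(arrays[0][arrays[0] >= 0].tolist())
        used_list = sorted(used)
        mu = len(used_list)
        # only features the tree actually splits on matter; others get 0 and
        # the subset lattice shrinks to 2^mu
        v: dict[int, np.ndarray] = {}
        for r in range(mu + 1):
            for subset in combinations(used_list, r):
                mask = np.zeros(m, dtype=bool)
                mask[list(subset)] = True
                key = sum(1 << j for j in subset)
                v[key] = _conditional_expectation(arrays, X, mask)
        for j in used_list:
            others = [f for f in used_list if f != j]
            for r in range(mu):
                for subset in combinations(others, r):
                    key = sum(1 << q for q in subset)
                    # absent features contribute no marginal value, so the
                    # Shapley weight over the full m features telescopes to
                    # the weight over the used features only
                    phi[:, j] += _shap_weight(r, mu) * (v[key | (1 << j)] - v[key])
    return phi / len(estimators)


def _shap_weight(s: int, m_used: int) -> float:
    return factorial(s) * factorial(m_used - s - 1) / factorial(m_used)


def expected_value(model, X: np.ndarray) -> float:
    """Base value: mean positive-class probability with no features known."""
    if hasattr(model, "estimators_"):
        estimators = model.estimators_
    else:
        estimators = [model]
    X = np.asarray(X, dtype=np.float64)
    base = 0.0
    for est in estimators:
        arrays = _tree_arrays(est)
        base += _conditional_expectation(
            arrays, X[:1], np.zeros(X.shape[1], dtype=bool)
        )[0]
    return base / len(estimators)
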