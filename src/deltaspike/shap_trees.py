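"""Shapley additive explanations for tree ensembles (path-dependent TreeSHAP).

Computes exact Shapley values of a decision tree's prediction under the
path-dependent conditional expectation: when a feature is "absent", the tree
is descended into both children weighted by their training sample counts.
For a forest, per-tree attributions are averaged, mirroring how the forest
averages tree probabilities, so the additivity property holds for the
ensemble: for every sample, sum(phi) + expected_value == predict_proba.

``brute_force_shap`` evaluates the same quantity by explicit enumeration of
feature subsets (exponential in the number of features used by the tree) and
serves as an independent correctness oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np


@dataclass
class _Tree:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray  # per-node positive-class probability
    weight: np.ndarray  # weighted_n_node_samples


def _extract_tree(estimator) -> _Tree:
    t = estimator.tree_
    raw = t.value[:, 0, :]
    totals = raw.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    frac = raw / totals
    value = frac[:, 1] if raw.shape[1] > 1 else frac[:, 0]
    return _Tree(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        value=value.astype(float),
        weight=t.weighted_n_node_samples.astype(float),
    )


def tree_expected_value(tree: _Tree) -> float:
    """Training-weighted mean leaf value (the model's base value)."""
    leaves = tree.children_left < 0
    return float(
        (tree.value[leaves] * tree.weight[leaves]).sum() / tree.weight[0]
    )


# ---------------------------------------------------------------------------
# Path-dependent TreeSHAP
# ---------------------------------------------------------------------------
# The "unique path" m is a list of [feature, zero_fraction, one_fraction,
# pweight] entries; extend/unwind maintain the permutation weights as the
# recursion descends the tree.


def _extend(m: list, pz: float, po: float, pi: int) -> list:
    m = [e.copy() for e in m]
    l = len(m)
    m.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l - 1, -1, -1):
        m[i + 1][3] += po * m[i][3] * (i + 1) / (l + 1)
        m[i][3] = pz * m[i][3] * (l - i) / (l + 1)
    return m


def _unwind(m: list, i: int) -> list:
    l = len(m) - 1
    one = m[i][2]
    zero = m[i][1]
    out = [e.copy() for e in m]
    n = out[l][3]
    if one != 0:
        for j in range(l - 1, -1, -1):
            t = out[j][3]
            out[j][3] = n * (l + 1) / ((j + 1) * one)
            n = t - out[j][3] * zero * (l - j) / (l + 1)
    else:
        for j in range(l - 1, -1, -1):
            out[j][3] = out[j][3] * (l + 1) / (zero * (l - j))
    for j in range(i, l):
        out[j][0], out[j][1], out[j][2] = out[j + 1][0], out[j + 1][1], out[j + 1][2]
    return out[:l]


def _unwound_sum(m: list, i: int) -> float:
    l = len(m) - 1
    one = m[i][2]
    zero = m[i][1]
    total = 0.0
    if one != 0:
        n = m[l][3]
        for j in range(l - 1, -1, -1):
            t = n * (l + 1) / ((j + 1) * one)
            total += t
            n = m[j][3] - t * zero * (l - j) / (l + 1)
    else:
        for j in range(l - 1, -1, -1):
            total += m[j][3] * (l + 1) / (zero * (l - j))
    return total


def _recurse(
    tree: _Tree,
    x: np.ndarray,
    phi: np.ndarray,
    node: int,
    m: list,
    pz: float,
    po: float,
    pi: int,
) -> None:
    m = _extend(m, pz, po, pi)
    if tree.children_left[node] < 0:  # leaf
        for i in range(1, len(m)):
            w = _unwound_sum(m, i)
            phi[m[i][0]] += w * (m[i][2] - m[i][1]) * tree.value[node]
        return
    d = tree.feature[node]
    left, right = tree.children_left[node], tree.children_right[node]
    hot, cold = (left, right) if x[d] <= tree.threshold[node] else (right, left)
    w = tree.weight[node]
    hot_z = tree.weight[hot] / w
    cold_z = tree.weight[cold] / w

    inc_z, inc_o = 1.0, 1.0
    k = next((j for j in range(1, len(m)) if m[j][0] == d), None)
    if k is not None:
        inc_z, inc_o = m[k][1], m[k][2]
        m = _unwind(m, k)
    _recurse(tree, x, phi, hot, m, hot_z * inc_z, inc_o, d)
    _recurse(tree, x, phi, cold, m, cold_z * inc_z, 0.0, d)


def tree_shap_values(tree_or_estimator, X: np.ndarray) -> np.ndarray:
    """Shapley values of the positive-class probability of one tree.

    Returns (n_samples, n_features).
    """
    tree = (
        tree_or_estimator
        if isinstance(tree_or_estimator, _Tree)
        else _extract_tree(tree_or_estimator)
    )
    X = np.atleast_2d(np.asarray(X, dtype=float))
    phi = np.zeros_like(X)
    for s in range(X.shape[0]):
        _recurse(tree, X[s], phi[s], 0, [], 1.0, 1.0, -1)
    return phi


def forest_shap_values(clf, X: np.ndarray) -> np.ndarray:
    """Average per-tree Shapley values of a fitted sklearn forest."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    trees = [_extract_tree(e) for e in clf.estimators_]
    phi = np.zeros_like(X, dtype=float)
    for tree in trees:
        phi += tree_shap_values(tree, X)
    return phi / len(trees)


def forest_expected_value(clf) -> float:
    return float(
        np.mean([tree_expected_value(_extract_tree(e)) for e in clf.estimators_])
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _conditional_expectation(tree: _Tree, x: np.ndarray, known: frozenset) -> float:
    """E[f(x) | x_S] under the path-dependent convention: absent features
    descend into both children weighted by training sample counts."""

    def walk(node: int) -> float:
        if tree.children_left[node] < 0:
            return tree.value[node]
        d = tree.feature[node]
        left, right = tree.children_left[node], tree.children_right[node]
        if d in known:
            nxt = left if x[d] <= tree.threshold[node] else right
            return walk(nxt)
        wl = tree.weight[left] / tree.weight[node]
        wr = tree.weight[right] / tree.weight[node]
        return wl * walk(left) + wr * walk(right)

    return walk(0)


def brute_force_shap(tree_or_estimator, x: np.ndarray) -> np.ndarray:
    """Exact Shapley values by subset enumeration (exponential; tests only)."""
    tree = (
        tree_or_estimator
        if isinstance(tree_or_estimator, _Tree)
        else _extract_tree(tree_or_estimator)
    )
    x = np.asarray(x, dtype=float)
    used = sorted(set(tree.feature[tree.feature >= 0].tolist()))
    M = len(used)
    phi = np.zeros(x.size)
    for i in used:
        rest = [f for f in used if f != i]
        for r in range(M):
            for subset in combinations(rest, r):
                S = frozenset(subset)
                w = factorial(r) * factorial(M - r - 1) / factorial(M)
                gain = _conditional_expectation(
                    tree, x, S | {i}
                ) - _conditional_expectation(tree, x, S)
                phi[i] += w * gain
    return phi
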