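"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle is a deliberately naive re-derivation of a quantity the library
computes by a different algorithm, so agreement is a genuine cross-check.
"""
from __future__ import annotations

import numpy as np


def circular_moving_average(x: np.ndarray, level: int) -> np.ndarray:
    """Causal circular 2^level-point moving average by direct summation."""
    x = np.asarray(x, dtype=float)
    t_len = x.size
    window = 2**level
    out = np.empty(t_len)
    for t in range(t_len):
        out[t] = sum(x[(t - l) % t_len] for l in range(window)) / window
    return out


def allpairs_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by counting all positive/negative pairs, ties worth one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def _sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0


def _naive_best_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (delta_sse, threshold) by evaluating every midpoint directly."""
    best = None
    values = np.unique(x)
    parent = _sse(y)
    for lo, hi in zip(values[:-1], values[1:]):
        thr = (lo + hi) / 2.0
        left = x < thr
        if left.sum() < min_leaf or (~left).sum() < min_leaf:
            continue
        delta = parent - _sse(y[left]) - _sse(y[~left])
        if best is None or delta > best[0] + 1e-12:
            best = (delta, thr)
    return best


def exhaustive_depth2_tree(x, y, complexity: float, min_leaf: int,
                           max_depth: int = 2):
    """Depth-2 SSE tree by exhaustive scan over all candidate cuts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 * min_leaf:
        return []
    root_sse = _sse(y)
    if root_sse <= 0:
        return []
    min_gain = complexity * root_sse
    root = _naive_best_split(x, y, min_leaf)
    if root is None or root[0] < min_gain:
        return []
    thresholds = [root[1]]
    if max_depth >= 2:
        left = x < root[1]
        for mask in (left, ~left):
            child = _naive_best_split(x[mask], y[mask], min_leaf)
            if child is not None and child[0] >= min_gain:
                thresholds.append(child[1])
    return sorted(thresholds)
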