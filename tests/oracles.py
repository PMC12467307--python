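"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as literal loops over the defining
formulas, independent of the vectorised implementations under test.
"""

from __future__ import annotations

import math

import numpy as np


def deboor_basis(knots: np.ndarray, i: int, k: int, t: float) -> float:
    """Cox-de Boor recursion for the i-th B-spline basis of degree k."""
    if k == 0:
        # half-open spans, closing the final one at the right edge
        if knots[i] <= t < knots[i + 1]:
            return 1.0
        if t == knots[-1] and knots[i] < knots[i + 1] == knots[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if knots[i + k] > knots[i]:
        left = (t - knots[i]) / (knots[i + k] - knots[i]) * deboor_basis(knots, i, k - 1, t)
    right = 0.0
    if knots[i + k + 1] > knots[i + 1]:
        right = (knots[i + k + 1] - t) / (knots[i + k + 1] - knots[i + 1]) \
            * deboor_basis(knots, i + 1, k - 1, t)
    return left + right


def deboor_eval(control: np.ndarray, t: float) -> float:
    """Clamped uniform cubic B-spline value by direct basis summation."""
    m = len(control)
    interior = np.linspace(0.0, 1.0, m - 2)
    knots = np.concatenate([np.zeros(3), interior, np.ones(3)])
    return sum(control[i] * deboor_basis(knots, i, 3, t) for i in range(m))


def gcn_dense_oracle(H: np.ndarray, A: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Renormalised graph convolution by explicit elementwise loops."""
    n, d_in = H.shape
    d_out = W.shape[1]
    At = A + np.eye(n)
    deg = [sum(At[i][j] for j in range(n)) for i in range(n)]
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            P[i][j] = At[i][j] / math.sqrt(deg[i]) / math.sqrt(deg[j])
    out = np.zeros((n, d_out))
    for i in range(n):
        for o in range(d_out):
            acc = 0.0
            for j in range(n):
                for f in range(d_in):
                    acc += P[i][j] * H[j][f] * W[f][o]
            out[i][o] = max(acc, 0.0)
    return out


def cooccurrence_oracle(corpus, au_ids):
    """Per-AU and pairwise counts by direct iteration."""
    n = len(au_ids)
    N = [0] * n
    N_pair = [[0] * n for _ in range(n)]
    for s in corpus:
        for i, a in enumerate(au_ids):
            if a in s:
                N[i] += 1
                for j, b in enumerate(au_ids):
                    if b in s:
                        N_pair[i][j] += 1
    return np.array(N), np.array(N_pair)


def confusion_metrics_oracle(pred, true):
    """Accuracy and macro F1 from an explicit confusion matrix."""
    labels = sorted(set(pred) | set(true))
    acc = sum(p == t for p, t in zip(pred, true)) / len(true)
    f1s = []
    for lab in labels:
        tp = sum(p == lab and t == lab for p, t in zip(pred, true))
        fp = sum(p == lab and t != lab for p, t in zip(pred, true))
        fn = sum(p != lab and t == lab for p, t in zip(pred, true))
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return acc, sum(f1s) / len(f1s)
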