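"""Batched linear SVM kernel for the searchlight.

The searchlight evaluates a leave-one-participant-out linear SVM at
every time-frequency grid point, for the observed labels and for
thousands of class-swap permutations.  scikit-learn's per-fit overhead
makes that infeasible at this volume, so the classifier is solved here
directly: an L1-loss soft-margin SVM (C = 1) in the dual by coordinate
descent (Hsieh et al. 2008), with the bias absorbed as an augmented
constant feature (Gram + 1).  Features are standardized by
training-fold statistics, which are label-independent and therefore
shared across permutations.

Predictions agree with ``sklearn.svm.SVC(kernel="linear", C=1)`` up to
decision-boundary ties (verified in the test suite).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _solve_dual(G, y, train_idx, C, tol, max_passes, f):
    """Dual coordinate descent; fills f with the decision values.

    G: (n, n) Gram matrix (already bias-augmented), y: +/-1 labels,
    train_idx: indices participating in training.  On exit f[j] =
    sum_i alpha_i y_i G[i, j] for all j (including held-out rows).
    """
    n = G.shape[0]
    alpha = np.zeros(n)
    for j in range(n):
        f[j] = 0.0
    for _ in range(max_passes):
        max_viol = 0.0
        for ii in range(train_idx.shape[0]):
            i = train_idx[ii]
            grad = y[i] * f[i] - 1.0
            # projected gradient for the box constraint [0, C]
            pg = grad
            if alpha[i] <= 0.0 and grad >= 0.0:
                pg = 0.0
            elif alpha[i] >= C and grad <= 0.0:
                pg = 0.0
            if pg != 0.0:
                if abs(pg) > max_viol:
                    max_viol = abs(pg)
                old = alpha[i]
                denom = G[i, i]
                if denom <= 1e-12:
                    denom = 1e-12
                new = old - grad / denom
                if new < 0.0:
                    new = 0.0
                elif new > C:
                    new = C
                d = (new - old) * y[i]
                if d != 0.0:
                    for j in range(n):
                        f[j] += d * G[i, j]
                    alpha[i] = new
        if max_viol < tol:
            break
    return alpha


@njit(cache=True)
def loo_fold_accuracies(Gfolds, flips, C, tol, max_passes):
    """Per-participant LOO accuracies for one label assignment.

    Gfolds: (P, 2P, 2P) bias-augmented Gram matrices, one per held-out
    participant (standardization differs per training fold).  Row layout:
    participant k occupies rows 2k (class 0) and 2k+1 (class 1).
    flips: (P,) int8; flips[k] = 1 swaps participant k's class labels.

    Returns acc: (P,) with values in {0, 0.5, 1}.  Ties on the decision
    boundary predict class 0 (fixed label order).
    """
    P = flips.shape[0]
    n = 2 * P
    acc = np.empty(P)
    y = np.empty(n)
    for k in range(P):
        s = 1.0 if flips[k] == 0 else -1.0
        y[2 * k] = s  # class 0 (unpleasant) -> +1 unless flipped
        y[2 * k + 1] = -s
    train_idx = np.empty(n - 2, dtype=np.int64)
    f = np.empty(n)
    for i in range(P):
        t = 0
        for j in range(n):
            if j != 2 * i and j != 2 * i + 1:
                train_idx[t] = j
                t += 1
        _solve_dual(Gfolds[i], y, train_idx, C, tol, max_passes, f)
        correct = 0
        for j in (2 * i, 2 * i + 1):
            pred = 1.0 if f[j] > 0.0 else -1.0  # tie -> class 0
            if pred == y[j]:
                correct += 1
        acc[i] = correct / 2.0
    return acc


def fold_grams(X: np.ndarray) -> np.ndarray:
    """Per-fold standardized, bias-augmented Gram matrices.

    X: (2P, d) feature matrix, rows ordered (participant, class).  For
    each held-out participant i, features are standardized by the mean
    and SD of the training rows (all rows except i's two), then the Gram
    of the standardized full matrix plus the bias constant is returned.
    """
    n, d = X.shape
    P = n // 2
    out = np.empty((P, n, n))
    for i in range(P):
        mask = np.ones(n, dtype=bool)
        mask[2 * i: 2 * i + 2] = False
        mu = X[mask].mean(axis=0)
        sd = X[mask].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Z = (X - mu) / sd
        out[i] = Z @ Z.T + 1.0
    return out
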