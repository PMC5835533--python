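"""Independent naive re-implementations used as test oracles.

Everything here is deliberately written from first principles — a dual
quadratic-program SVM solved with SLSQP, plain-Python leave-one-out and
permutation loops, run-length cluster scanning, textbook t statistics and
fine-grid Riemann integration — and never calls the package's own code
paths, so agreement between the two routes is informative.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import minimize


def svm_decision_function(X_train, y_train, X_test, C):
    """Soft-margin linear SVM via the dual QP, solved with SLSQP.

    maximize  sum(a) - 1/2 a^T Q a   s.t. 0 <= a <= C,  y^T a = 0
    with Q_ij = y_i y_j x_i.x_j; the bias is recovered from the
    unbounded support vectors (KKT), falling back to the midpoint rule.
    """
    X_train = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)  # +-1
    n = len(y)
    K = X_train @ X_train.T
    Q = (y[:, None] * y[None, :]) * K

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(n)

    res = minimize(
        neg_dual,
        x0=np.full(n, min(C, 1.0) / 2.0),
        jac=grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    a = np.clip(res.x, 0.0, C)
    w = (a * y) @ X_train
    margin = ~np.isclose(a, 0.0, atol=1e-8) & ~np.isclose(a, C, atol=1e-8)
    if margin.any():
        b = float(np.mean(y[margin] - X_train[margin] @ w))
    else:
        sv = a > 1e-8
        if sv.any():
            b = float(np.mean(y[sv] - X_train[sv] @ w))
        else:
            b = 0.0
    return np.asarray(X_test, dtype=float) @ w + b


def naive_loo_accuracy(X, y_pm1, C):
    """Plain leave-one-out loop with the QP oracle; one-class folds predict
    the only training label."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_pm1, dtype=float)
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            pred = y[mask][0]
        else:
            pred = np.sign(svm_decision_function(X[mask], y[mask], X[i : i + 1], C)[0])
            if pred == 0:
                pred = 1.0
        correct += pred == y[i]
    return correct / n


def naive_zscore(X):
    X = np.asarray(X, dtype=float)
    out = np.zeros_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        sd = np.sqrt(np.mean((col - col.mean()) ** 2))
        if sd > 0:
            out[:, j] = (col - col.mean()) / sd
    return out


def naive_permutation_pvalue(X, y_pm1, C):
    """Exhaustive class-size-preserving relabelling null, observed included."""
    y = np.asarray(y_pm1, dtype=float)
    n = len(y)
    n_pos = int(np.sum(y > 0))
    observed = naive_loo_accuracy(X, y, C)
    dist = []
    for pos in combinations(range(n), n_pos):
        lab = -np.ones(n)
        lab[list(pos)] = 1.0
        dist.append(naive_loo_accuracy(X, lab, C))
    dist = np.asarray(dist)
    assert len(dist) == comb(n, n_pos)
    return float(np.mean(dist >= observed - 1e-12)), dist, observed


def naive_t_two_sample(a, b):
    """Pooled-variance independent two-sample t, textbook formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def naive_cluster_scan(t_series, crit):
    """Brute-force run scanner: walk the series sample by sample."""
    clusters = []
    state, start = 0, None
    for i, t in enumerate(list(t_series) + [0.0]):  # sentinel flushes last run
        s = 1 if t > crit else (-1 if t < -crit else 0)
        if s != state:
            if state != 0:
                clusters.append((start, i - 1, float(np.sum(t_series[start:i])), state))
            state, start = s, i
    return clusters


def fine_grid_integral(waveform, times, window, oversample=100):
    """Riemann midpoint sum of the piecewise-linear interpolant on a grid
    ``oversample`` times finer than the samples."""
    w0, w1 = window
    dt = (times[1] - times[0]) / oversample
    grid = np.arange(w0, w1, dt) + dt / 2.0
    grid = grid[grid < w1]
    return float(np.sum(np.interp(grid, times, waveform)) * dt)
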