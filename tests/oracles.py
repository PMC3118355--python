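"""Independent reference implementations used to cross-check the package.

Each oracle is deliberately naive (explicit loops, closed forms) and shares
no code with the implementation path it validates.
"""

import statistics

import numpy as np


def brute_force_kde2d(points, bandwidths, eval_points):
    """Naive O(n·k) double-loop product-Gaussian KDE."""
    h_a, h_m = bandwidths
    out = []
    n = len(points)
    for x, y in eval_points:
        total = 0.0
        for a, m in points:
            za = (x - a) / h_a
            zm = (y - m) / h_m
            total += np.exp(-0.5 * za * za) * np.exp(-0.5 * zm * zm)
        out.append(total / (n * h_a * h_m * 2.0 * np.pi))
    return np.asarray(out)


def oracle_weighted_loess(x, y, prior_w, span, x0s):
    """Per-point weighted least squares on the k nearest points.

    Neighbourhoods found by sorting distances (boundary ties included); the
    local line is solved through the 2×2 normal equations.
    """
    n = len(x)
    k = int(np.ceil(span * n))
    out = []
    for x0 in x0s:
        d = np.abs(x - x0)
        d_sorted = np.sort(d)
        d_max = d_sorted[k - 1]
        sel = d <= d_max
        xw, yw, pw, dw = x[sel], y[sel], prior_w[sel], d[sel]
        if d_max == 0:
            out.append(np.average(yw, weights=pw))
            continue
        w = (1 - (dw / d_max) ** 3) ** 3 * pw
        if w.sum() <= 0:
            w = pw
        X = np.column_stack([np.ones(len(xw)), xw])
        A = X.T @ (w[:, None] * X)
        b = X.T @ (w * yw)
        if np.linalg.matrix_rank(A) < 2:
            out.append(np.average(yw, weights=w))
            continue
        beta = np.linalg.solve(A, b)
        out.append(beta[0] + beta[1] * x0)
    return np.asarray(out)


def oracle_median_polish(x, tol=1e-6, max_iter=10):
    """Sweep-by-sweep Tukey median polish with explicit Python loops."""
    x = [list(map(float, row)) for row in x]
    nr, nc = len(x), len(x[0])
    overall, row, col = 0.0, [0.0] * nr, [0.0] * nc
    old = sum(abs(v) for r in x for v in r)
    for _ in range(max_iter):
        for i in range(nr):
            md = statistics.median(x[i])
            for j in range(nc):
                x[i][j] -= md
            row[i] += md
        d = statistics.median(col)
        col = [c - d for c in col]
        overall += d
        for j in range(nc):
            md = statistics.median(x[i][j] for i in range(nr))
            for i in range(nr):
                x[i][j] -= md
            col[j] += md
        d = statistics.median(row)
        row = [r - d for r in row]
        overall += d
        new = sum(abs(v) for r in x for v in r)
        if abs(old - new) <= tol:
            break
        old = new
    return overall, row, col, x


def mann_whitney_auc(score, is_de):
    """Pairwise-comparison U statistic: ties earn half credit."""
    pos = np.asarray(score)[np.asarray(is_de)]
    neg = np.asarray(score)[~np.asarray(is_de)]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
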