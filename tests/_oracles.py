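"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (double loops, literal formulas) and
shares no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_neighbor_counts(points: np.ndarray, threshold: float):
    """O(n^2) double-loop neighbor counts and unordered pair count."""
    n = len(points)
    counts = [0] * n
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = points[i][0] - points[j][0]
            dy = points[i][1] - points[j][1]
            if (dx * dx + dy * dy) ** 0.5 <= threshold:
                counts[i] += 1
                counts[j] += 1
                pairs += 1
    return np.array(counts), pairs


def cr1_sandwich_se(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Cluster-robust (CR1) standard errors, coded from the sandwich formula.

    V = c * (X'X)^-1 [ sum_g X_g' u_g u_g' X_g ] (X'X)^-1,
    c = G/(G-1) * (N-1)/(N-k).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    u = y - X @ beta
    labels = np.unique(groups)
    meat = np.zeros((k, k))
    for g in labels:
        m = groups == g
        s = X[m].T @ u[m]
        meat += np.outer(s, s)
    G = len(labels)
    c = (G / (G - 1.0)) * ((n - 1.0) / (n - k))
    V = c * xtx_inv @ meat @ xtx_inv
    return np.sqrt(np.diag(V))


def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """Simple-regression slope/intercept/R^2 straight from the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    fitted = intercept + slope * x
    rss = ((y - fitted) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1.0 - rss / tss


def quantile_type7(values, q: float) -> float:
    """Type-7 quantile computed by explicit sorting and interpolation."""
    v = sorted(values)
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] + frac * (v[hi] - v[lo])


def sort_and_chunk_binscatter(x, y, n_bins: int):
    """Binned means by explicit sort and near-equal chunking."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    base, extra = divmod(len(x), n_bins)
    xs, ys, cs = [], [], []
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        idx = order[start : start + size]
        xs.append(float(np.mean([x[i] for i in idx])))
        ys.append(float(np.mean([y[i] for i in idx])))
        cs.append(size)
        start += size
    return np.array(xs), np.array(ys), np.array(cs)


def krippendorff_interval_literal(a, b) -> float:
    """Literal coincidence-matrix Krippendorff alpha, interval metric.

    Builds the full coincidence matrix over observed values with nested
    loops, then alpha = 1 - D_o / D_e.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    vals = sorted(set(a) | set(b))
    idx = {v: i for i, v in enumerate(vals)}
    V = len(vals)
    o = np.zeros((V, V))
    for ai, bi in zip(a, b):
        # unit with 2 ratings: each ordered pair once, divided by (m_u - 1) = 1
        o[idx[ai], idx[bi]] += 1
        o[idx[bi], idx[ai]] += 1
    n_c = o.sum(axis=1)
    n = n_c.sum()
    d_o = 0.0
    for c in range(V):
        for k in range(V):
            d_o += o[c, k] * (vals[c] - vals[k]) ** 2
    d_o /= n
    d_e = 0.0
    for c in range(V):
        for k in range(V):
            d_e += n_c[c] * n_c[k] * (vals[c] - vals[k]) ** 2
    d_e /= n * (n - 1)
    return 1.0 - d_o / d_e
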