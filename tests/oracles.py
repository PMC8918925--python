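"""Independent naive reference implementations used only as test oracles.

These deliberately take a different computational route from the
package (explicit loops, cdist, rfft, exhaustive enumeration) so that
agreement is evidence of correctness, not of shared code.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, log, log2

import numpy as np
from scipy.spatial.distance import cdist


def time_domain_loop(x):
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    sq = [(x[i + 1] - x[i]) ** 2 for i in range(n - 1)]
    return mean, var**0.5, (sum(sq) / len(sq)) ** 0.5


def relrr_loop(rr):
    return [100.0 * rr[i + 1] / rr[i] for i in range(len(rr) - 1)]


def prsa_loop(rr, direction, L=2, anchor_limit=0.20):
    rr = list(map(float, rr))
    anchors = []
    for i in range(1, len(rr)):
        ratio = rr[i] / rr[i - 1]
        if direction == "decel" and not ratio > 1.0:
            continue
        if direction == "accel" and not ratio < 1.0:
            continue
        if abs(ratio - 1.0) > anchor_limit:
            continue
        if i - L < 0 or i + L > len(rr) - 1:
            continue
        anchors.append(i)
    if not anchors:
        return float("nan")
    def X(k):
        return sum(rr[i + k] for i in anchors) / len(anchors)
    return (X(0) + X(1) - X(-1) - X(-2)) / 4.0


def shannon_loop(x, n_bins=16):
    x = list(map(float, x))
    lo, hi = min(x), max(x)
    if lo == hi:
        return 0.0
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in x:
        k = min(int((v - lo) / width), n_bins - 1)
        counts[k] += 1
    n = len(x)
    return -sum(c / n * log2(c / n) for c in counts if c > 0)


def sampen_cdist(x, m=2, r_factor=0.2):
    """Sample entropy via scipy cdist with the Chebyshev metric."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = np.std(x, ddof=1)
    if sd == 0:
        return 0.0
    r = r_factor * sd
    n_t = n - m
    if n_t < 2:
        return float("nan")
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_t]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_t]
    b = int((cdist(tm, tm, "chebyshev") <= r).sum()) - n_t
    a = int((cdist(tm1, tm1, "chebyshev") <= r).sum()) - n_t
    if a <= 0 or b <= 0:
        return float("nan")
    return -log(a / b)


def sampen_pure_loop(x, m=2, r_factor=0.2):
    x = list(map(float, x))
    n = len(x)
    sd = (sum((v - sum(x) / n) ** 2 for v in x) / (n - 1)) ** 0.5
    r = r_factor * sd
    n_t = n - m
    a = b = 0
    for i in range(n_t):
        for j in range(n_t):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a <= 0 or b <= 0:
        return float("nan")
    return -log(a / b)


def specen_rfft(x):
    """Normalised spectral entropy from a one-sided rfft periodogram."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    X = np.fft.rfft(x)
    P = np.abs(X) ** 2
    # one-sided scaling: double everything except DC and (if n even) Nyquist
    scale = np.full(P.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    P = P * scale
    P = P[1:]
    total = P.sum()
    if total <= 0:
        return float("nan")
    p = P / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() / np.log2(P.size))


def pearson_loop(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((a[i] - ma) * (b[i] - mb) for i in range(n))
    va = sum((v - ma) ** 2 for v in a)
    vb = sum((v - mb) ** 2 for v in b)
    return cov / (va * vb) ** 0.5


def confusion_recount(y_true, y_pred):
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if p == 1 and t == 1:
            tp += 1
        elif p == 1 and t == 0:
            fp += 1
        elif p == 0 and t == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def ranksum_exact_p(pos, neg):
    """Exact one-tailed (pos stochastically lower) rank-sum p-value by
    full enumeration; assumes no ties across groups."""
    pooled = sorted(list(pos) + list(neg))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in pos)
    n = len(pooled)
    n1 = len(pos)
    count = 0
    total = 0
    all_ranks = list(range(1, n + 1))
    for c in combinations(all_ranks, n1):
        total += 1
        if sum(c) <= obs:
            count += 1
    return count / total


def shapley_brute(value_fn, n_features):
    """Exact Shapley values of an arbitrary set function by enumeration."""
    phi = [0.0] * n_features
    full = list(range(n_features))
    for j in full:
        others = [i for i in full if i != j]
        for size in range(len(others) + 1):
            w = 1.0 / (n_features * comb(n_features - 1, size))
            for S in combinations(others, size):
                phi[j] += w * (value_fn(set(S) | {j}) - value_fn(set(S)))
    return phi


def tree_coalition_value(tree, x, background, S):
    """v(S): mean over background rows of the tree's positive-class
    probability with features in S taken from x."""
    vals = []
    pos_col = list(tree.classes_).index(1)
    for z in background:
        hybrid = np.array(z, dtype=float)
        for j in S:
            hybrid[j] = x[j]
        vals.append(tree.predict_proba(hybrid.reshape(1, -1))[0, pos_col])
    return float(np.mean(vals))
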