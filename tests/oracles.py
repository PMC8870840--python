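"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles — direct enumeration
over joint tables, exhaustive neighbour searches — and deliberately
shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_entropy_family(counts: np.ndarray) -> dict[str, float]:
    """H(X), H(Y), H(X|Y), H(Y|X), IG, GR, SU by cell-wise enumeration."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    hx = 0.0
    for row in counts:
        px = row.sum() / n
        if px > 0:
            hx -= px * math.log2(px)
    hy = 0.0
    for col in counts.T:
        py = col.sum() / n
        if py > 0:
            hy -= py * math.log2(py)
    hx_given_y = 0.0
    for x in range(counts.shape[0]):
        for y in range(counts.shape[1]):
            pxy = counts[x, y] / n
            py = counts[:, y].sum() / n
            if pxy > 0:
                hx_given_y -= pxy * math.log2(pxy / py)
    hy_given_x = 0.0
    for x in range(counts.shape[0]):
        for y in range(counts.shape[1]):
            pxy = counts[x, y] / n
            px = counts[x, :].sum() / n
            if pxy > 0:
                hy_given_x -= pxy * math.log2(pxy / px)
    ig = hx - hx_given_y
    return {
        "hx": hx, "hy": hy, "hx_given_y": hx_given_y, "hy_given_x": hy_given_x,
        "ig": ig,
        "gr": ig / hx if hx > 0 else float("nan"),
        "su": 2 * ig / (hx + hy) if hx + hy > 0 else float("nan"),
    }


def mutual_information(counts: np.ndarray) -> float:
    """Σ p(x,y) log2 [p(x,y) / (p(x)p(y))] — the symmetric identity."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    px = counts.sum(axis=1) / n
    py = counts.sum(axis=0) / n
    mi = 0.0
    for x in range(counts.shape[0]):
        for y in range(counts.shape[1]):
            pxy = counts[x, y] / n
            if pxy > 0:
                mi += pxy * math.log2(pxy / (px[x] * py[y]))
    return mi


def pair_distance(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    diffs = [abs(ai - bi) for ai, bi in zip(a, b)]
    if metric == "euclidean":
        return math.sqrt(sum(d * d for d in diffs))
    if metric == "chebyshev":
        return max(diffs)
    if metric == "manhattan":
        return sum(diffs)
    raise ValueError(metric)


def brute_knn(train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray,
              k: int, metric: str) -> np.ndarray:
    """Exhaustive k-NN with the documented tie rules: neighbour ties by
    ascending train index, vote ties by smallest summed distance then
    lowest class code."""
    preds = []
    for t in test_X:
        dists = [(pair_distance(t, x, metric), i) for i, x in enumerate(train_X)]
        dists.sort()                      # (distance, index) lexicographic
        nn = dists[:k]
        votes: dict[int, int] = {}
        sums: dict[int, float] = {}
        for d, i in nn:
            c = int(train_y[i])
            votes[c] = votes.get(c, 0) + 1
            sums[c] = sums.get(c, 0.0) + d
        best = max(votes.values())
        tied = [c for c, v in votes.items() if v == best]
        tied.sort(key=lambda c: (sums[c], c))
        preds.append(tied[0])
    return np.array(preds)


def brute_relieff(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Hand-traceable ReliefF pass: every instance sampled, Manhattan
    distance on range-normalized columns, miss weights P(C)/(1-P(cls))."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    rng_span = X.max(axis=0) - X.min(axis=0)
    span = np.where(rng_span > 0, rng_span, 1.0)
    Xn = (X - X.min(axis=0)) / span
    Xn[:, rng_span == 0] = 0.0
    classes = sorted(set(int(c) for c in y))
    priors = {c: float(np.mean(y == c)) for c in classes}
    W = np.zeros(d)
    for i in range(n):
        ci = int(y[i])
        others = [(sum(abs(Xn[i] - Xn[j])), j) for j in range(n) if j != i]
        others.sort()
        hits = [j for _, j in others if y[j] == ci][:k]
        if hits:
            for f in range(d):
                W[f] -= np.mean([abs(Xn[i, f] - Xn[j, f]) for j in hits]) / n
        for c in classes:
            if c == ci:
                continue
            misses = [j for _, j in others if y[j] == c][:k]
            if misses:
                w = priors[c] / (1.0 - priors[ci])
                for f in range(d):
                    W[f] += w * np.mean(
                        [abs(Xn[i, f] - Xn[j, f]) for j in misses]) / n
    return W
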