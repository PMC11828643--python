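"""Independent brute-force oracles used to check the implementation.

These deliberately avoid every vectorized code path in floodqc: plain Python
loops over pixels, windows, and rank assignments.
"""

from itertools import combinations

import numpy as np


def brute_integral_uniformity(counts, mask):
    """Scan every in-mask pixel with a Python loop."""
    vals = [counts[i, j] for i in range(counts.shape[0]) for j in range(counts.shape[1]) if mask[i, j]]
    vmax, vmin = max(vals), min(vals)
    return 100.0 * (vmax - vmin) / (vmax + vmin)


def brute_differential_uniformity(counts, mask, axis, window=5):
    """Scan every fully in-mask window with Python loops.

    Returns (worst contrast, n_windows), or (None, 0) if no window exists.
    """
    n, m = counts.shape
    worst = None
    n_windows = 0
    if axis == "x":
        runs = ((i, j, 0, 1) for i in range(n) for j in range(m - window + 1))
    else:
        runs = ((i, j, 1, 0) for i in range(n - window + 1) for j in range(m))
    for i, j, di, dj in runs:
        cells = [(i + k * di, j + k * dj) for k in range(window)]
        if not all(mask[r, c] for r, c in cells):
            continue
        vals = [counts[r, c] for r, c in cells]
        contrast = 100.0 * (max(vals) - min(vals)) / (max(vals) + min(vals))
        n_windows += 1
        if worst is None or contrast > worst:
            worst = contrast
    return worst, n_windows


def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def brute_mann_whitney_u(a, b):
    """U for group a via pairwise comparison counting (ties count 1/2)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def exact_permutation_p(a, b):
    """Exact two-sided p of the U statistic by enumerating all C(n, n_a)
    assignments of the pooled midranks to group a."""
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    n_a = len(a)
    mu = n_a * len(b) / 2.0
    offset = n_a * (n_a + 1) / 2.0
    u_obs = sum(ranks[: n_a]) - offset
    stat_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        u = sum(ranks[i] for i in idx) - offset
        if abs(u - mu) >= stat_obs - 1e-12:
            count += 1
        total += 1
    return count / total
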