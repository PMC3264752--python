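"""Independent brute-force oracles used to verify the pipeline's algorithms.

Everything here is deliberately naive — exhaustive enumeration and direct
textbook formulas — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# gated partial matching (tracking oracle)
# ---------------------------------------------------------------------------

def brute_force_matching(
    points_a: np.ndarray, points_b: np.ndarray, gate: float
) -> tuple[int, float]:
    """Best gated partial matching by exhaustive enumeration.

    Returns ``(cardinality, cost)`` of the matching that is maximal in
    cardinality among all gated one-to-one partial matchings and, among
    those, minimal in summed squared displacement.
    """
    points_a = np.asarray(points_a, dtype=float)
    points_b = np.asarray(points_b, dtype=float)
    n, m = len(points_a), len(points_b)
    gate2 = gate * gate
    d2 = ((points_a[:, None, :] - points_b[None, :, :]) ** 2).sum(axis=2)

    best_card = 0
    best_cost = 0.0
    k_max = min(n, m)
    for k in range(k_max, -1, -1):
        found = False
        cost_k = math.inf
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    if d2[i, j] > gate2:
                        ok = False
                        break
                    cost += d2[i, j]
                if ok:
                    found = True
                    cost_k = min(cost_k, cost)
        if found:
            best_card = k
            best_cost = cost_k if k > 0 else 0.0
            break
    return best_card, best_cost


def matching_cost(points_a: np.ndarray, points_b: np.ndarray, pairs) -> float:
    points_a = np.asarray(points_a, dtype=float)
    points_b = np.asarray(points_b, dtype=float)
    return float(
        sum(((points_a[i] - points_b[j]) ** 2).sum() for i, j in pairs)
    )


# ---------------------------------------------------------------------------
# rank statistics (direct textbook formulas, midranks by hand)
# ---------------------------------------------------------------------------

def midranks(values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def kruskal_h(groups) -> float:
    """Tie-corrected Kruskal-Wallis H from the rank-sum formula."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        size = len(g)
        r_sum = ranks[start : start + size].sum()
        h += r_sum * r_sum / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


def kruskal_permutation_p(groups, statistic: float) -> float:
    """Exact permutation p-value of the KW statistic (total n must be small).

    Enumerates every distinct assignment of the pooled values to groups of
    the observed sizes (order within a group does not change H).
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    count = 0
    total = 0

    def recurse(remaining: tuple[int, ...], chosen: list[tuple[int, ...]]):
        nonlocal count, total
        if len(chosen) == len(sizes):
            regrouped = [pooled[list(idx)] for idx in chosen]
            total += 1
            if kruskal_h(regrouped) >= statistic - 1e-12:
                count += 1
            return
        size = sizes[len(chosen)]
        for combo in itertools.combinations(remaining, size):
            rest = tuple(i for i in remaining if i not in combo)
            recurse(rest, chosen + [combo])

    recurse(tuple(range(len(pooled))), [])
    return count / total


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """U of the first sample and the exact two-sided p by enumeration.

    Valid for tie-free data: enumerates all C(n_a+n_b, n_a) assignments of
    the pooled values to group A and counts those at least as extreme (in
    |U - mean U|) as observed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    def u_stat(x, y):
        return float(sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y))

    u_obs = u_stat(a, b)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    mean_u = n_a * len(b) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


def spearman_r(x, y) -> float:
    """Spearman r as the Pearson correlation of midranks."""
    rx = midranks(x)
    ry = midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def dunn_z(groups) -> np.ndarray:
    """Dunn pairwise z statistics from pooled midranks with tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = midranks(pooled)
    sizes = [len(g) for g in groups]
    means = []
    start = 0
    for size in sizes:
        means.append(ranks[start : start + size].mean())
        start += size
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (n - 1))
    var = n * (n + 1) / 12.0 - tie
    k = len(groups)
    z = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                se = math.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
                z[i, j] = (means[i] - means[j]) / se
    return z
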