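"""Independent brute-force oracles used to validate package computations.

Everything here is deliberately naive (enumeration / exhaustive search) and
shares no code with the package internals it checks.
"""
from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def hypergeom_one_sided_p(a: int, n1: int, b: int, n2: int) -> float:
    """P(X >= a) for X ~ Hypergeom by direct enumeration over the fixed margins.

    Table: group 1 of size n1 with `a` successes, group 2 of size n2 with `b`
    successes; total successes K = a + b drawn among N = n1 + n2.
    """
    N, K = n1 + n2, a + b
    denom = comb(N, K)
    p = 0.0
    for x in range(max(0, K - n2), min(n1, K) + 1):
        if x >= a:
            p += comb(n1, x) * comb(n2, K - x) / denom
    return p


def rank_sum_two_sided_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumeration of all group assignments."""
    x, y = list(map(float, x)), list(map(float, y))
    pooled = np.array(x + y)
    order = pooled.argsort(kind="stable")
    ranks = np.empty(len(pooled))
    # average ranks on ties
    sorted_vals = pooled[order]
    i = 0
    pos = 1
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        avg = (pos + (pos + j - i - 1)) / 2
        for k in range(i, j):
            ranks[order[k]] = avg
        pos += j - i
        i = j
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    total = hits = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= abs(w_obs - mean) - 1e-12:
            hits += 1
    return hits / total


def exhaustive_best_pair_set(vote_matrix: np.ndarray, is_scc: np.ndarray, max_size: int):
    """Best strict-majority voting subset of candidate pairs, exhaustively.

    ``vote_matrix``: (n_pairs, n_samples) boolean SCC votes.  Returns
    (best_accuracy, list of index tuples achieving it).
    """
    n_pairs = vote_matrix.shape[0]
    best_acc = -1.0
    best_sets: list[tuple[int, ...]] = []
    for size in range(1, max_size + 1):
        for idx in combinations(range(n_pairs), size):
            votes = vote_matrix[list(idx)].sum(axis=0)
            calls = votes > size / 2
            acc = float((calls == is_scc).mean())
            if acc > best_acc + 1e-12:
                best_acc = acc
                best_sets = [idx]
            elif abs(acc - best_acc) <= 1e-12:
                best_sets.append(idx)
    return best_acc, best_sets


def random_monotone_transform(rng: np.random.Generator):
    """A random strictly increasing scalar function applied elementwise."""
    a = rng.uniform(0.2, 3.0)
    b = rng.uniform(-5.0, 5.0)
    kind = rng.integers(0, 3)
    if kind == 0:
        return lambda v: a * v + b
    if kind == 1:
        return lambda v: np.exp(a * (v - b) / 10.0)
    return lambda v: a * v**3 + b  # odd power: strictly increasing on R
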