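"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the hypergeometric
oracle enumerates subsets as bitmasks, the Mann-Whitney oracle enumerates
group labelings, and the path-length oracle is networkx's BFS.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import comb

import numpy as np


@lru_cache(maxsize=None)
def _overlap_table(N: int, m: int):
    """counts[q][k] = number of q-subsets of {0..N-1} whose overlap with the
    first m elements is exactly k, by exhaustive bitmask enumeration."""
    masks = np.arange(2 ** N, dtype=np.uint32)
    bits = (masks[:, None] >> np.arange(N, dtype=np.uint32)) & 1
    sizes = bits.sum(axis=1)
    overlaps = bits[:, :m].sum(axis=1) if m > 0 else np.zeros(len(masks), dtype=int)
    table = np.zeros((N + 1, m + 1), dtype=np.int64)
    np.add.at(table, (sizes, overlaps), 1)
    return table


def hypergeom_upper_tail(k: int, N: int, m: int, q: int) -> float:
    """P(overlap >= k) over all q-subsets, by subset enumeration."""
    table = _overlap_table(N, m)
    total = comb(N, q)
    hits = int(table[q, max(k, 0):].sum())
    return hits / total


def mwu_statistic(a, b) -> float:
    """U statistic for group a (count of (a_i > b_j) pairs, untied data)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    gt = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


def mwu_exact_two_sided(a, b) -> float:
    """Two-sided p by full enumeration of all group labelings."""
    a = list(a)
    b = list(b)
    pooled = a + b
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    obs = abs(mwu_statistic(a, b) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(mwu_statistic(ga, gb) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def mwu_permutation_p(a, b, n_perm: int, seed: int) -> float:
    """Monte-Carlo permutation p for large samples."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    obs = abs(mwu_statistic(a, b) - mu)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(mwu_statistic(perm[:n1], perm[n1:]) - mu) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def bfs_path_length(graph, source, target):
    """Independent shortest-path oracle (networkx BFS); None if unreachable."""
    import networkx as nx

    try:
        return nx.shortest_path_length(graph, source, target)
    except nx.NetworkXNoPath:
        return None
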