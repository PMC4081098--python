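"""Independent brute-force oracles the tests compare the implementation against.

Everything here is written for clarity, not speed, and deliberately avoids
the code paths under test: ranking is done by pairwise comparison counts,
hypergeometric tails by combinatorial enumeration, BH by the literal
step-up definition.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_ranks_desc(column: np.ndarray) -> np.ndarray:
    """Descending competition-free ranks with average ties, by pairwise counts."""
    n = len(column)
    ranks = np.empty(n)
    for i in range(n):
        greater = sum(1 for j in range(n) if column[j] > column[i])
        equal = sum(1 for j in range(n) if column[j] == column[i])
        # average of ranks greater+1 .. greater+equal
        ranks[i] = greater + (equal + 1) / 2.0
    return ranks


def naive_rank_product(matrix: np.ndarray) -> np.ndarray:
    """Geometric mean of per-column descending ranks.

    Ranking is independent (pairwise comparison counts); the final
    geometric mean is evaluated as exp(mean(log ranks)) so that tie
    comparisons against the implementation's RP values are bit-exact.
    """
    G, K = matrix.shape
    ranks = np.column_stack([naive_ranks_desc(matrix[:, k]) for k in range(K)])
    out = np.ones(G)
    for g in range(G):
        out[g] = np.exp(np.log(ranks[g]).mean())
    return out


def naive_ranks_asc(values: np.ndarray) -> np.ndarray:
    return naive_ranks_desc(-np.asarray(values, dtype=float))


def naive_pfp(matrix: np.ndarray, n_perm: int, rng_seed: int) -> np.ndarray:
    """Permutation pfp recomputed from scratch, same permutation stream.

    The stream contract: one default_rng(rng_seed); per permutation, per
    column in order, one rng.permutation(G) reindexing that column.
    """
    G, K = matrix.shape
    rp_obs = naive_rank_product(matrix)
    rng = np.random.default_rng(rng_seed)
    exceed = np.zeros(G)
    for _ in range(n_perm):
        perm = np.empty_like(matrix)
        for k in range(K):
            perm[:, k] = matrix[rng.permutation(G), k]
        rp_null = naive_rank_product(perm)
        for g in range(G):
            exceed[g] += sum(1 for h in range(G) if rp_null[h] <= rp_obs[g])
    e_g = exceed / n_perm
    return e_g / naive_ranks_asc(rp_obs)


def enumerate_pfp_single_column(column: np.ndarray) -> np.ndarray:
    """Exact pfp for K=1 by enumerating every ordering of the column.

    With one column RP equals the rank itself, so the permutation-null RP
    values are always {1..G} and the expected count at or below rank r is
    exactly r, giving pfp = r / r = 1 for every transcript. Enumeration
    over all G! orderings verifies that identity.
    """
    G = len(column)
    ranks = naive_ranks_desc(column)
    total_leq = np.zeros(G)
    n_orderings = 0
    for perm in itertools.permutations(range(G)):
        null_ranks = naive_ranks_desc(column[list(perm)])
        n_orderings += 1
        for g in range(G):
            total_leq[g] += sum(1 for h in range(G) if null_ranks[h] <= ranks[g])
    e_g = total_leq / n_orderings
    return e_g / naive_ranks_asc(ranks)


def hypergeom_upper_tail(k: int, N: int, m: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, m, n), by direct enumeration."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(m, n) + 1):
        total += math.comb(m, j) * math.comb(N - m, n - j)
    return total / denom


def bh_stepup(p: list[float]) -> list[float]:
    """Literal Benjamini-Hochberg step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, p[i] * m / rank_from_end, 1.0)
        adj[i] = val
        prev = val
    return adj
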