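"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: itemset frequency is
computed by exhaustive bitmask enumeration of every non-empty subset of the
species universe, and the one-sided exact independence p-value by direct
summation of hypergeometric point masses via binomial coefficients.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def exhaustive_frequent_itemsets(
    transactions: list[frozenset[str]], min_support: float
) -> dict[frozenset[str], float]:
    """All itemsets with support >= min_support, by full enumeration.

    Enumerates every one of the 2^m - 1 non-empty subsets of the m observed
    species (m <= ~15) and counts containment with bitmasks.
    """
    species = sorted({sp for t in transactions for sp in t})
    m = len(species)
    index = {sp: i for i, sp in enumerate(species)}
    tmasks = np.array(
        [sum(1 << index[sp] for sp in t) for t in transactions], dtype=np.int64
    )
    n = len(transactions)
    out: dict[frozenset[str], float] = {}
    subsets = np.arange(1, 1 << m, dtype=np.int64)
    # containment: subset & transaction == subset
    counts = ((subsets[:, None] & tmasks[None, :]) == subsets[:, None]).sum(axis=1)
    for mask, count in zip(subsets, counts):
        sup = count / n
        if sup >= min_support:
            items = frozenset(sp for sp in species if (1 << index[sp]) & int(mask))
            out[items] = sup
    return out


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    lo = max(k, 0, K + n - N)
    hi = min(K, n)
    if lo > hi:
        return 0.0
    total = math.comb(N, n)
    acc = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1))
    return acc / total


def brute_force_association_pairs(
    records, distance_fn, threshold_m: float
) -> set[frozenset[str]]:
    """Unordered species pairs with at least one record pair within range."""
    pairs: set[frozenset[str]] = set()
    for a, b in combinations(records, 2):
        if a.species != b.species and distance_fn(
            (a.latitude, a.longitude), (b.latitude, b.longitude)
        ) < threshold_m:
            pairs.add(frozenset((a.species, b.species)))
    return pairs
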