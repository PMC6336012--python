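"""Level-wise Apriori mining of frequent species itemsets.

Candidates are produced by the classic apriori-gen function: frequent
k-itemsets sharing their first k-1 items (under lexicographic item order)
are joined into (k+1)-candidates, then any candidate with an infrequent
k-subset is pruned. Correctness rests on downward closure: every subset of
a frequent itemset is itself frequent.

Support is the fraction of transactions whose species set contains the
itemset; the frequency cut is inclusive (support >= min_support) by
default, configurable to strict.

Corpora here are small (at most a few hundred distinct species sets), so
transactions are collapsed to unique sets with multiplicities and no
transaction-reduction or hashing optimisations are used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import EmptyInputError

DEFAULT_MIN_SUPPORT = 0.15


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    support: float
    count: int


def _as_sets(transactions) -> list[frozenset[str]]:
    out = []
    for t in transactions:
        out.append(frozenset(t.species_set if hasattr(t, "species_set") else t))
    return out


def itemset_support(items: Iterable[str], transactions) -> tuple[int, float]:
    """Count and fraction of transactions containing every item.

    The empty itemset is contained in every transaction by convention.
    """
    tsets = _as_sets(transactions)
    if not tsets:
        raise EmptyInputError("support is undefined over zero transactions")
    iset = frozenset(items)
    count = sum(1 for t in tsets if iset <= t)
    return count, count / len(tsets)


def apriori_gen(frequent_k: Iterable[frozenset[str]]) -> set[frozenset[str]]:
    """Generate (k+1)-candidates from frequent k-itemsets (join + prune).

    All inputs must share one cardinality k >= 1; a mixed-size input is a
    contract violation and raises ValueError.
    """
    fk = [frozenset(s) for s in frequent_k]
    if not fk:
        return set()
    sizes = {len(s) for s in fk}
    if len(sizes) != 1:
        raise ValueError(f"apriori_gen requires uniform itemset size, got sizes {sorted(sizes)}")
    (k,) = sizes
    if k < 1:
        raise ValueError("apriori_gen requires itemsets of size >= 1")

    fk_set = set(fk)
    ordered = sorted(tuple(sorted(s)) for s in fk)
    candidates: set[frozenset[str]] = set()
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            if a[: k - 1] != b[: k - 1]:
                # ordered list is sorted, so later j can't share the prefix either
                break
            cand = frozenset(a) | frozenset(b)
            # prune: every k-subset must be frequent
            if all(cand - {item} in fk_set for item in cand):
                candidates.add(cand)
    return candidates


def find_frequent_itemsets(
    transactions,
    min_support: float = DEFAULT_MIN_SUPPORT,
    strict: bool = False,
) -> list[FrequentItemset]:
    """Mine all itemsets meeting the support threshold, level by level.

    Parameters
    ----------
    transactions
        Sequence of species sets (or objects exposing ``species_set``).
    min_support
        Support threshold in (0, 1].
    strict
        If True the cut is ``support > min_support`` instead of ``>=``.

    Returns
    -------
    list of FrequentItemset sorted by (size, items); exactly the itemsets of
    size >= 1 meeting the threshold.
    """
    if not (0 < min_support <= 1):
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    tsets = _as_sets(transactions)
    if not tsets:
        raise EmptyInputError("cannot mine an empty transaction list")

    n = len(tsets)
    multiplicity = Counter(tsets)

    def support_of(candidates: Iterable[frozenset[str]]) -> dict[frozenset[str], int]:
        counts: dict[frozenset[str], int] = {}
        for cand in candidates:
            c = sum(m for t, m in multiplicity.items() if cand <= t)
            counts[cand] = c
        return counts

    def keep(count: int) -> bool:
        sup = count / n
        return sup > min_support if strict else sup >= min_support

    # level 1: single species
    item_counts: Counter[str] = Counter()
    for t, m in multiplicity.items():
        for item in t:
            item_counts[item] += m
    level = {
        frozenset((item,)): c for item, c in item_counts.items() if keep(c)
    }

    frequent: list[FrequentItemset] = [
        FrequentItemset(items, c / n, c) for items, c in level.items()
    ]
    while level:
        candidates = apriori_gen(level.keys())
        if not candidates:
            break
        counts = support_of(candidates)
        level = {cand: c for cand, c in counts.items() if keep(c)}
        frequent.extend(FrequentItemset(items, c / n, c) for items, c in level.items())

    frequent.sort(key=lambda f: (len(f.items), tuple(sorted(f.items))))
    return frequent
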