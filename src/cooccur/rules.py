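"""Association-rule generation, scoring and classification.

For every frequent itemset Z with at least two species, each non-empty
proper subset A yields a candidate rule A -> Z\\A. Metrics follow the
standard market-basket definitions:

    support(A -> C)    = P(A u C)           (joint support of the itemset)
    confidence(A -> C) = support(A u C) / support(A)  = P(C | A)
    lift(A -> C)       = support(A u C) / (support(A) * support(C))

Each side of a rule is treated as a single presence/absence event over
transactions (set containment), giving a 2x2 contingency table per rule.
Two independence statistics are computed on it:

* Pearson chi-square without continuity correction (df = 1), reported for
  every rule;
* the one-sided hypergeometric upper tail P(X >= n11) with the table's
  margins fixed (the one-sided Fisher exact test). This directional
  p-value drives classification: near 0 means the two sides co-occur more
  than independence allows, near 1 means less.

A rule is *positive* when lift exceeds 1 and the directional p-value is at
most alpha; *negative* when lift is below 1 and the p-value is at least
1 - alpha; *independent* when it clears the support/confidence gates but
neither tail criterion fires; *negligible* otherwise. Degenerate tables
(a zero row or column margin, e.g. a species present in every transaction)
conventionally score chi2 = 0, p = 1, so a ubiquitous consequent can never
produce a positive rule no matter how high its lift.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from itertools import combinations
from scipy import stats

from .apriori import FrequentItemset
from .errors import EmptyInputError

LABELS = ("positive", "negative", "independent", "negligible")


@dataclass(frozen=True)
class RuleThresholds:
    """Gates and boundaries for rule emission and classification.

    ``positive_min_lift`` / ``negative_max_lift`` are the strict lift
    boundaries of the positive (lift > 1) and negative (lift < 1) regions;
    a lift of exactly 1 is never positive or negative. ``alpha`` bounds the
    directional p-value ("~0" is p <= alpha, "~1" is p >= 1 - alpha).
    """

    min_support: float = 0.15
    min_confidence: float = 0.3
    positive_min_lift: float = 1.0
    negative_max_lift: float = 1.0
    alpha: float = 0.05
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValueError(f"min_support out of (0,1]: {self.min_support}")
        if not (0 <= self.min_confidence <= 1):
            raise ValueError(f"min_confidence out of [0,1]: {self.min_confidence}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha out of (0,1): {self.alpha}")
        if self.positive_min_lift < 0 or self.negative_max_lift < 0:
            raise ValueError("lift boundaries must be non-negative")


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 presence/absence cross-tabulation of a rule's two sides."""

    N: int
    n11: int  # antecedent and consequent both present
    n10: int  # antecedent only
    n01: int  # consequent only
    n00: int  # neither

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n11 + self.n10 + self.n01 + self.n00 != self.N:
            raise ValueError("contingency counts must sum to N")

    @property
    def antecedent_total(self) -> int:
        return self.n11 + self.n10

    @property
    def consequent_total(self) -> int:
        return self.n11 + self.n01


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float
    chi2: float = float("nan")
    p_value: float = float("nan")
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("rule sides must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("rule sides must be disjoint")

    @property
    def items(self) -> frozenset[str]:
        return self.antecedent | self.consequent


def generate_candidate_rules(
    frequent: Sequence[FrequentItemset],
    thresholds: RuleThresholds = RuleThresholds(),
) -> list[AssociationRule]:
    """Split every frequent itemset of size >= 2 into confident rules.

    Antecedent and consequent supports are looked up among the frequent
    itemsets themselves (downward closure guarantees they are present).
    """
    support_by_items = {f.items: f.support for f in frequent}
    rules: list[AssociationRule] = []
    for f in frequent:
        if len(f.items) < 2:
            continue
        items = sorted(f.items)
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                antecedent = frozenset(ante)
                consequent = f.items - antecedent
                sup_a = support_by_items[antecedent]
                sup_c = support_by_items[consequent]
                confidence = f.support / sup_a
                if confidence < thresholds.min_confidence:
                    continue
                rules.append(
                    AssociationRule(
                        antecedent=antecedent,
                        consequent=consequent,
                        support=f.support,
                        confidence=confidence,
                        lift=f.support / (sup_a * sup_c),
                    )
                )
    rules.sort(
        key=lambda r: (len(r.items), tuple(sorted(r.antecedent)), tuple(sorted(r.consequent)))
    )
    return rules


def contingency_table(rule: AssociationRule, transactions) -> ContingencyCounts:
    """Cross-tabulate presence/absence of the rule's sides over transactions."""
    n11 = n10 = n01 = n00 = 0
    count = 0
    for t in transactions:
        tset = t.species_set if hasattr(t, "species_set") else t
        count += 1
        a = rule.antecedent <= tset
        c = rule.consequent <= tset
        if a and c:
            n11 += 1
        elif a:
            n10 += 1
        elif c:
            n01 += 1
        else:
            n00 += 1
    if count == 0:
        raise EmptyInputError("contingency table over zero transactions")
    return ContingencyCounts(count, n11, n10, n01, n00)


def _degenerate(c: ContingencyCounts) -> bool:
    rows = (c.n11 + c.n10, c.n01 + c.n00)
    cols = (c.n11 + c.n01, c.n10 + c.n00)
    return 0 in rows or 0 in cols


def chi_square_statistic(counts: ContingencyCounts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction, df=1) and two-sided p.

    A table with a zero row or column margin carries no information about
    association; by convention it returns (0, 1).
    """
    if _degenerate(counts):
        return 0.0, 1.0
    n11, n10, n01, n00, N = counts.n11, counts.n10, counts.n01, counts.n00, counts.N
    num = N * (n11 * n00 - n10 * n01) ** 2
    den = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    chi2 = num / den
    return chi2, float(stats.chi2.sf(chi2, df=1))


def directional_p_value(counts: ContingencyCounts) -> float:
    """One-sided upper-tail hypergeometric p-value P(X >= n11), margins fixed.

    X is the overlap of the antecedent's transactions with the consequent's
    under independence (population N, antecedent_total successes,
    consequent_total draws). Values near 0 flag positive association, near
    1 negative association; degenerate margins give p = 1 because the
    distribution collapses to a single point.
    """
    rv = stats.hypergeom(counts.N, counts.antecedent_total, counts.consequent_total)
    return float(min(1.0, rv.sf(counts.n11 - 1)))


def classify_rule(
    rule: AssociationRule,
    counts: ContingencyCounts,
    thresholds: RuleThresholds = RuleThresholds(),
    alpha: float | None = None,
) -> str:
    """Assign positive / negative / independent / negligible to a scored rule."""
    a = thresholds.alpha if alpha is None else alpha
    p = directional_p_value(counts)
    if rule.lift > thresholds.positive_min_lift and p <= a:
        return "positive"
    if rule.lift < thresholds.negative_max_lift and p >= 1.0 - a:
        return "negative"
    if rule.support >= thresholds.min_support and rule.confidence >= thresholds.min_confidence:
        return "independent"
    return "negligible"


def score_and_classify(
    rules: Sequence[AssociationRule],
    transactions,
    thresholds: RuleThresholds = RuleThresholds(),
) -> list[AssociationRule]:
    """Attach chi2, directional p-value and label to each candidate rule.

    With ``thresholds.bonferroni`` the classification alpha is divided by
    the number of candidate rules (off by default).
    """
    alpha = thresholds.alpha
    if thresholds.bonferroni and rules:
        alpha = thresholds.alpha / len(rules)
    tsets = [t.species_set if hasattr(t, "species_set") else frozenset(t) for t in transactions]
    scored = []
    for rule in rules:
        counts = contingency_table(rule, tsets)
        chi2, _ = chi_square_statistic(counts)
        p = directional_p_value(counts)
        label = classify_rule(rule, counts, thresholds, alpha=alpha)
        scored.append(replace(rule, chi2=chi2, p_value=p, label=label))
    return scored


def summarize_rules(rules: Sequence[AssociationRule], transactions) -> dict[str, pd.DataFrame]:
    """Summary tables over labeled rules and the transaction corpus.

    Returns four DataFrames keyed by name:

    ``appearances``
        per-species appearance count in positive rules;
    ``roles``
        per-species counts as antecedent vs consequent (all rules);
    ``transaction_frequency``
        per-species fraction of transactions containing it;
    ``rule_sizes``
        distribution of rule sizes (species per rule, all rules).
    """
    appearance: Counter[str] = Counter()
    ante_roles: Counter[str] = Counter()
    cons_roles: Counter[str] = Counter()
    sizes: Counter[int] = Counter()
    for rule in rules:
        if rule.label == "positive":
            for sp in rule.items:
                appearance[sp] += 1
        for sp in rule.antecedent:
            ante_roles[sp] += 1
        for sp in rule.consequent:
            cons_roles[sp] += 1
        sizes[len(rule.items)] += 1

    tsets = [t.species_set if hasattr(t, "species_set") else frozenset(t) for t in transactions]
    freq: Counter[str] = Counter()
    for tset in tsets:
        for sp in tset:
            freq[sp] += 1
    n = len(tsets)

    appearances_df = pd.DataFrame(
        sorted(appearance.items()), columns=["species", "positive_rule_appearances"]
    )
    all_role_species = sorted(set(ante_roles) | set(cons_roles))
    roles_df = pd.DataFrame(
        {
            "species": all_role_species,
            "antecedent": [ante_roles.get(s, 0) for s in all_role_species],
            "consequent": [cons_roles.get(s, 0) for s in all_role_species],
        }
    )
    freq_df = pd.DataFrame(
        {
            "species": sorted(freq),
            "transaction_fraction": [freq[s] / n if n else 0.0 for s in sorted(freq)],
        }
    )
    sizes_df = pd.DataFrame(
        sorted(sizes.items()), columns=["rule_size", "n_rules"]
    )
    return {
        "appearances": appearances_df,
        "roles": roles_df,
        "transaction_frequency": freq_df,
        "rule_sizes": sizes_df,
    }
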