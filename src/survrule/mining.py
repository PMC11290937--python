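"""Frequent-itemset mining and rule scoring on a 2x2 contingency basis.

Implements level-wise Apriori over the binary transaction matrix and, for
each antecedent -> outcome pair, the measure suite: support, confidence,
lift, cosine, the phi correlation coefficient, the (uncorrected) Pearson
chi-square statistic, and the odds ratio with a Woolf 95% confidence
interval.  All measures are pure functions of the pair's 2x2 table.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cohort import Item, TransactionMatrix

__all__ = [
    "AssociationRule",
    "ContingencyTable",
    "Itemset",
    "MiningError",
    "RuleMetrics",
    "compute_metrics",
    "contingency",
    "generate_rules",
    "mine_frequent_itemsets",
    "rules_to_jsonl",
]


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class Itemset:
    """A distinct set of items together with its support count."""

    items: frozenset[Item]
    support_count: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", frozenset(self.items))
        if self.support_count < 0:
            raise MiningError("support_count must be >= 0")

    @property
    def canonical(self) -> str:
        return " & ".join(sorted(item.canonical for item in self.items))

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 co-occurrence counts for an antecedent/consequent pair.

    ``n11`` counts records with both A and B, ``n10`` A without B, ``n01``
    B without A, ``n00`` neither.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise MiningError("contingency counts must be >= 0")
        if self.total < 1:
            raise MiningError("contingency table must cover >= 1 record")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def a_count(self) -> int:
        """|A|: records containing the antecedent."""
        return self.n11 + self.n10

    @property
    def b_count(self) -> int:
        """|B|: records containing the consequent."""
        return self.n11 + self.n01

    @property
    def both_count(self) -> int:
        """|A ∩ B|."""
        return self.n11

    def swapped(self) -> "ContingencyTable":
        """The table of the reversed rule B -> A."""
        return ContingencyTable(self.n11, self.n01, self.n10, self.n00)


@dataclass(frozen=True)
class RuleMetrics:
    support: float
    confidence: float
    lift: float
    cosine: float
    correlation: float  # phi; NaN when a marginal is degenerate
    chi_square: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    p_value: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "support": self.support,
            "confidence": self.confidence,
            "lift": self.lift,
            "cosine": self.cosine,
            "correlation": self.correlation,
            "chi_square": self.chi_square,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class AssociationRule:
    """antecedent itemset -> single outcome item, with its score vector."""

    antecedent: Itemset
    consequent: Item
    metrics: RuleMetrics

    def __post_init__(self) -> None:
        if self.consequent in self.antecedent.items:
            raise MiningError("antecedent and consequent must be disjoint")

    @property
    def canonical(self) -> str:
        return f"{self.antecedent.canonical} -> {self.consequent.canonical}"


# ---------------------------------------------------------------------------
# Apriori


def mine_frequent_itemsets(
    matrix: TransactionMatrix,
    min_support: float = 0.05,
    max_len: int = 1,
) -> list[Itemset]:
    """All itemsets of size <= ``max_len`` with support >= ``min_support``.

    Level-wise Apriori: candidates of size k are joins of frequent
    (k-1)-itemsets and are pruned unless every (k-1)-subset is frequent.
    Returned sorted by (size, canonical string) for determinism.
    """
    if not 0.0 <= min_support <= 1.0:
        raise MiningError("min_support must lie in [0, 1]")
    if max_len < 1:
        raise MiningError("max_len must be >= 1")
    n = matrix.n_patients
    if n == 0:
        raise MiningError("empty transaction matrix")
    min_count = min_support * n

    # level 1: singleton supports straight from the column sums
    counts = matrix.incidence.sum(axis=0)
    frequent: dict[frozenset[Item], int] = {
        frozenset([item]): int(c)
        for item, c in zip(matrix.catalog, counts)
        if c >= min_count
    }
    result = dict(frequent)

    level = frequent
    k = 2
    while level and k <= max_len:
        # candidate generation: union pairs sharing k-2 items
        keys = sorted(level, key=lambda s: sorted(i.canonical for i in s))
        candidates: set[frozenset[Item]] = set()
        for a, b in itertools.combinations(keys, 2):
            union = a | b
            if len(union) == k:
                candidates.add(union)
        next_level: dict[frozenset[Item], int] = {}
        for cand in candidates:
            # Apriori pruning: every (k-1)-subset must be frequent
            if any(cand - {item} not in level for item in cand):
                continue
            count = matrix.support_count(cand)
            if count >= min_count:
                next_level[cand] = count
        result.update(next_level)
        level = next_level
        k += 1

    itemsets = [Itemset(items, count) for items, count in result.items()]
    itemsets.sort(key=lambda s: (len(s.items), s.canonical))
    return itemsets


# ---------------------------------------------------------------------------
# Contingency and measures


def contingency(
    matrix: TransactionMatrix, antecedent: Iterable[Item], consequent: Item
) -> ContingencyTable:
    """Exact 2x2 counts of an antecedent itemset against a consequent item."""
    antecedent = list(antecedent)
    for item in [*antecedent, consequent]:
        if not matrix.has(item):
            raise MiningError(f"item not in catalog: {item.canonical}")
    a_mask = np.ones(matrix.n_patients, dtype=bool)
    for item in antecedent:
        a_mask &= matrix.column(item)
    b_mask = matrix.column(consequent)
    n11 = int((a_mask & b_mask).sum())
    n10 = int((a_mask & ~b_mask).sum())
    n01 = int((~a_mask & b_mask).sum())
    n00 = int((~a_mask & ~b_mask).sum())
    return ContingencyTable(n11, n10, n01, n00)


def _pearson_chi_square(table: ContingencyTable) -> float:
    """Uncorrected Pearson statistic; 0 when a marginal is degenerate.

    Computed cell-by-cell from observed and expected counts rather than via
    the phi shortcut, so the chi2 = N * phi**2 identity is a genuine check.
    """
    observed = np.array(
        [[table.n11, table.n10], [table.n01, table.n00]], dtype=float
    )
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / table.total
    with np.errstate(invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def compute_metrics(table: ContingencyTable) -> RuleMetrics:
    """The full measure suite from one 2x2 table.

    * support      = n11 / N
    * confidence   = n11 / |A|            (|A| = 0 is an error)
    * lift         = N * n11 / (|A| |B|)  (0 when n11 = 0)
    * cosine       = n11 / sqrt(|A| |B|)
    * correlation  = phi coefficient; NaN when a marginal is 0 or N
    * chi_square   = Pearson statistic, no continuity correction
    * odds_ratio   = n11*n00 / (n10*n01), +0.5 on every cell if any is 0
    * or_ci        = Woolf interval, exp(log OR +- 1.96 * SE)
    """
    n = table.total
    a, b, n11 = table.a_count, table.b_count, table.n11
    if a == 0:
        raise MiningError("confidence undefined: antecedent never occurs")

    support = n11 / n
    confidence = n11 / a
    lift = 0.0 if n11 == 0 else n * n11 / (a * b)
    cosine = 0.0 if n11 == 0 else n11 / math.sqrt(a * b)

    denom = a * b * (n - a) * (n - b)
    if denom > 0:
        correlation = (n * n11 - a * b) / math.sqrt(denom)
    else:
        correlation = math.nan

    chi_square = _pearson_chi_square(table)

    cells = [table.n11, table.n10, table.n01, table.n00]
    if min(cells) == 0:
        cells = [c + 0.5 for c in cells]
    c11, c10, c01, c00 = cells
    odds_ratio = (c11 * c00) / (c10 * c01)
    se = math.sqrt(sum(1.0 / c for c in cells))
    log_or = math.log(odds_ratio)
    ci_low = math.exp(log_or - 1.96 * se)
    ci_high = math.exp(log_or + 1.96 * se)

    return RuleMetrics(
        support=support,
        confidence=confidence,
        lift=lift,
        cosine=cosine,
        correlation=correlation,
        chi_square=chi_square,
        odds_ratio=odds_ratio,
        or_ci_low=ci_low,
        or_ci_high=ci_high,
    )


# ---------------------------------------------------------------------------
# Rule generation


def generate_rules(
    itemsets: Sequence[Itemset],
    matrix: TransactionMatrix,
    consequents: Iterable[Item],
    min_confidence: float = 0.10,
) -> list[AssociationRule]:
    """One rule per (frequent antecedent, consequent) meeting ``min_confidence``.

    Antecedents containing any consequent item are skipped, so outcome items
    never appear on the left-hand side.
    """
    consequents = list(consequents)
    if not consequents:
        raise MiningError("need at least one consequent item")
    if not 0.0 <= min_confidence <= 1.0:
        raise MiningError("min_confidence must lie in [0, 1]")
    outcome_set = set(consequents)

    rules: list[AssociationRule] = []
    for itemset in itemsets:
        if itemset.items & outcome_set:
            continue
        if itemset.support_count == 0:
            continue  # confidence undefined for never-occurring antecedents
        for consequent in consequents:
            table = contingency(matrix, itemset.items, consequent)
            metrics = compute_metrics(table)
            if metrics.confidence >= min_confidence:
                rules.append(AssociationRule(itemset, consequent, metrics))
    return rules


def rules_to_jsonl(rules: Sequence[AssociationRule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rule in rules:
            fh.write(
                json.dumps(
                    {
                        "antecedent": sorted(
                            i.canonical for i in rule.antecedent.items
                        ),
                        "consequent": rule.consequent.canonical,
                        "metrics": rule.metrics.as_dict(),
                    }
                )
                + "\n"
            )
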