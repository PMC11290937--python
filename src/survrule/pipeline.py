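"""End-to-end convenience: records -> transactions -> rules -> ranked table."""

from __future__ import annotations

from typing import Sequence

from .cohort import AttributeSchema, PatientRecord, encode_transactions
from .mining import generate_rules, mine_frequent_itemsets
from .ranking import RankedRuleTable, filter_redundant, rank_rules

__all__ = ["mine_cohort"]


def mine_cohort(
    records: Sequence[PatientRecord],
    schema: AttributeSchema,
    min_support: float = 0.05,
    min_confidence: float = 0.10,
    max_antecedent: int = 1,
    top: int = 10,
    alpha: float = 0.05,
    drop_redundant: bool = True,
) -> RankedRuleTable:
    """Mine, score, filter and rank survivability rules for a cohort."""
    matrix = encode_transactions(records, schema)
    itemsets = mine_frequent_itemsets(matrix, min_support, max_antecedent)
    rules = generate_rules(
        itemsets, matrix, schema.outcome_items(), min_confidence
    )
    if drop_redundant:
        rules = filter_redundant(rules)
    return rank_rules(rules, k=top, alpha=alpha)
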