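"""Redundancy filtering, significance flags, confidence ranking, reporting."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

from .cohort import Item
from .mining import AssociationRule

__all__ = [
    "RankedRule",
    "RankedRuleTable",
    "benjamini_hochberg",
    "filter_redundant",
    "rank_rules",
    "significance_flag",
    "write_report",
]

REPORT_COLUMNS = [
    "Rule",
    "Antecedent (LHS)",
    "Consequent (RHS)",
    "Support",
    "Confidence",
    "Lift",
    "Cosine",
    "Correlation coefficient",
    "Chi-square",
    "OR (95% CI)",
]


@dataclass(frozen=True)
class RankedRule:
    rank: int
    rule: AssociationRule
    p_value: float
    significant: bool


@dataclass
class RankedRuleTable:
    """Per-consequent ranked rule lists, confidence non-increasing."""

    groups: dict[Item, list[RankedRule]]

    def __post_init__(self) -> None:
        for consequent, ranked in self.groups.items():
            confs = [r.rule.metrics.confidence for r in ranked]
            if any(b > a for a, b in zip(confs, confs[1:])):
                raise ValueError(
                    f"confidence not non-increasing for {consequent.canonical}"
                )
            if [r.rank for r in ranked] != list(range(1, len(ranked) + 1)):
                raise ValueError("ranks must be consecutive from 1")


def filter_redundant(rules: Sequence[AssociationRule]) -> list[AssociationRule]:
    """Drop rules dominated by a simpler retained rule.

    A rule is removed iff a retained rule with the same consequent has a
    strictly smaller antecedent (proper subset) and at least the same
    confidence — i.e. the extra items buy no confidence improvement.
    Idempotent; input order is preserved among the survivors.
    """
    order = sorted(range(len(rules)), key=lambda i: len(rules[i].antecedent.items))
    retained_idx: list[int] = []
    for i in order:
        rule = rules[i]
        dominated = any(
            rules[j].consequent == rule.consequent
            and rules[j].antecedent.items < rule.antecedent.items
            and rules[j].metrics.confidence >= rule.metrics.confidence
            for j in retained_idx
        )
        if not dominated:
            retained_idx.append(i)
    retained_idx.sort()
    return [rules[i] for i in retained_idx]


def significance_flag(
    rule: AssociationRule, alpha: float = 0.05
) -> tuple[bool, float]:
    """Upper-tail chi-square(1 df) p-value of the rule's statistic."""
    p_value = float(stats.chi2.sf(rule.metrics.chi_square, df=1))
    return p_value < alpha, p_value


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p_values[i] * m / (pos + 1))
        adjusted[i] = running
    return adjusted


def rank_rules(
    rules: Sequence[AssociationRule],
    k: int = 10,
    alpha: float = 0.05,
) -> RankedRuleTable:
    """Group rules by consequent, rank by confidence, keep the top ``k``.

    Ties break on support descending, then canonical antecedent ascending,
    so reports are fully deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    groups: dict[Item, list[AssociationRule]] = {}
    for rule in rules:
        groups.setdefault(rule.consequent, []).append(rule)

    ranked_groups: dict[Item, list[RankedRule]] = {}
    for consequent, members in groups.items():
        members = sorted(
            members,
            key=lambda r: (
                -r.metrics.confidence,
                -r.metrics.support,
                r.antecedent.canonical,
            ),
        )[:k]
        ranked = []
        for position, rule in enumerate(members, start=1):
            significant, p_value = significance_flag(rule, alpha)
            ranked.append(RankedRule(position, rule, p_value, significant))
        ranked_groups[consequent] = ranked
    return RankedRuleTable(ranked_groups)


def _format_or(rule: AssociationRule) -> str:
    m = rule.metrics
    return f"{m.odds_ratio:.3f} ({m.or_ci_low:.3f}-{m.or_ci_high:.3f})"


def report_frame(
    table: RankedRuleTable, include_bh: bool = False
) -> pd.DataFrame:
    """Tabular report, one block per consequent, ranked rows within."""
    rows = []
    for consequent in table.groups:
        for entry in table.groups[consequent]:
            m = entry.rule.metrics
            rows.append(
                {
                    "Rule": entry.rank,
                    "Antecedent (LHS)": entry.rule.antecedent.canonical,
                    "Consequent (RHS)": consequent.canonical,
                    "Support": round(m.support, 3),
                    "Confidence": round(m.confidence, 3),
                    "Lift": round(m.lift, 3),
                    "Cosine": round(m.cosine, 3),
                    "Correlation coefficient": round(m.correlation, 3),
                    "Chi-square": round(m.chi_square, 3),
                    "OR (95% CI)": _format_or(entry.rule),
                    "p_value": entry.p_value,
                    "significant": entry.significant,
                }
            )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS + ["p_value", "significant"])
    if include_bh and len(frame):
        frame["p_bh"] = benjamini_hochberg(list(frame["p_value"]))
    return frame


def write_report(
    table: RankedRuleTable, path: str | Path, include_bh: bool = False
) -> None:
    report_frame(table, include_bh=include_bh).to_csv(path, index=False)
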