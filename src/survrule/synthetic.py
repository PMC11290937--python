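"""Seedable synthetic cohorts with known marginals and planted rules.

The generator draws each attribute independently from per-attribute
categorical marginals, then plants antecedent -> death associations of a
chosen confidence: a patient matching a planted antecedent dies within the
outcome window with exactly that probability, everyone else with the
baseline probability.  This gives pipelines a ground truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import AttributeSchema, Item, PatientRecord

__all__ = [
    "MarginalSpec",
    "PlantedRule",
    "SyntheticError",
    "generate_cohort",
    "generate_survival_times",
    "save_generator_config",
]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class MarginalSpec:
    """Per-attribute category probability vectors, aligned with a schema."""

    probabilities: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "probabilities",
            {k: tuple(float(p) for p in v) for k, v in self.probabilities.items()},
        )
        for name, probs in self.probabilities.items():
            if any(p < 0 for p in probs):
                raise SyntheticError(f"negative probability for {name!r}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise SyntheticError(
                    f"probabilities for {name!r} sum to {sum(probs)!r}, not 1"
                )

    def validate_against(self, schema: AttributeSchema) -> None:
        if set(self.probabilities) != set(schema.attribute_names):
            raise SyntheticError("marginal attributes do not match the schema")
        for name, probs in self.probabilities.items():
            if len(probs) != len(schema.categories(name)):
                raise SyntheticError(
                    f"marginal for {name!r} has {len(probs)} entries for "
                    f"{len(schema.categories(name))} categories"
                )

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, Sequence[float]]
    ) -> "MarginalSpec":
        """Normalize raw category counts into probability vectors."""
        probs = {}
        for name, vec in counts.items():
            total = float(sum(vec))
            if total <= 0:
                raise SyntheticError(f"counts for {name!r} sum to zero")
            probs[name] = tuple(c / total for c in vec)
        return cls(probs)


@dataclass(frozen=True)
class PlantedRule:
    """An antecedent item with a target death-within-window confidence."""

    antecedent: Item
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise SyntheticError("confidence must lie in [0, 1]")


def generate_cohort(
    schema: AttributeSchema,
    marginals: MarginalSpec,
    planted: Sequence[PlantedRule] = (),
    baseline_death_prob: float = 0.5,
    n: int = 1000,
    seed: int = 0,
) -> list[PatientRecord]:
    """Draw ``n`` records; attributes independent, outcomes per planted rules.

    A patient matching several planted antecedents takes the first match in
    list order (rules must reference distinct attributes).  Deaths get a
    survival length uniform on [1, cutoff]; survivors uniform on
    (cutoff, 2*cutoff].  Identical arguments and seed reproduce the cohort
    exactly.
    """
    if n < 1:
        raise SyntheticError("n must be >= 1")
    if not 0.0 <= baseline_death_prob <= 1.0:
        raise SyntheticError("baseline_death_prob must lie in [0, 1]")
    marginals.validate_against(schema)
    attrs_seen = set()
    for rule in planted:
        name = rule.antecedent.attribute
        if name not in schema.attribute_names:
            raise SyntheticError(f"planted antecedent on unknown attribute {name!r}")
        if rule.antecedent.category not in schema.categories(name):
            raise SyntheticError(
                f"planted antecedent {rule.antecedent.canonical!r} not in schema"
            )
        if name in attrs_seen:
            raise SyntheticError("planted antecedents must reference distinct attributes")
        attrs_seen.add(name)

    rng = np.random.default_rng(seed)
    cutoff = schema.outcome_cutoff_months

    columns: dict[str, np.ndarray] = {}
    for name in schema.attribute_names:
        cats = schema.categories(name)
        idx = rng.choice(len(cats), size=n, p=marginals.probabilities[name])
        columns[name] = np.asarray(cats, dtype=object)[idx]

    death_prob = np.full(n, baseline_death_prob)
    assigned = np.zeros(n, dtype=bool)
    for rule in planted:
        match = (columns[rule.antecedent.attribute] == rule.antecedent.category)
        take = match & ~assigned
        death_prob[take] = rule.confidence
        assigned |= match

    dead = rng.random(n) < death_prob
    months = np.where(
        dead,
        rng.integers(1, cutoff + 1, size=n),
        rng.integers(cutoff + 1, 2 * cutoff + 1, size=n),
    )

    return [
        PatientRecord(
            values={name: columns[name][i] for name in schema.attribute_names},
            survival_months=int(months[i]),
            dead_within_followup=bool(dead[i]),
        )
        for i in range(n)
    ]


def _per_record_rates(
    records: Sequence[PatientRecord],
    hazard_per_month: float | Sequence[float] | Mapping[str, float],
) -> np.ndarray:
    if isinstance(hazard_per_month, Mapping):
        rates = []
        for record in records:
            for key, rate in hazard_per_month.items():
                item = Item.from_canonical(key)
                if record.values.get(item.attribute) == item.category:
                    rates.append(rate)
                    break
            else:
                raise SyntheticError("record matches no hazard group")
        return np.asarray(rates, dtype=float)
    if np.isscalar(hazard_per_month):
        return np.full(len(records), float(hazard_per_month))
    rates = np.asarray(hazard_per_month, dtype=float)
    if rates.shape != (len(records),):
        raise SyntheticError("per-record rates must match the cohort length")
    return rates


def generate_survival_times(
    records: Sequence[PatientRecord],
    hazard_per_month: float | Sequence[float] | Mapping[str, float],
    censor_at_months: int = 120,
    seed: int = 0,
) -> list[tuple[float, bool]]:
    """Exponential event times with administrative right-censoring.

    ``hazard_per_month`` may be a single rate, a per-record sequence, or a
    mapping from canonical item strings (``"attribute: category"``) to
    per-group rates.  Zero hazard yields all-censored data.
    """
    rates = _per_record_rates(records, hazard_per_month)
    if np.any(rates < 0):
        raise SyntheticError("hazard rates must be >= 0")
    if censor_at_months <= 0:
        raise SyntheticError("censor_at_months must be > 0")

    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        raw = np.where(
            rates > 0,
            rng.exponential(1.0, size=len(records)) / np.where(rates > 0, rates, 1.0),
            np.inf,
        )
    observed = np.minimum(raw, censor_at_months)
    event = raw <= censor_at_months
    return [(float(t), bool(e)) for t, e in zip(observed, event)]


def save_generator_config(
    path: str | Path,
    schema: AttributeSchema,
    marginals: MarginalSpec,
    planted: Sequence[PlantedRule],
    baseline_death_prob: float,
    n: int,
    seed: int,
) -> None:
    """Provenance sidecar: everything needed to regenerate the cohort."""
    payload = {
        "schema": schema.to_dict(),
        "marginals": {k: list(v) for k, v in marginals.probabilities.items()},
        "planted": [
            {"antecedent": r.antecedent.canonical, "confidence": r.confidence}
            for r in planted
        ],
        "baseline_death_prob": baseline_death_prob,
        "n": n,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
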