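"""Patient-record data model, cohort I/O, and transaction encoding.

A cohort is a table of categorical clinicopathologic attributes plus a
survival length in months and a vital-status flag.  Records are validated
against an :class:`AttributeSchema` and encoded as binary transactions of
``"attribute: category"`` items, with a single derived outcome item per
patient (death within, or survival beyond, a cutoff — 60 months by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AttributeSchema",
    "CohortValidationError",
    "Item",
    "NumericBinning",
    "PatientRecord",
    "TransactionMatrix",
    "OUTCOME_ATTRIBUTE",
    "DEATH_LABEL",
    "SURVIVE_LABEL",
    "derive_outcome",
    "encode_transactions",
    "load_cohort",
    "load_schema",
    "write_cohort",
    "write_transactions",
]

#: Attribute name reserved for the derived 5-year survivability consequent.
OUTCOME_ATTRIBUTE = "survival_5y"
DEATH_LABEL = "death<=5y"
SURVIVE_LABEL = "survive>5y"

SURVIVAL_MONTHS_FIELD = "survival_months"
DEAD_FIELD = "dead_within_followup"


class CohortValidationError(ValueError):
    """Raised when a record or schema violates its declared contract."""


@dataclass(frozen=True, order=True)
class Item:
    """A single ``attribute: category`` token of the transaction alphabet."""

    attribute: str
    category: str

    def __post_init__(self) -> None:
        if ": " in self.attribute:
            raise CohortValidationError(
                f"attribute name {self.attribute!r} may not contain ': '"
            )

    @property
    def canonical(self) -> str:
        return f"{self.attribute}: {self.category}"

    @classmethod
    def from_canonical(cls, text: str) -> "Item":
        attribute, sep, category = text.partition(": ")
        if not sep:
            raise CohortValidationError(f"not a canonical item string: {text!r}")
        return cls(attribute, category)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


@dataclass(frozen=True)
class NumericBinning:
    """Ordered bins turning a numeric column into category labels.

    ``edges`` are the interior cut points; value ``v`` falls in bin ``i``
    when ``edges[i-1] <= v < edges[i]`` with open outer bins, so ``k`` labels
    need ``k - 1`` strictly increasing edges.
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise CohortValidationError("numeric binning needs at least one label")
        if len(self.edges) != len(self.labels) - 1:
            raise CohortValidationError(
                f"{len(self.labels)} labels need {len(self.labels) - 1} edges, "
                f"got {len(self.edges)}"
            )
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise CohortValidationError("bin edges must be strictly increasing")

    def assign(self, value: float) -> str:
        idx = int(np.searchsorted(self.edges, value, side="right"))
        return self.labels[idx]


@dataclass
class AttributeSchema:
    """Declares attributes, their category alphabets, N/A policy and binning.

    Parameters
    ----------
    attributes
        Ordered ``name -> categories`` mapping. Category order is preserved
        and fixes the deterministic item-catalog order.
    na_label
        Label representing nonavailable pathology data.  It must appear as a
        category for exactly the attributes listed in ``na_attributes``.
    na_attributes
        Attributes allowed to carry ``na_label`` (e.g. pathology fields that
        are undefined for nonsurgical patients).
    numeric_bins
        Binning for attributes whose raw column is numeric; the binned
        labels must equal the attribute's declared categories.
    outcome_cutoff_months
        Boundary of the survivability consequent (strictly greater than the
        cutoff counts as survival).
    """

    attributes: dict[str, tuple[str, ...]]
    na_label: str = "N/A"
    na_attributes: tuple[str, ...] = ()
    numeric_bins: dict[str, NumericBinning] = field(default_factory=dict)
    outcome_cutoff_months: int = 60

    def __post_init__(self) -> None:
        self.attributes = {k: tuple(v) for k, v in self.attributes.items()}
        self.na_attributes = tuple(self.na_attributes)
        names = list(self.attributes)
        if len(set(names)) != len(names):
            raise CohortValidationError("attribute names must be unique")
        if OUTCOME_ATTRIBUTE in names:
            raise CohortValidationError(
                f"{OUTCOME_ATTRIBUTE!r} is reserved for the derived outcome"
            )
        for name, cats in self.attributes.items():
            if len(set(cats)) != len(cats):
                raise CohortValidationError(f"duplicate categories for {name!r}")
            if not cats:
                raise CohortValidationError(f"attribute {name!r} has no categories")
            has_na = self.na_label in cats
            if has_na and name not in self.na_attributes:
                raise CohortValidationError(
                    f"{name!r} carries {self.na_label!r} but is not an N/A attribute"
                )
            if not has_na and name in self.na_attributes:
                raise CohortValidationError(
                    f"N/A attribute {name!r} must list {self.na_label!r} as a category"
                )
        for name in self.na_attributes:
            if name not in self.attributes:
                raise CohortValidationError(f"unknown N/A attribute {name!r}")
        for name, binning in self.numeric_bins.items():
            if name not in self.attributes:
                raise CohortValidationError(f"unknown numeric attribute {name!r}")
            if tuple(binning.labels) != self.attributes[name]:
                raise CohortValidationError(
                    f"bin labels for {name!r} must match its declared categories"
                )
        if self.outcome_cutoff_months < 1:
            raise CohortValidationError("outcome_cutoff_months must be >= 1")

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(self.attributes)

    def categories(self, attribute: str) -> tuple[str, ...]:
        return self.attributes[attribute]

    def item_catalog(self) -> list[Item]:
        """Deterministic catalog: schema attribute order, then category order,
        then the two outcome items."""
        catalog = [
            Item(name, cat)
            for name, cats in self.attributes.items()
            for cat in cats
        ]
        catalog.append(Item(OUTCOME_ATTRIBUTE, DEATH_LABEL))
        catalog.append(Item(OUTCOME_ATTRIBUTE, SURVIVE_LABEL))
        return catalog

    def outcome_items(self) -> tuple[Item, Item]:
        return (Item(OUTCOME_ATTRIBUTE, DEATH_LABEL), Item(OUTCOME_ATTRIBUTE, SURVIVE_LABEL))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "attributes": {k: list(v) for k, v in self.attributes.items()},
            "na_label": self.na_label,
            "na_attributes": list(self.na_attributes),
            "numeric_bins": {
                k: {"edges": list(b.edges), "labels": list(b.labels)}
                for k, b in self.numeric_bins.items()
            },
            "outcome_cutoff_months": self.outcome_cutoff_months,
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AttributeSchema":
        bins = {
            k: NumericBinning(tuple(v["edges"]), tuple(v["labels"]))
            for k, v in raw.get("numeric_bins", {}).items()
        }
        return cls(
            attributes={k: tuple(v) for k, v in raw["attributes"].items()},
            na_label=raw.get("na_label", "N/A"),
            na_attributes=tuple(raw.get("na_attributes", ())),
            numeric_bins=bins,
            outcome_cutoff_months=int(raw.get("outcome_cutoff_months", 60)),
        )


def load_schema(path: str | Path) -> AttributeSchema:
    """Read an :class:`AttributeSchema` from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return AttributeSchema.from_dict(raw)


@dataclass(frozen=True)
class PatientRecord:
    """One validated patient row: attribute values plus survival fields."""

    values: Mapping[str, str]
    survival_months: int
    dead_within_followup: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        if self.survival_months < 1:
            raise CohortValidationError("survival_months must be >= 1")

    def item(self, attribute: str) -> Item:
        return Item(attribute, self.values[attribute])


def _validate_value(
    schema: AttributeSchema, attribute: str, raw: str, row: int
) -> str:
    binning = schema.numeric_bins.get(attribute)
    if binning is not None and str(raw) not in schema.attributes[attribute]:
        # raw numeric value -> discretize; already-binned labels pass through
        try:
            return binning.assign(float(raw))
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(
                f"row {row}: attribute {attribute!r}: value {raw!r} is neither "
                "a bin label nor numeric"
            ) from exc
    value = str(raw)
    if value not in schema.attributes[attribute]:
        raise CohortValidationError(
            f"row {row}: attribute {attribute!r}: unknown category {value!r}"
        )
    return value


def load_cohort(path: str | Path, schema: AttributeSchema) -> list[PatientRecord]:
    """Read and validate a cohort CSV; numeric attributes are discretized.

    The header must contain every schema attribute plus ``survival_months``
    and ``dead_within_followup``.  A header-only file yields an empty list.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return records_from_frame(frame, schema)


def records_from_frame(
    frame: pd.DataFrame, schema: AttributeSchema
) -> list[PatientRecord]:
    required = set(schema.attribute_names) | {SURVIVAL_MONTHS_FIELD, DEAD_FIELD}
    missing = required - set(frame.columns)
    if missing:
        raise CohortValidationError(f"missing columns: {sorted(missing)}")

    records: list[PatientRecord] = []
    for row_idx, row in enumerate(frame.itertuples(index=False)):
        row_map = dict(zip(frame.columns, row))
        values = {
            name: _validate_value(schema, name, row_map[name], row_idx)
            for name in schema.attribute_names
        }
        raw_months = row_map[SURVIVAL_MONTHS_FIELD]
        if raw_months in ("", None):
            raise CohortValidationError(f"row {row_idx}: missing survival_months")
        try:
            months = int(float(raw_months))
        except ValueError as exc:
            raise CohortValidationError(
                f"row {row_idx}: bad survival_months {raw_months!r}"
            ) from exc
        dead = str(row_map[DEAD_FIELD]).strip().lower() in ("1", "true", "yes")
        records.append(PatientRecord(values, months, dead))
    return records


def cohort_frame(records: Sequence[PatientRecord], schema: AttributeSchema) -> pd.DataFrame:
    rows = [
        {
            **{name: r.values[name] for name in schema.attribute_names},
            SURVIVAL_MONTHS_FIELD: r.survival_months,
            DEAD_FIELD: int(r.dead_within_followup),
        }
        for r in records
    ]
    columns = list(schema.attribute_names) + [SURVIVAL_MONTHS_FIELD, DEAD_FIELD]
    return pd.DataFrame(rows, columns=columns)


def write_cohort(
    records: Sequence[PatientRecord], schema: AttributeSchema, path: str | Path
) -> None:
    cohort_frame(records, schema).to_csv(path, index=False)


def derive_outcome(record: PatientRecord, schema: AttributeSchema) -> Item:
    """The survivability consequent: survival strictly beyond the cutoff.

    A patient surviving exactly ``outcome_cutoff_months`` months is a
    non-survivor — the survivor bin is open (> cutoff).
    """
    if record.survival_months > schema.outcome_cutoff_months:
        return Item(OUTCOME_ATTRIBUTE, SURVIVE_LABEL)
    return Item(OUTCOME_ATTRIBUTE, DEATH_LABEL)


@dataclass
class TransactionMatrix:
    """N patients x M items binary incidence matrix over a fixed catalog."""

    catalog: list[Item]
    incidence: np.ndarray  # bool, shape (N, M)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.incidence.ndim != 2 or self.incidence.shape[1] != len(self.catalog):
            raise CohortValidationError("incidence shape does not match catalog")
        self._index = {item: j for j, item in enumerate(self.catalog)}
        if len(self._index) != len(self.catalog):
            raise CohortValidationError("duplicate items in catalog")

    @property
    def n_patients(self) -> int:
        return self.incidence.shape[0]

    def column(self, item: Item) -> np.ndarray:
        try:
            return self.incidence[:, self._index[item]]
        except KeyError:
            raise KeyError(f"item not in catalog: {item.canonical}") from None

    def has(self, item: Item) -> bool:
        return item in self._index

    def support_count(self, items: Iterable[Item]) -> int:
        mask = np.ones(self.n_patients, dtype=bool)
        for item in items:
            mask &= self.column(item)
        return int(mask.sum())

    def transactions(self) -> list[list[Item]]:
        return [
            [self.catalog[j] for j in np.flatnonzero(row)]
            for row in self.incidence
        ]


def encode_transactions(
    records: Sequence[PatientRecord], schema: AttributeSchema
) -> TransactionMatrix:
    """One row per record: one item per schema attribute plus the outcome item.

    N/A values are encoded as ordinary items; the catalog covers the full
    schema alphabet in deterministic order regardless of which categories
    occur in the data.
    """
    catalog = schema.item_catalog()
    index = {item: j for j, item in enumerate(catalog)}
    incidence = np.zeros((len(records), len(catalog)), dtype=bool)
    for i, record in enumerate(records):
        for name in schema.attribute_names:
            incidence[i, index[record.item(name)]] = True
        incidence[i, index[derive_outcome(record, schema)]] = True
    return TransactionMatrix(catalog, incidence)


def write_transactions(matrix: TransactionMatrix, path: str | Path) -> None:
    """Write one semicolon-separated line of canonical item strings per patient."""
    with open(path, "w") as fh:
        for row in matrix.transactions():
            fh.write(";".join(item.canonical for item in row) + "\n")
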