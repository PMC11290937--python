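from __future__ import annotations

import numpy as np
import pytest

from survrule.cohort import (
    AttributeSchema,
    Item,
    NumericBinning,
    PatientRecord,
    TransactionMatrix,
)


@pytest.fixture
def toy_schema() -> AttributeSchema:
    """Three attributes, one with an N/A category and one numeric-binned."""
    return AttributeSchema(
        attributes={
            "age_range": ("<50", "50-69", ">=70"),
            "surgical_margin": ("negative", "positive", "N/A"),
            "stage": ("early", "late"),
        },
        na_label="N/A",
        na_attributes=("surgical_margin",),
        numeric_bins={
            "age_range": NumericBinning((50.0, 70.0), ("<50", "50-69", ">=70"))
        },
    )


@pytest.fixture
def toy_records(toy_schema) -> list[PatientRecord]:
    rows = [
        ({"age_range": "<50", "surgical_margin": "negative", "stage": "early"}, 72, False),
        ({"age_range": "50-69", "surgical_margin": "positive", "stage": "late"}, 10, True),
        ({"age_range": ">=70", "surgical_margin": "N/A", "stage": "late"}, 61, False),
    ]
    return [PatientRecord(v, m, d) for v, m, d in rows]


def make_matrix(rows: list[list[int]], n_items: int) -> TransactionMatrix:
    """Anonymous item catalog i0..i{n-1} over explicit index rows."""
    catalog = [Item("attr", f"i{j}") for j in range(n_items)]
    incidence = np.zeros((len(rows), n_items), dtype=bool)
    for r, row in enumerate(rows):
        incidence[r, row] = True
    return TransactionMatrix(catalog, incidence)


#: 10 rows over 4 items; item 0 = A (|A| = 4), item 1 = B (|B| = 5),
#: co-occurrence 3 -> contingency (3, 1, 2, 4).
TOY_ROWS = [
    [0, 1],
    [0, 1],
    [0, 1, 2],
    [0, 3],
    [1, 2],
    [1, 3],
    [2],
    [2, 3],
    [3],
    [],
]


@pytest.fixture
def toy_matrix() -> TransactionMatrix:
    return make_matrix(TOY_ROWS, 4)


def random_matrix(rng: np.random.Generator, n_rows: int, n_items: int) -> TransactionMatrix:
    catalog = [Item("attr", f"i{j}") for j in range(n_items)]
    incidence = rng.random((n_rows, n_items)) < rng.uniform(0.2, 0.8, size=n_items)
    return TransactionMatrix(catalog, incidence)
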