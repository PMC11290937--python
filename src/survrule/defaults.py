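"""A ready-made oral-cancer cohort configuration for simulation and demos.

Category frequencies follow published marginal distributions of a regional
oral-cancer cohort (surgical-pathology fields carry an explicit N/A category
for the nonsurgical group); age is drawn from decade bins approximating a
normal distribution with mean 64 and SD 8.9 years.
"""

from __future__ import annotations

from scipy import stats

from .cohort import AttributeSchema
from .synthetic import MarginalSpec

__all__ = ["default_schema", "default_marginals"]

NA = "N/A"

# attribute -> ordered (category, relative frequency) pairs
_FREQUENCIES: dict[str, list[tuple[str, float]]] = {
    "gender": [("male", 460), ("female", 437)],
    "comorbidities": [
        ("none", 565),
        ("diabetes mellitus", 48),
        ("hypertension", 90),
        ("dyslipidemia", 4),
        ("heart disease", 7),
        ("neurological disease", 5),
        ("kidney disease", 9),
        ("multiple diseases", 60),
        ("others", 2),
    ],
    "tumor_location": [
        ("oral tongue", 405),
        ("floor of mouth", 112),
        ("buccal mucosa", 108),
        ("alveolar ridge", 120),
        ("hard palate", 37),
        ("lip", 78),
        ("retromolar trigone", 33),
        ("uncertain site", 4),
    ],
    "t_stage": [("T1", 125), ("T2", 240), ("T3", 128), ("T4a", 370), ("T4b", 34)],
    "n_stage": [
        ("N0", 407),
        ("N1", 150),
        ("N2a", 70),
        ("N2b", 167),
        ("N2c", 83),
        ("N3", 20),
    ],
    "tnm_stage": [
        ("stage I", 91),
        ("stage II", 135),
        ("stage III", 135),
        ("stage IVa", 481),
        ("stage IVb", 48),
        ("stage IVc", 7),
    ],
    "tumor_type": [
        ("SCC, WD", 522),
        ("SCC, MD", 234),
        ("SCC, PD", 41),
        ("undifferentiated CA", 18),
        ("nonkeratinizing CA", 9),
        ("adenoid cystic CA", 29),
        ("mucoepidermoid CA", 18),
        ("others", 26),
    ],
    "lymph_node_metastasis": [("negative", 407), ("positive", 490)],
    "surgical_margin": [("negative", 397), ("positive", 133), (NA, 367)],
    "extranodal_extension": [("negative", 473), ("positive", 46), (NA, 378)],
    "lymphovascular_invasion": [("negative", 473), ("positive", 93), (NA, 367)],
    "perineural_invasion": [("negative", 437), ("positive", 93), (NA, 367)],
    "recurrence": [
        ("no", 705),
        ("local recurrence", 81),
        ("regional recurrence", 49),
        ("locoregional recurrence", 62),
    ],
    "distant_metastasis": [
        ("no", 832),
        ("lung metastasis", 49),
        ("bone metastasis", 11),
        ("brain metastasis", 1),
        ("other area metastasis", 4),
    ],
    "treatment": [
        ("surgery only", 149),
        ("surgery and radiotherapy", 252),
        ("surgery and concurrent chemoradiotherapy", 129),
        ("induction chemotherapy", 57),
        ("concurrent chemoradiotherapy", 216),
        ("palliative treatment", 94),
    ],
}

_AGE_LABELS = ["<40", "40-49", "50-59", "60-69", "70-79", ">=80"]
_AGE_EDGES = [40.0, 50.0, 60.0, 70.0, 80.0]
_AGE_MEAN, _AGE_SD = 64.0, 8.88

_NA_ATTRIBUTES = (
    "surgical_margin",
    "extranodal_extension",
    "lymphovascular_invasion",
    "perineural_invasion",
)


def default_schema(outcome_cutoff_months: int = 60) -> AttributeSchema:
    """Schema with decade age bins and N/A-bearing pathology fields."""
    from .cohort import NumericBinning

    attributes = {"age_range": tuple(_AGE_LABELS)}
    attributes.update(
        {name: tuple(cat for cat, _ in pairs) for name, pairs in _FREQUENCIES.items()}
    )
    return AttributeSchema(
        attributes=attributes,
        na_label=NA,
        na_attributes=_NA_ATTRIBUTES,
        numeric_bins={
            "age_range": NumericBinning(tuple(_AGE_EDGES), tuple(_AGE_LABELS))
        },
        outcome_cutoff_months=outcome_cutoff_months,
    )


def _age_bin_probabilities() -> list[float]:
    dist = stats.norm(_AGE_MEAN, _AGE_SD)
    cdf = [0.0] + [float(dist.cdf(e)) for e in _AGE_EDGES] + [1.0]
    return [b - a for a, b in zip(cdf, cdf[1:])]


def default_marginals() -> MarginalSpec:
    counts: dict[str, list[float]] = {"age_range": _age_bin_probabilities()}
    counts.update(
        {name: [freq for _, freq in pairs] for name, pairs in _FREQUENCIES.items()}
    )
    return MarginalSpec.from_counts(counts)
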