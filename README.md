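# survrule

Association-rule mining of 5-year survivability in clinical cohorts.

`survrule` turns a table of categorical clinicopathologic patient records
into binary transactions, mines frequent antecedents with Apriori, scores
every `antecedent -> outcome` rule with a six-measure suite (support,
confidence, lift, cosine, phi correlation, chi-square) plus an odds ratio
with a Woolf 95% CI, filters redundant rules, and ranks the survivors by
confidence per outcome. It also computes grouped 5-year survival rates and
Kaplan-Meier curves, and ships a seedable synthetic-cohort generator with
plantable rules of known confidence so the whole pipeline can be validated
end to end.

## Library quick start

```python
import survrule as sr

schema = sr.default_schema()            # oral-cancer style attribute schema
marginals = sr.default_marginals()      # realistic category frequencies

# synthetic cohort with one planted high-risk rule
records = sr.generate_cohort(
    schema, marginals,
    planted=[sr.PlantedRule(sr.Item("extranodal_extension", "positive"), 0.9)],
    baseline_death_prob=0.4, n=2000, seed=1,
)

table = sr.mine_cohort(records, schema, min_support=0.05, top=10)
for outcome, ranked in table.groups.items():
    for entry in ranked[:3]:
        print(entry.rank, entry.rule.canonical, round(entry.rule.metrics.confidence, 3))
```

Outcome items are derived from `survival_months`: strictly more than the
schema cutoff (60 months by default) is `survive>5y`, anything at or below
it `death<=5y`. `N/A` pathology values (nonsurgical patients) are first-class
items, never imputed or dropped.

## CLI

```bash
# simulate a cohort with a planted rule; a .run.json sidecar records provenance
survrule simulate --n 1000 --seed 7 \
    --plant "extranodal_extension: positive=0.95" --out cohort.csv

# mine and rank rules into a report CSV
survrule mine --input cohort.csv --min-support 0.05 --min-confidence 0.10 \
    --max-antecedent 1 --top 10 --alpha 0.05 --out report.csv

# Kaplan-Meier curve and grouped survivor fraction
survrule km --input cohort.csv --at 60 --out curve.csv
```

Custom schemas are YAML/JSON configs (see `AttributeSchema.to_dict()` for
the shape); numeric columns such as age are discretized via the schema's
bin edges at load time.

## Layout

- `src/survrule/cohort.py` — schema, records, items, transaction encoding, CSV I/O
- `src/survrule/synthetic.py` — seedable cohort generator with planted rules
- `src/survrule/mining.py` — Apriori, 2x2 contingency tables, measure suite
- `src/survrule/ranking.py` — redundancy filter, significance, ranking, report
- `src/survrule/survival.py` — grouped survival rate, Kaplan-Meier estimator
- `src/survrule/pipeline.py` / `cli.py` — end-to-end helpers and `survrule` CLI
- `tests/` — unit, property and acceptance suites with brute-force oracles
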