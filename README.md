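# fhirtab

Flatten FHIR R4 clinical resources into a small relational schema and run
descriptive patient-centered and cohort analytics over it.

FHIR represents clinical data as nested JSON resources — great for
exchange, poor for the "how many patients per allergy?" class of question.
`fhirtab` is a desk-scale ETL + analytics tool for health-informatics
engineers and researchers: it streams resources of seven kinds (Patient,
AllergyIntolerance, Practitioner, Condition, ServiceRequest,
DiagnosticReport, Appointment) from a local NDJSON/Bundle store or a FHIR
REST endpoint, flattens each through a per-type **mapping template**
(ordered element-path → table/column entries, applied "on the fly" while
streaming) into an embedded SQLite schema keyed by patient and practitioner
references, and answers five descriptive workflows:

1. patients by gender,
2. patient registrations by year,
3. distinct patients per allergy label (allergy→patient join),
4. test orders per test name, with integer percentages by
   largest-remainder apportionment (Σ = 100 exactly),
5. test orders by year.

A deterministic synthetic dataset generator produces referentially closed
fixtures whose marginal distributions are configured **exactly** (assigned
by quota, not sampled), so every pipeline output is checkable against a
brute-force count over the raw JSON. The default configuration is a
700-resource extract: 100 resources per type, 55/45 gender split, 17
allergy labels, 8 test names, years spanning 1950–2021.

## Worked example

```sh
fhirtab all --fixture default --seed 1729 --out run1/
```

prints

```
{"resources": 700, "workflow_totals": {"gender_distribution": 100, "registrations_by_year": 100, "allergy_cohorts": 100, "test_order_distribution": 100, "test_orders_by_year": 100}}
```

meaning: 700 resources were generated into `run1/fixture/` (7 NDJSON files
+ `manifest.json`), mapped into `run1/store.sqlite`, and each workflow
accounted for all 100 of its rows (no orphans, no undated exclusions).
`run1/results/` then holds one CSV and one JSON per workflow;
`run1/results/gender_distribution.csv` reads

```
label,count,percent
male,55,
female,45,
```

i.e. 55 of the 100 registered patients are male and 45 female. The same
run is available stepwise (`generate`, `map`, `analyze`) and as a library:

```python
from fhirtab import (default_fixture_config, generate_dataset, open_source,
                     create_schema, drf_run, ResourceType, allergy_cohort_counts)

generate_dataset(default_fixture_config(), "fixture/")
schema = create_schema("store.sqlite")
drf_run(open_source("fixture/"), list(ResourceType), schema)
print(allergy_cohort_counts(schema).as_dict()["Shellfish"])   # 9
```

`fhirtab report --store store.sqlite` prints table counts and an integrity
summary (orphan references, duplicate natural keys, null rates).

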