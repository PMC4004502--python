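# qicompare

Compute colorectal-cancer-surgery quality indicators from two parallel
patient-level datasets — a manually abstracted registry and a structured EMR
extract — match patients across the sources without shared identifiers,
quantify agreement with diagnostic-accuracy statistics and an
overlapping-samples proportion test, and measure per-item data quality
(structured availability, completeness, correctness). A synthetic-cohort
generator with controlled quality defects makes every stage runnable without
external data.

## Modules

| module | purpose |
| --- | --- |
| `qicompare.indicator_engine` | declarative indicator definitions (JSON predicate trees, YAML code lists) evaluated under three-valued logic, with computability assessment |
| `qicompare.patient_matching` | deterministic linkage on (gender, year of birth, operation date) with procedure-set Jaccard tie-breaking and explicit ambiguity reporting |
| `qicompare.concordance_stats` | cross-classification of selections, sensitivity/specificity/PPV/NPV/PLR/NLR with explicit undefined states, overlapping-samples z-test |
| `qicompare.data_quality` | per-item completeness ('unknown' counts as absent), effect-equivalence correctness, applicability-aware averages |
| `qicompare.synthetic_data` | paired-cohort generator (missingness, errors, extraction anomalies, free-text-only items) and deterministic fixtures built from published summary counts |
| `qicompare.cli_reporting` | end-to-end pipeline and CSV/JSON report bundle |

## CLI

```bash
# generate a paired synthetic cohort
qicompare simulate --config examples/generator.yaml --out synthetic_out

# full pipeline from a config that names either dataset paths or a generator
qicompare run --config pipeline.yaml --out report_out [--seed N] [--strict-exclusions] [--locale comma]

# single-source indicator computation / data-quality table
qicompare indicators --dataset registry.csv
qicompare quality --registry registry.csv --emr emr.csv
```

A minimal pipeline config (YAML):

```yaml
generator:
  n_patients: 79
  seed: 11
  registry_coverage: 0.95
  unstructured_items: [ct_stage, pn_stage, pm_stage,
                       examined_lymph_nodes, circumferential_margin_mm]
  per_item_error: {chemotherapy: 0.3}
  emr_extract_noise: {missing_diagnosis: 0.05, diagnosis_after_operation: 0.08}
output_dir: report_out
```

or, with existing data:

```yaml
registry_path: registry.csv
emr_path: emr.csv
output_dir: report_out
```

The report bundle contains the indicator-results table (with computability
flags and accuracy statistics), the cross-classification table, the
data-quality table, a matching flow summary, a categorised problems log, the
serialised match result and a run manifest. Identical config + seed gives a
byte-identical bundle.

Datasets are CSV or JSON, one row per patient, one column per data item
(compound items flattened, e.g. `diagnosis_location`) plus a
`<item>_status` column with `present | absent | unknown | unstructured`;
dates are ISO-8601.

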