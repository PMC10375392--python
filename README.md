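# qcs — qualifying-comorbidity-set screening toolkit

A desk-scale library and CLI that classifies a patient as **multimorbid**
when their comorbid-condition profile contains a *qualifying set* — a
rule-base combination of 1–3 conditions — plus the statistics used to
evaluate such a screening tool in a usability trial.

## What's inside

| module | role |
|---|---|
| `qcs.catalog` | Rule base: conditions, clinical-code lists (ICD-9/10-CM, CPT, HCPCS), qualifying sets; JSON loading, normalization, validation (`data/catalog.schema.json` documents the format) |
| `qcs.mapper` | Coded claims → condition profiles (exact and prefix code matching, dotted/undotted dialects unified) |
| `qcs.matcher` | Multimorbidity decision: batch (`evaluate`, full witness list) and incremental (`IncrementalMatcher`, fires on the first selection completing any set) |
| `qcs.session` | Screening-flow emulation: organ-system pages, condition toggling, immediate multimorbid notification, early termination, notification payload |
| `qcs.evaluation` | Trial analysis: selection-error tallies, trial-level sensitivity/specificity, paired t-tests on completion times, 1–5 Likert summaries (sample SD) |
| `qcs.fixtures` | Built-in scenarios and reference 50-trial dataset, a NON-CLINICAL demonstration catalog, seeded synthetic patient/rater generators |

The demonstration catalog's qualifying sets are invented for internal
consistency of the fixtures; they are **not** clinically derived, and the
claims classifier refuses the catalog without `--allow-toy`.

## CLI

```sh
qcs validate catalog.json                        # schema/invariant audit, nonzero exit on errors
qcs screen --catalog catalog.json --conditions a,b,c
qcs screen --interactive --log session.jsonl     # terminal screening session
qcs classify --catalog catalog.json --claims claims.csv        # JSONL per patient
qcs simulate --participants 10 --miss-rate 0.2 --seed 7 --out trials.csv
qcs evaluate --trials trials.csv --survey survey.csv --report report.json
qcs fixtures --out fixtures/                     # export toy catalog, scenarios, reference trials
```

File formats:

* **Catalog** — JSON with `version`, `conditions` (array), `sets` (array of
  arrays of condition ids); see `src/qcs/data/catalog.schema.json`.
* **Claims** — CSV or JSONL with `patient_id, system, code`.
* **Trials CSV** — `participant_id, scenario_id, selected_ids, predicted,
  truth, mmapp_time_s, comparator_time_s` (`selected_ids` semicolon-delimited;
  optional `intended_ids` column, otherwise resolved from the built-in
  scenarios).
* **Survey CSV** — `participant_id, statement_id, rating`.

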