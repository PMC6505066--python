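# ehrdays

Build a standardized **patient-facility-day** dataset from raw multi-hospital
EHR extracts: reconstruct hospitalizations from specialty-transfer records,
harmonize laboratory tests and vital signs across facilities, derive per-day
medication indicators from hand-typed administration records, and compute
daily organ-dysfunction scores, two sepsis phenotypes, ventilation detection,
and hospitalization outcomes. A synthetic extract generator with known ground
truth makes the whole pipeline testable without access to any protected data.

## Data model

* **Specialty stay** — contiguous period under one treating specialty at one
  facility (the raw input interval).
* **Bedded stay** — consecutive specialty stays at one facility whose records
  abut exactly in time (an in-place specialty handoff).
* **Single-site hospitalization (SSH)** — maximal run of *acute* specialty
  stays at one facility, contiguous up to a configurable calendar gap
  (default 1 day); the primary analysis unit.
* **Acute hospitalization** — a patient's SSHs chained across facilities
  under the same gap rule (inter-facility transfers).
* **Episode of care** — bedded stays of any specialty chained the same way.
* **Patient-facility-day** — one row per patient per facility per calendar
  date (admission and discharge dates inclusive), carrying daily lab/vital
  extremes, drug indicators, organ scores, and an ICU-day flag. A same-day
  transfer yields one row per facility.

Four organ components (coagulation, liver, cardiovascular, renal) are scored
0–4 from the worst daily values; missing inputs yield missing scores, never
zeros. Organ failure is a score of 3–4. Sepsis is flagged two ways: a
claims-based definition (infection + organ-dysfunction codes, or an explicit
severe-sepsis/septic-shock code, with GEM-based code-list conversion between
ICD-9 and ICD-10) and an EHR-surveillance definition (blood culture anchored
by ≥4 consecutive systemic-antibiotic days plus concurrent organ
dysfunction). Ventilation is detected from procedure codes at the
hospitalization level only — day-level queries raise by design. Severity
components (age, admission diagnosis category, 30 comorbidity flags, 11
admission labs) are emitted without any composite score.

All clinically contestable inputs — specialty classifications, test
definitions (LOINC sets, name synonyms, units, plausible ranges), the drug
lexicon, scoring thresholds, surveillance-sepsis parameters, code lists —
live in editable configuration (`ehrdays.config`), seeded with standard
defaults.

## CLI

```bash
# synthetic raw extract (5 record tables + ground truth), deterministic per seed
ehrdays simulate --out raw/ --n-patients 200 --sepsis-prevalence 0.05 --seed 1

# full build: episodes -> physiology -> medications -> phenotypes
ehrdays build --in raw/ --out build/

# spot-check audit: recompute sampled days independently from raw records
ehrdays audit --in raw/ --build-dir build/ --n 50 --seed 1 --out audit.csv

# the fixed worked example (two facilities, same-day transfer, ICU day)
ehrdays demo --out demo/
```

`build` writes `patient_facility_days.csv`, `ssh.csv`, `phenotypes.csv`,
`acute_hospitalizations.csv`, `episodes_of_care.csv`, `risk_components.csv`,
per-stage audit reports under `audit/`, and a `manifest.txt` with the config
hash and per-stage row/rejection counts. Runs are byte-identical given
identical inputs and configuration. A YAML file passed via `--config` deep-
merges over any configuration section (see `ehrdays.config` for the schema).

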