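# Cohort file schemas

Both tables are comma-separated UTF-8 with a required header row.
Missing values are empty fields.  Flags are `1`/`0` (also accepted:
`true`/`false`, `yes`/`no`).  Times are **days since the pre-therapy
study** (time 0), not calendar dates; convert dates at the I/O boundary.

## baseline.csv — one row per patient

| column | type | notes |
|---|---|---|
| patient_id | string | unique, non-empty |
| age | number | years; must exceed 18 |
| stage | enum | `I`, `II`, `III` |
| laterality | enum | `left`, `right`, `bilateral` |
| hormone_receptor_positive | flag | ER and/or PR positive |
| post_menopausal | flag | |
| anthracycline_received | flag | |
| cumulative_anthracycline | number, optional | mg/m²; empty or 0 when not received |
| radiotherapy | flag | |
| diabetes | flag | |
| hypertension | flag | |
| dyslipidemia | flag | |
| current_smoker | flag | |
| ex_smoker | flag | |
| coronary_artery_disease | flag | |
| heart_failure_history | flag | |
| atrial_fibrillation | flag | |
| baseline_lvef | number | percent, in (0, 100] |
| baseline_modality | enum | `MUGA`, `echo` |
| troponin | number, optional | ng/L (high-sensitivity troponin I) |
| bnp | number, optional | pg/mL |

## lvef.csv — one row per LVEF measurement

| column | type | notes |
|---|---|---|
| patient_id | string | must have a baseline row |
| time | number | days since the pre-therapy study; ≥ 0 |
| lvef | number | percent, in (0, 100] |
| modality | enum | `MUGA`, `echo` |
| hf_symptoms | flag, optional | heart-failure symptoms at that visit; empty = not recorded (treated as absent) |

Constraints: each patient's series must contain a time-0 measurement;
(patient, time, modality) must be unique; a patient may switch
modalities mid-series (the adjudicator compares each follow-up to the
earliest measurement of its own modality by default).

## Outputs

* Exclusion log: TSV with `patient_id`, `reason`.
* Adjudication calls: TSV with `patient_id`, `definition`, `event`,
  `first_event_time`, `criterion`.
* Validation report: JSON keyed by `model::definition`, containing the
  incidence-by-category table, association test, AUC with 95% CI, and
  calibration points; all writers are bit-stable given fixed input.
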