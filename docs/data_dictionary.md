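# Data dictionary

All tables are CSV with ISO-8601 dates (`YYYY-MM-DD`). Intervals are closed
on both ends.

## Input tables

### persons.csv

| column | type | values |
|---|---|---|
| person_id | string | unique |
| birth_year | int | calendar year |
| sex | enum | `male`, `female` |
| qualification | enum | `no_vocational_training`, `vocational_training`, `master_craftsman`, `bachelor`, `diploma_master`, `phd`, `unknown`, `not_applicable` (= never employed) |
| income_group | enum | `low`, `middle`, `high`, `unknown` (optional; derived from `income_value` when absent) |
| income_value | float | pre-tax annual income in EUR; empty for `unknown` |

### spells.csv

| column | type | notes |
|---|---|---|
| person_id | string | must exist in persons.csv |
| start_date | date | first covered day |
| end_date | date | last covered day; `>= start_date` |

A person may have any number of spells; overlaps are merged.

### cases.csv

| column | type | notes |
|---|---|---|
| person_id | string | must exist in persons.csv |
| admission_date | date | one row per inpatient stay |
| main_dx | string | ICD-10 code, `A00`/`A00.0` shape |
| secondary_dx | string | semicolon-joined ICD-10 codes, may be empty |

## Report bundle (run_pipeline output)

* `cohort_sizes.csv` — subpopulation, n, pct_excluded_sequential,
  pct_excluded_cumulative.
* `selectivity_<stratifier>.csv` (`age_bin`, `qualification`,
  `income_group`) — stratum, sex, n_base, n_con, proportion_excluded,
  lookback_years (all lookbacks stacked).
* `age_summary.csv` — subpopulation, sex, median_age, q1_age, q3_age.
* `rates_crude.csv` — disease, subpopulation, sex, n_at_risk, n_cases,
  person_years, rate_per_10k.
* `rates_standardized.csv` — disease, subpopulation, sex, income_group,
  n_cases, person_years, standardized_rate_per_10k (BASE-standardized).
* `gradient.csv` — disease, subpopulation, sex, gradient_low_minus_high.
* `run_log.txt` — config hash, input row counts, per-stage counts.
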