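# Methods

This note documents the models and conventions behind `washout`: what is
computed, what the synthetic-data generator does and does not emulate, and
the choices made where the design was genuinely open.

## 1. Spell algebra and person-time

Insurance spells are **closed** day intervals `[start, end]` — both the
entrance and the leave date are covered days, matching the date semantics of
German claims extracts. All derived predicates reduce to day-set operations:

* *merge*: spells that overlap, touch, or are separated by at most
  `gap_tolerance_days` uncovered days are unioned. The default tolerance is
  0 — "continuously insured" is read literally. The parameter exists because
  real extracts often contain 1-day administrative gaps between contiguous
  memberships; pass `gap_tolerance_days=1` to bridge them.
* *continuous coverage* of calendar years `[y1, y2]`: one merged spell
  covers Jan 1 of `y1` through Dec 31 of `y2`.
* *person-days/-years*: covered days in the index year divided by the year's
  true length (365 or 366), so a fully covered leap year is 1.0
  person-years.

## 2. Cohorts

`BASE` is everyone aged ≥ `min_age` (default 25, by birth-year arithmetic —
claims extracts carry birth year, not birth date) insured at least one day
of the index year. `CONk` additionally requires continuous coverage of the
`k` preceding **calendar years** (not rolling 365-day windows). Because a
longer window implies every shorter one, the cohorts nest; the nesting is an
enforced invariant and a property test.

Exclusion percentages are reported in both conventions found in practice —
sequential (each subpopulation vs the previous one) and cumulative (vs
BASE) — explicitly labelled, since the two are easily confused. Rounding of
reported percentages is half-up at one decimal, the convention of printed
tables (Python's built-in `round` is half-to-even and would disagree on
exact .5 cases).

## 3. Case definition and washout

Index cases are inpatient stays in the index year whose **main diagnosis**
matches the codeset (first treatment of MI/stroke is almost always
inpatient, so hospital main diagnoses identify onset): MI = I21 prefix,
stroke = I60–I64 prefixes, matched on normalized codes (uppercase; `I21`
matches `I21.0` … `I21.9`). The washout flags every person with a
main-diagnosis match in the lookback window, plus — for MI — anyone whose
window stay carries I25.2 ("old myocardial infarction") in **any** diagnosis
position. Flagged persons leave numerator *and* denominator: they are not at
risk of a first event. BASE (k = 0) applies no history correction.

Open points resolved as defaults with config switches:

* The I25.2 search window defaults to the lookback window;
  `full_history=True` searches all data before the index year.
* Person-time defaults to the person's full insured time in the index year
  (`censor_at_event=False`): study populations in this design are
  person-based with ~99% full-year coverage among the lookback cohorts, and
  prior-event persons are removed for the whole year rather than
  part-censored (a washed-out person is "not any more at risk", not at risk
  until their event). Conventional incidence practice censors at the event;
  `censor_at_event=True` does that, and with annual event probabilities
  under 1% it moves rates by well under 1%.

## 4. Standardization and the gradient

Direct age standardization weights age-bin-specific rates by the **BASE**
population's per-sex person-year shares over 5-year bins (25–29 … 95+).
Using BASE as the standard makes "standardized BASE rate = crude BASE rate"
an exact identity (a regression test), and income-stratified rates use the
same per-sex weights for every income group, so differences between income
groups are not age artifacts. Bins with no person-time in a target stratum
are dropped and the remaining weights renormalized, with a logged warning.
The social gradient is `rate(low) − rate(high)` of standardized rates.

For directional tests, the sampling noise of a BASE-vs-CONk comparison is
approximated by splitting each bin's cases into retained and excluded
independent Poisson counts: for rates `r_F = c_F / Y_F` (full) and
`r_R = c_R / Y_R` (restricted subset),
`Var(r_F − r_R) ≈ c_E / Y_F² + c_R (1/Y_F − 1/Y_R)²` with `c_E = c_F − c_R`;
weighted bin-wise aggregation gives the SE of a standardized-gradient
change. This paired form is what makes small rate shifts testable — the two
populations share almost all their cases.

## 5. The synthetic claims generator

The generator states a world; analyses then measure it. Per person and
calendar year over `[index_year − history_years, index_year]`:

* **Demographics.** Ages ≥ 25 from a 15-bin distribution matching the
  10-year margins of a large German statutory fund (about 19% aged 25–34
  down to 4.8% aged 85+); 51.3% women; 50.8% with an employment episode
  (only those carry one of the seven qualification levels); income groups
  low/middle/high/unknown at 19/28/20/34%. Income values are drawn uniformly
  within the group bounds (low < 14,000 €, high > 29,000 € up to the 76,200 €
  contribution ceiling, the 2017 German reference values); "unknown" has no
  value — in reality the co-insured, unemployed and marginally employed.
* **Churn.** Everyone is enrolled at the start of the window. Each year a
  member exits with probability `expit(intercept + slope·age + δ_unknown +
  δ_precarious)` at a uniform-random day; a former member re-joins with
  probability `entry_prob` at a uniform-random day (a new spell — the
  left-censoring single-fund data show). Whoever is outside the fund when
  the index year arrives re-joins during it, so the generated population
  *is* the index-year fund population (BASE by construction); members can
  still exit during the index year (~7% do, mirroring the ~93% full-year
  coverage of real BASE populations). Death is not modelled separately: an
  exit is an exit, whatever its reason, since no downstream analysis
  distinguishes them.
* **Hospitalizations.** Annual first-event probabilities per 5-year age bin
  (reference: male, high income), multiplied by income-group multipliers
  (low ≥ middle ≥ high), a sex multiplier, and the precarious multiplier,
  prorated by the insured fraction of the year (constant per-day hazard) and
  clipped to [0, 1]. After a first event the annual probability is scaled by
  `recurrence_multiplier`. Events are dated uniformly within the insured part
  of the year, so no case falls outside coverage. Background
  (non-cardiovascular) admissions occur at a flat prorated rate; after an
  MI they carry I25.2 as a secondary diagnosis with probability `i252_prob`.
* **Determinism.** One `numpy` generator seeded from the config; identical
  configs give byte-identical tables.

### The `selective_churn_scenario` preset

This preset is calibrated — by design, before any test was frozen — to the
qualitative selection-bias pattern reported for single-fund claims data:

* churn `expit(−0.84 − 0.062·age)`, + 0.45 on the logit for unknown income,
  + 1.50 for the precarious subgroup; re-entry 0.5/year. This yields ~10%/yr
  discontinuity at age 27 falling below 1%/yr above 80, so a 5-year lookback
  excludes ~41% of ages 25–44 but only 1–3% of ages 75+ at one year —
  the ranges reported for large single-fund claims populations.
* precarious prevalence 0.50 / 0.20 / 0.03 / 0.25 in the low / middle /
  high / unknown income groups, hazard multiplier 3.0. This latent subgroup
  is the load-bearing mechanism: exclusion that is selective *within* an
  income stratum is the only way a lookback can move that stratum's
  age-standardized rate, and tying high churn to high risk inside the
  low-income group is what narrows the gradient. The
  `income_independent_churn_scenario` twin (same hazards, churn from age
  only) is the built-in counterfactual in which the gradient stays flat.
* hazards roughly 2–3× real-world German MI/stroke incidence. The package is
  exercised at desk scale (1–2·10⁵ persons standing in for a 2·10⁶-person
  fund); inflating hazards keeps case counts — and thus the power of the
  3·SE directional tests — comparable to the original setting. Absolute
  rates from this preset are therefore *not* epidemiologically meaningful;
  only directions and relative changes are.
* `pre_index_hazard_scale = 0.03`: hazards before the index year are scaled
  down so that prior-event prevalence stays at realistic low levels despite
  the inflated index-year hazards. This matters: washing out prevalent cases
  removes disproportionately high-frailty (precarious) persons, which would
  otherwise depress CONk rates and narrow the gradient even under
  frailty-independent churn, contaminating both counterfactual checks. At
  0.03 the washout machinery stays exercised (hundreds of flagged persons at
  n = 2·10⁵) while being rate-neutral to within sampling noise.
  `recurrence_multiplier` is 1.0 in this preset for the same reason (1.5 in
  `default_scenario`, where no counterfactual comparison is made).

### What a green test does — and does not — establish

The generator emulates the *mechanisms* (age/SES-selective churn, left/right
censoring, age- and SES-graded hazards, history codes), not the original
data: no family co-insurance structure, no regional structure, no secular
trends, sex-independent income distributions, churn constant across
history years, at most one event per disease per year. Green directional
tests establish that the pipeline detects the selection biases in a world
known to contain them — not that any particular real dataset has biases of
that size.

## 6. Numerical conventions

* Dates are `datetime64[D]`/`Timestamp`; intervals closed on both ends.
* Rates: per 10,000 person-years; reported tables round rates to one
  decimal; internal computation is unrounded.
* `percent_excluded` and composition percentages: half-up rounding via
  `decimal` (exact, no binary-float .5 artifacts).
* Quartiles of age: linear interpolation between order statistics
  (`numpy.percentile` default).
* Degenerate inputs: zero person-time yields NaN rates (flagged, never
  divided); empty base strata are kept with NaN proportions; an empty
  population yields all-zero cohort sizes.

## 7. Known limitations

* Everything in "what a green test does not establish" above.
* Qualification is drawn independently of income and age.
* The churn logistic cannot express a plateau among the working-age with a
  sharp drop at retirement; calibration to both the young and the old
  exclusion ranges leaves the middle-aged pattern an interpolation.
* Fatal events before hospital admission are invisible by design (inpatient
  main diagnoses only), as in the data this emulates.
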