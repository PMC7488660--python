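"""Generate a synthetic single-fund claims dataset and look at its shape.

Simulates 20,000 insured persons aged 25+ over the years 2012-2017 with
age-dependent fund switching (churn) and cardiovascular hospitalization
hazards, then writes the three claims tables as CSV.
"""

from pathlib import Path

from washout import generate_scenario, selective_churn_scenario, write_tables

config = selective_churn_scenario(n_persons=20_000, seed=1)
persons, spells, cases = generate_scenario(config)

out = Path("scratch/example_data")
paths = write_tables(persons, spells, cases, out)

print(f"persons: {len(persons):>7,} rows -> {paths['persons']}")
print(f"spells:  {len(spells):>7,} rows -> {paths['spells']}")
print(f"cases:   {len(cases):>7,} rows -> {paths['cases']}")

# Spell boundaries are fund exits/entries; more spells than persons means
# some people interrupted their membership during 2012-2017.
multi = spells.groupby("person_id").size().gt(1).sum()
print(f"\npersons with interrupted insurance history: {multi:,} "
      f"({100 * multi / len(persons):.1f}%)")

acute = cases["main_dx"].str.startswith(("I21", "I6"))
print(f"acute MI/stroke stays: {int(acute.sum()):,}; "
      f"other admissions: {int((~acute).sum()):,}")
print("\nEvery case happens on an insured day, and every person is insured at "
      "least one day of 2017 - the generated table is an index-year fund "
      "population.")
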