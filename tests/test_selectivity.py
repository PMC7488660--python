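"""Selectivity tables: income classification, composition shares, exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from washout.bins import FIVE_YEAR_BINS, TEN_YEAR_BINS
from washout.selectivity import (
    IncomeClassification,
    age_summary,
    classify_income,
    classify_income_values,
    column_percentages,
    composition_percentages,
    exclusion_by_stratum,
)


class TestIncomeClassification:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (13_999, "low"),       # just under the 40%-of-average bound
            (14_000, "middle"),    # bound itself is not low
            (29_000, "middle"),    # bound itself is not high
            (29_001, "high"),      # just above the 80%-of-average bound
            (None, "unknown"),
            (float("nan"), "unknown"),
            (0, "low"),
        ],
    )
    def test_bounds(self, value, expected):
        assert classify_income(value) == expected

    def test_negative_income_is_a_data_error(self):
        with pytest.raises(ValueError):
            classify_income(-1.0)
        with pytest.raises(ValueError):
            classify_income_values(pd.Series([1000.0, -5.0]))

    def test_vectorized_agrees_with_scalar(self):
        values = pd.Series([0, 13_999, 14_000, 22_000, 29_000, 29_001, None])
        got = classify_income_values(values)
        want = [classify_income(v) for v in values]
        assert list(got) == want

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError):
            IncomeClassification(low_bound=30_000, high_bound=29_000)


class TestAgeBins:
    def test_five_year_labels(self):
        labels = FIVE_YEAR_BINS.labels
        assert labels[0] == "25-29"
        assert labels[-1] == "95+"
        assert len(labels) == 15

    def test_every_age_maps_to_one_bin(self):
        ages = np.arange(25, 120)
        idx = FIVE_YEAR_BINS.assign_index(ages)
        assert idx.min() == 0 and idx.max() == 14
        assert (np.diff(idx) >= 0).all()
        with pytest.raises(ValueError):
            FIVE_YEAR_BINS.assign_index(np.array([24]))


# Printed population-description counts (2017 base population of a large
# German statutory fund); the shares are the published percentages.
TABLE1_AGE = pd.DataFrame(
    {
        "male": [210_541, 169_466, 210_458, 178_316, 112_623, 95_961, 26_696],
        "female": [184_730, 153_846, 197_943, 176_663, 126_146, 145_101, 71_905],
    },
    index=["25-34", "35-44", "45-54", "55-64", "65-74", "75-84", "85+"],
)
TABLE1_QUAL = pd.DataFrame(
    {
        "male": [73_708, 332_122, 23_390, 7_143, 19_090, 1_300, 143_795],
        "female": [54_278, 265_326, 8_280, 7_177, 21_549, 1_047, 89_488],
    },
    index=[
        "no_vocational_training", "vocational_training", "master_craftsman",
        "bachelor", "diploma_master", "phd", "unknown",
    ],
)


def test_column_percentages_reproduce_published_age_shares():
    pct = column_percentages(TABLE1_AGE)
    assert pct.loc["25-34", "male"] == 21.0
    assert pct.loc["35-44", "male"] == 16.9
    assert pct.loc["45-54", "male"] == 21.0
    assert pct.loc["85+", "male"] == 2.7
    assert pct.loc["25-34", "female"] == 17.5
    assert pct.loc["85+", "female"] == 6.8
    assert pct["male"].sum() == pytest.approx(100.0, abs=0.3)


def test_column_percentages_reproduce_published_qualification_shares():
    pct = column_percentages(TABLE1_QUAL)
    assert pct.loc["vocational_training", "male"] == 55.3
    assert pct.loc["vocational_training", "female"] == 59.3
    assert pct.loc["unknown", "male"] == 23.9
    assert pct.loc["no_vocational_training", "female"] == 12.1


def test_single_stratum_is_100_percent():
    assert column_percentages(pd.Series({"only": 42}))["only"] == 100.0
    with pytest.raises(ValueError):
        column_percentages(pd.Series({"only": 0}))


def test_composition_percentages_on_golden(golden_tables):
    persons, _, _ = golden_tables
    comp = composition_percentages(
        persons, "income_group", index_year=2017, by_sex=False
    ).set_index("stratum")
    # 10 persons: 3 low, 2 middle, 2 high, 3 unknown
    assert comp.loc["low", "n"] == 3
    assert comp.loc["low", "pct_n"] == 30.0
    assert comp["pct_n"].sum() == pytest.approx(100.0, abs=0.2)
    # qualification table only covers the ever-employed (7 of 10)
    qual = composition_percentages(
        persons, "qualification", index_year=2017, by_sex=False
    )
    assert qual["n"].sum() == 7


def test_exclusion_by_stratum_matches_hand_count(golden_tables, golden_assignments):
    persons, _, _ = golden_tables
    # by hand at k=5: low {P01,P05,P08}: P05 excluded -> 1/3;
    # middle {P04,P06}: P06 excluded -> 1/2; high {P03,P09}: P09 -> 1/2;
    # unknown in base {P02,P07}: both excluded -> 2/2
    table = exclusion_by_stratum(
        golden_assignments, persons, "income_group", k=5, by_sex=False
    ).set_index("stratum")
    assert table.loc["low", "proportion_excluded"] == pytest.approx(1 / 3)
    assert table.loc["middle", "proportion_excluded"] == pytest.approx(0.5)
    assert table.loc["high", "proportion_excluded"] == pytest.approx(0.5)
    assert table.loc["unknown", "proportion_excluded"] == pytest.approx(1.0)
    assert (table["n_base"] >= table["n_con"]).all()


def test_exclusion_is_monotone_in_lookback(golden_tables, golden_assignments):
    persons, _, _ = golden_tables
    tables = {
        k: exclusion_by_stratum(
            golden_assignments, persons, "age_bin", k, index_year=2017,
            by_sex=False,
        ).set_index("stratum")["proportion_excluded"]
        for k in (1, 3, 5)
    }
    joint = pd.concat(tables, axis=1).dropna()
    assert (joint[3] >= joint[1] - 1e-12).all()
    assert (joint[5] >= joint[3] - 1e-12).all()


def test_empty_base_stratum_is_flagged_not_divided(golden_tables,
                                                   golden_assignments):
    persons, _, _ = golden_tables
    table = exclusion_by_stratum(
        golden_assignments, persons, "age_bin", k=1, index_year=2017,
        by_sex=False,
    ).set_index("stratum")
    empty = table[table["n_base"] == 0]
    assert len(empty) > 0  # most 5-year bins are unpopulated in a 10-person set
    assert empty["proportion_excluded"].isna().all()


def test_unknown_stratifier_raises(golden_tables, golden_assignments):
    persons, _, _ = golden_tables
    with pytest.raises(ValueError, match="stratifier"):
        exclusion_by_stratum(golden_assignments, persons, "shoe_size", 1)


class TestAgeSummary:
    def test_single_person(self):
        persons = pd.DataFrame({"person_id": ["a"], "birth_year": [1966]})
        assert age_summary(persons, 2017) == (51, 51, 51)

    def test_uniform_range_median(self):
        persons = pd.DataFrame(
            {"person_id": range(51), "birth_year": 2017 - np.arange(25, 76)}
        )
        med, q1, q3 = age_summary(persons, 2017)
        assert med == 50.0

    @given(st.lists(st.integers(25, 99), min_size=1, max_size=40))
    def test_matches_sorted_order_statistics(self, ages):
        persons = pd.DataFrame(
            {"person_id": range(len(ages)),
             "birth_year": [2017 - a for a in ages]}
        )
        med, q1, q3 = age_summary(persons, 2017)
        assert q1 <= med <= q3
        assert med == float(np.median(sorted(ages)))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            age_summary(pd.DataFrame({"person_id": [], "birth_year": []}), 2017)
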