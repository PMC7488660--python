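"""Case finding, washout adjustment, rates and standardization."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from washout import (
    MI,
    STROKE,
    build_cohorts,
    generate_scenario,
    null_scenario,
    rate_analysis,
)
from washout.incidence import (
    crude_rate,
    find_index_cases,
    find_lookback_events,
    income_gradient,
    normalize_icd,
    paired_rate_diff_se,
    person_years_in_year,
    standardized_rate,
    washout_adjust,
)


def _case(pid, date, main, secondary=""):
    return {
        "person_id": pid,
        "admission_date": pd.Timestamp(date),
        "main_dx": main,
        "secondary_dx": secondary,
    }


class TestCaseFinding:
    def test_acute_mi_main_diagnosis_is_a_case(self):
        cases = pd.DataFrame([_case("a", "2017-02-01", "I21.4")])
        found = find_index_cases(cases, MI, 2017)
        assert list(found.index) == ["a"]

    def test_history_code_alone_is_not_an_index_case(self):
        cases = pd.DataFrame([_case("a", "2017-02-01", "I25.2")])
        assert find_index_cases(cases, MI, 2017).empty

    def test_event_outside_index_year_is_not_a_case(self):
        cases = pd.DataFrame([_case("a", "2016-02-01", "I63.3")])
        assert find_index_cases(cases, STROKE, 2017).empty

    def test_earliest_admission_is_kept(self):
        cases = pd.DataFrame(
            [_case("a", "2017-08-01", "I21.0"), _case("a", "2017-03-05", "I21.9")]
        )
        found = find_index_cases(cases, MI, 2017)
        assert found["a"] == pd.Timestamp("2017-03-05")

    def test_malformed_code_is_a_data_error(self):
        cases = pd.DataFrame([_case("a", "2017-02-01", "21.4")])
        with pytest.raises(ValueError, match="malformed"):
            find_index_cases(cases, MI, 2017)
        with pytest.raises(ValueError):
            normalize_icd("I2")
        assert normalize_icd(" i21.4 ") == "I21.4"

    @pytest.mark.parametrize(
        "year, k, flagged",
        [
            (2015, 1, False),  # 2015 event outside the 1-year window (2016)
            (2015, 3, True),   # inside the 3-year window 2014-2016
            (2016, 1, True),
            (2012, 5, True),
            (2011, 5, False),
        ],
    )
    def test_lookback_window_is_calendar_years(self, year, k, flagged):
        cases = pd.DataFrame([_case("a", f"{year}-06-15", "I21.9")])
        got = find_lookback_events(cases, MI, 2017, k)
        assert ("a" in got) == flagged

    def test_secondary_i252_flags_mi_history(self):
        cases = pd.DataFrame(
            [_case("a", "2016-06-15", "J18.9", "I25.2"),
             _case("b", "2016-06-15", "J18.9", "E11.9;I25.20")]
        )
        got = find_lookback_events(cases, MI, 2017, 1, use_secondary_history=True)
        assert set(got) == {"a", "b"}
        off = find_lookback_events(cases, MI, 2017, 1, use_secondary_history=False)
        assert off.empty
        # stroke defines no history codes, so nothing is flagged
        assert find_lookback_events(cases, STROKE, 2017, 1).empty

    def test_full_history_extends_beyond_the_window(self):
        cases = pd.DataFrame([_case("a", "2013-06-15", "J18.9", "I25.2")])
        assert find_lookback_events(cases, MI, 2017, 1).empty
        got = find_lookback_events(cases, MI, 2017, 1, full_history=True)
        assert set(got) == {"a"}


class TestWashout:
    def test_flagged_person_removed_from_both_counts(self):
        subpop = pd.Index(["a", "b", "c"])
        index_cases = pd.Series(
            {"a": pd.Timestamp("2017-02-01"), "b": pd.Timestamp("2017-03-01")}
        )
        at_risk, incident = washout_adjust(subpop, index_cases, pd.Index(["a"]))
        assert set(at_risk) == {"b", "c"}
        assert set(incident.index) == {"b"}

    def test_empty_flag_set_changes_nothing(self):
        subpop = pd.Index(["a", "b"])
        index_cases = pd.Series({"a": pd.Timestamp("2017-02-01")})
        at_risk, incident = washout_adjust(subpop, index_cases, pd.Index([]))
        assert list(at_risk) == ["a", "b"]
        assert set(incident.index) == {"a"}

    def test_eight_person_fixture_matches_hand_enumeration(self):
        # persons a..h in the subpopulation; c,d had lookback events;
        # index cases: a, c, e.  By hand: at risk {a,b,e,f,g,h}, incident {a,e}.
        subpop = pd.Index(list("abcdefgh"))
        index_cases = pd.Series(
            {p: pd.Timestamp("2017-05-01") for p in ["a", "c", "e"]}
        )
        at_risk, incident = washout_adjust(subpop, index_cases,
                                           pd.Index(["c", "d"]))
        assert set(at_risk) == set("abefgh")
        assert set(incident.index) == {"a", "e"}
        assert set(incident.index) <= set(at_risk) <= set(subpop)


class TestRates:
    def test_five_cases_in_ten_thousand_person_years(self):
        assert crude_rate(5, 10_000.0) == pytest.approx(5.0)
        assert crude_rate(0, 123.0) == 0.0
        assert np.isnan(crude_rate(3, 0.0))

    def test_person_years_full_and_partial(self):
        spells = pd.DataFrame(
            {
                "person_id": ["a", "b"],
                "start_date": [pd.Timestamp("2016-06-01"),
                               pd.Timestamp("2017-05-01")],
                "end_date": [pd.Timestamp("2018-01-31"),
                             pd.Timestamp("2017-12-31")],
            }
        )
        py = person_years_in_year(spells, 2017, pd.Index(["a", "b", "c"]))
        assert py["a"] == pytest.approx(1.0)
        assert py["b"] == pytest.approx(245 / 365)
        assert py["c"] == 0.0

    def test_censoring_stops_person_time_at_the_event(self):
        spells = pd.DataFrame(
            {
                "person_id": ["a"],
                "start_date": [pd.Timestamp("2017-01-01")],
                "end_date": [pd.Timestamp("2017-12-31")],
            }
        )
        censor = pd.Series({"a": pd.Timestamp("2017-03-10")})
        py = person_years_in_year(spells, 2017, pd.Index(["a"]),
                                  censor_dates=censor)
        assert py["a"] == pytest.approx(69 / 365)


class TestStandardization:
    def test_equal_bin_rates_standardize_to_that_rate(self):
        rates = pd.Series({"25-29": 7.5, "30-34": 7.5, "35-39": 7.5})
        weights = pd.Series({"25-29": 0.2, "30-34": 0.5, "35-39": 0.3})
        assert standardized_rate(rates, weights) == pytest.approx(7.5)

    def test_two_bin_arithmetic(self):
        rates = pd.Series({"young": 10.0, "old": 30.0})
        weights = pd.Series({"young": 0.25, "old": 0.75})
        assert standardized_rate(rates, weights) == pytest.approx(25.0)

    def test_empty_bins_renormalize_with_warning(self, caplog):
        rates = pd.Series({"young": 10.0, "mid": np.nan, "old": 30.0})
        weights = pd.Series({"young": 0.25, "mid": 0.4, "old": 0.35})
        with caplog.at_level("WARNING", logger="washout.incidence"):
            got = standardized_rate(rates, weights)
        assert got == pytest.approx((0.25 * 10 + 0.35 * 30) / 0.6)
        assert any("renormalizing" in r.message for r in caplog.records)

    def test_split_bin_with_identical_rates_is_invariant(self):
        rates = pd.Series({"a": 12.0, "b": 40.0})
        weights = pd.Series({"a": 0.6, "b": 0.4})
        split_rates = pd.Series({"a1": 12.0, "a2": 12.0, "b": 40.0})
        split_weights = pd.Series({"a1": 0.35, "a2": 0.25, "b": 0.4})
        assert standardized_rate(split_rates, split_weights) == pytest.approx(
            standardized_rate(rates, weights)
        )

    def test_gradient_is_low_minus_high(self):
        assert income_gradient(
            pd.Series({"low": 30.0, "middle": 20.0, "high": 14.8})
        ) == pytest.approx(15.2)
        assert income_gradient(pd.Series({"low": 5.0, "high": 5.0})) == 0.0
        with pytest.raises(KeyError):
            income_gradient(pd.Series({"low": 5.0}))


@pytest.fixture(scope="module")
def mi_result(golden_tables, golden_assignments):
    persons, spells, cases = golden_tables
    return rate_analysis(persons, spells, cases, golden_assignments, MI, 2017)


@pytest.fixture(scope="module")
def stroke_result(golden_tables, golden_assignments):
    persons, spells, cases = golden_tables
    return rate_analysis(persons, spells, cases, golden_assignments,
                         STROKE, 2017)


class TestGoldenAnalysis:
    """The 10-person fixture, enumerated by hand."""

    def test_mi_counts(self, mi_result):
        crude = mi_result["crude"].groupby("subpopulation")[
            ["n_at_risk", "n_cases", "person_years"]
        ].sum()
        # BASE: 9 at risk, cases P01,P04,P06
        assert crude.loc["BASE", "n_at_risk"] == 9
        assert crude.loc["BASE", "n_cases"] == 3
        assert crude.loc["BASE", "person_years"] == pytest.approx(7 + 459 / 365)
        # CON1: P04 washed out (2016 MI); incident P01,P06
        assert crude.loc["CON1", "n_at_risk"] == 5
        assert crude.loc["CON1", "n_cases"] == 2
        assert crude.loc["CON1", "person_years"] == pytest.approx(4 + 214 / 365)
        # CON3/CON5: P06 additionally flagged via the I25.2 stay in 2015
        assert crude.loc["CON3", "n_at_risk"] == 3
        assert crude.loc["CON3", "n_cases"] == 1
        assert crude.loc["CON5", "n_at_risk"] == 3
        assert crude.loc["CON5", "n_cases"] == 1

    def test_stroke_counts(self, stroke_result):
        crude = stroke_result["crude"].groupby("subpopulation")[
            ["n_at_risk", "n_cases", "person_years"]
        ].sum()
        assert crude.loc["BASE", "n_cases"] == 2          # P03, P07
        assert crude.loc["CON1", "n_at_risk"] == 6        # nobody flagged
        assert crude.loc["CON1", "n_cases"] == 1          # P07 not in CON1
        assert crude.loc["CON3", "n_at_risk"] == 4        # P08 washed out
        assert crude.loc["CON5", "n_at_risk"] == 3
        assert crude.loc["CON5", "person_years"] == pytest.approx(2 + 214 / 365)

    def test_invariant_incident_within_at_risk(self, mi_result):
        crude = mi_result["crude"]
        assert (crude["n_cases"] <= crude["n_at_risk"]).all()
        assert (crude["person_years"] <= crude["n_at_risk"]).all()


class TestNullScenarioIdentity:
    def test_rates_identical_across_lookbacks(self):
        """No churn and no pre-index events: washout removes nobody, so the
        crude and standardized rates agree across BASE/CON1/CON3/CON5 to
        machine precision."""
        cfg = null_scenario(n_persons=10_000, seed=21)
        persons, spells, cases = generate_scenario(cfg)
        assignments = build_cohorts(persons, spells, cfg.index_year)
        for codeset in (MI, STROKE):
            result = rate_analysis(persons, spells, cases, assignments,
                                   codeset, cfg.index_year)
            crude = result["crude"].pivot(index="sex",
                                          columns="subpopulation",
                                          values="rate_per_10k")
            for col in ("CON1", "CON3", "CON5"):
                assert np.allclose(crude[col], crude["BASE"], rtol=0, atol=1e-12)
            grad = result["gradient"].pivot(index="sex",
                                            columns="subpopulation",
                                            values="gradient_low_minus_high")
            for col in ("CON1", "CON3", "CON5"):
                assert np.allclose(grad[col], grad["BASE"], rtol=0, atol=1e-9)

    def test_standardized_base_equals_crude_base(self):
        cfg = null_scenario(n_persons=10_000, seed=22)
        persons, spells, cases = generate_scenario(cfg)
        assignments = build_cohorts(persons, spells, cfg.index_year)
        result = rate_analysis(persons, spells, cases, assignments, MI,
                               cfg.index_year)
        crude = result["crude"].set_index(["subpopulation", "sex"])
        pooled = result["standardized_pooled"].set_index(
            ["subpopulation", "sex"]
        )
        for sex in ("male", "female"):
            assert pooled.loc[("BASE", sex), "standardized_rate_per_10k"] == (
                pytest.approx(crude.loc[("BASE", sex), "rate_per_10k"],
                              rel=1e-12)
            )


def test_paired_rate_diff_se_shrinks_with_case_count():
    wide = paired_rate_diff_se(100, 10_000, 80, 8_000)
    narrow = paired_rate_diff_se(10_000, 1_000_000, 8_000, 800_000)
    assert narrow < wide
    assert np.isnan(paired_rate_diff_se(5, 0.0, 5, 10.0))
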