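"""Selectivity of lookback preconditions: who gets excluded.

Quantifies how the composition of the study population shifts when a
continuous-insurance precondition is applied: exclusion proportions per
stratum (age bin, occupational qualification, income group), column-percent
composition tables, and age summaries.  Qualification analyses are restricted
to persons with at least one employment episode (``qualification !=
"not_applicable"``), since insurance funds only hold qualification data for
the ever-employed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .bins import FIVE_YEAR_BINS, TEN_YEAR_BINS, AgeBinScheme
from .cohorts import con_column

__all__ = [
    "IncomeClassification",
    "classify_income",
    "classify_income_values",
    "exclusion_by_stratum",
    "composition_percentages",
    "column_percentages",
    "age_summary",
    "round_half_up",
]

STRATIFIERS = ("age_bin", "qualification", "income_group")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at ``decimals`` places (report convention;
    Python's built-in ``round`` rounds half to even)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IncomeClassification:
    """Absolute annual pre-tax income bounds separating low / middle / high.

    Defaults are the 2017 German reference values: below 40% of the national
    average income (14,000 EUR) is *low*, above 80% (29,000 EUR) is *high*,
    in between is *middle*; persons without an income value are *unknown*.
    """

    low_bound: float = 14_000.0
    high_bound: float = 29_000.0

    def __post_init__(self) -> None:
        if not (0 < self.low_bound < self.high_bound):
            raise ValueError("need 0 < low_bound < high_bound")


def classify_income(value, classification: IncomeClassification | None = None) -> str:
    """Income group of a single value; ``None``/NaN maps to ``"unknown"``."""
    c = classification or IncomeClassification()
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    if value < 0:
        raise ValueError(f"negative income value: {value}")
    if value < c.low_bound:
        return "low"
    if value > c.high_bound:
        return "high"
    return "middle"


def classify_income_values(
    values: pd.Series, classification: IncomeClassification | None = None
) -> pd.Series:
    """Vectorized :func:`classify_income` over a Series."""
    c = classification or IncomeClassification()
    v = pd.to_numeric(values, errors="coerce")
    if (v.dropna() < 0).any():
        bad = values[v < 0].iloc[0]
        raise ValueError(f"negative income value: {bad}")
    out = pd.Series("middle", index=values.index, dtype=object)
    out[v < c.low_bound] = "low"
    out[v > c.high_bound] = "high"
    out[v.isna()] = "unknown"
    return out


def _stratum_values(
    persons: pd.DataFrame,
    stratifier: str,
    index_year: int | None,
    age_bins: AgeBinScheme,
) -> tuple[pd.DataFrame, pd.Series]:
    """Relevant person subset and its stratum labels for a stratifier."""
    if stratifier == "age_bin":
        if index_year is None:
            raise ValueError("index_year is required for the age_bin stratifier")
        ages = index_year - persons["birth_year"]
        subset = persons[ages >= age_bins.min_age]
        strata = pd.Series(
            age_bins.assign_labels(index_year - subset["birth_year"]),
            index=subset.index,
        )
    elif stratifier == "qualification":
        subset = persons[persons["qualification"] != "not_applicable"]
        strata = subset["qualification"]
    elif stratifier == "income_group":
        subset = persons
        strata = subset["income_group"]
    else:
        raise ValueError(
            f"unknown stratifier {stratifier!r}; expected one of {STRATIFIERS}"
        )
    return subset, strata


def exclusion_by_stratum(
    assignments: pd.DataFrame,
    persons: pd.DataFrame,
    stratifier: str,
    k: int,
    index_year: int | None = None,
    by_sex: bool = True,
    age_bins: AgeBinScheme = FIVE_YEAR_BINS,
) -> pd.DataFrame:
    """Proportion of the base population excluded by the CONk precondition,
    per stratum (optionally per sex).

    Returns one row per stratum (x sex) with ``n_base``, ``n_con`` and
    ``proportion_excluded = (n_base - n_con) / n_base``; strata with an empty
    base are kept with a NaN proportion rather than divided.
    """
    subset, strata = _stratum_values(persons, stratifier, index_year, age_bins)
    flags = assignments.reindex(subset["person_id"])
    in_base = flags["in_base"].eq(True).to_numpy(dtype=bool)
    in_con = flags[con_column(k)].eq(True).to_numpy(dtype=bool)

    frame = pd.DataFrame(
        {
            "stratum": strata.array,  # .array keeps the categorical dtype
            "in_base": in_base,
            "in_con": in_con,
        }
    )
    keys = ["stratum"]
    if by_sex:
        frame["sex"] = subset["sex"].to_numpy()
        keys.append("sex")
    grouped = frame.groupby(keys, observed=False)[["in_base", "in_con"]].sum()
    out = grouped.rename(columns={"in_base": "n_base", "in_con": "n_con"})
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = (out["n_base"] - out["n_con"]) / out["n_base"]
    out["proportion_excluded"] = prop.where(out["n_base"] > 0)
    out["lookback_years"] = k
    return out.reset_index()


def column_percentages(counts: pd.DataFrame | pd.Series, decimals: int = 1):
    """Column percentages of a counts table, rounded half-up.

    Each column of ``counts`` (or the single Series) is divided by its sum
    and expressed in percent; this is the arithmetic behind population-
    description tables that print a count and its share per sex column.
    """
    if isinstance(counts, pd.Series):
        total = counts.sum()
        if total <= 0:
            raise ValueError("counts must have a positive total")
        return (100.0 * counts / total).map(lambda v: round_half_up(v, decimals))
    out = {}
    for col in counts.columns:
        out[col] = column_percentages(counts[col], decimals)
    return pd.DataFrame(out, index=counts.index)


def composition_percentages(
    persons: pd.DataFrame,
    stratifier: str,
    index_year: int | None = None,
    by_sex: bool = True,
    age_bins: AgeBinScheme = TEN_YEAR_BINS,
    decimals: int = 1,
) -> pd.DataFrame:
    """Counts and column percentages of a person subset by stratum (x sex).

    Percentages are per sex column (or overall when ``by_sex`` is False) and
    sum to 100 up to rounding.
    """
    if persons.empty:
        raise ValueError("composition_percentages requires a non-empty subset")
    subset, strata = _stratum_values(persons, stratifier, index_year, age_bins)
    frame = pd.DataFrame({"stratum": strata.array})
    if by_sex:
        frame["sex"] = subset["sex"].to_numpy()
        counts = (
            frame.groupby(["stratum", "sex"], observed=False)
            .size()
            .unstack("sex", fill_value=0)
        )
    else:
        counts = frame.groupby("stratum", observed=False).size().to_frame("n")
    pct = column_percentages(counts, decimals)
    pct.columns = [f"pct_{c}" for c in pct.columns]
    counts.columns = [f"n_{c}" if by_sex else "n" for c in counts.columns]
    return pd.concat([counts, pct], axis=1).reset_index()


def age_summary(persons: pd.DataFrame, index_year: int) -> tuple[float, float, float]:
    """Median and quartiles (linear interpolation) of age in the index year.

    Returns ``(median, q1, q3)``.
    """
    if persons.empty:
        raise ValueError("age_summary requires a non-empty subset")
    ages = (index_year - persons["birth_year"]).to_numpy(dtype=float)
    q1, med, q3 = np.percentile(ages, [25, 50, 75])
    return float(med), float(q1), float(q3)
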