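"""Incident-case identification and lookback-adjusted incidence rates.

An *incident* case in the index year is an inpatient stay with a qualifying
main diagnosis and no qualifying event during the lookback window.  The
washout adjustment removes persons with a lookback event from **both** the
numerator and the denominator: someone who already had the event is no
longer at risk of a first occurrence.  For myocardial infarction the history
code I25.2 ("old myocardial infarction"), recorded in any diagnosis position
of a lookback-window stay, additionally flags a past event.

Rates are reported per 10,000 person-years.  Person-time is the insured time
within the index year; by default a case contributes their full insured year
(``censor_at_event=False`` — study populations in single-fund analyses are
person-based, with near-complete index-year coverage), optionally censored
at the first event date.  Direct age standardization uses the base
population's per-sex person-years by 5-year age bin as the standard weights,
so the standardized base rate reproduces the crude base rate exactly.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bins import FIVE_YEAR_BINS, AgeBinScheme
from .cohorts import con_column
from .spells import merge_spells_frame

__all__ = [
    "DiseaseCodeset",
    "MI",
    "STROKE",
    "CODESETS",
    "normalize_icd",
    "find_index_cases",
    "find_lookback_events",
    "washout_adjust",
    "person_years_in_year",
    "crude_rate",
    "age_specific_rates",
    "standardized_rate",
    "income_gradient",
    "rate_analysis",
    "paired_rate_diff_se",
    "gradient_narrowing",
]

logger = logging.getLogger(__name__)

_ICD_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")


@dataclass(frozen=True)
class DiseaseCodeset:
    """Diagnosis prefixes identifying acute events and disease history.

    ``main_prefixes`` match the main (discharge) diagnosis of an acute stay;
    ``history_secondary_prefixes`` match codes in any diagnosis position that
    document a past event (e.g. I25.2 for an old myocardial infarction).
    Matching is prefix-based on normalized codes, so ``I21`` covers I21,
    I21.0 ... I21.9.
    """

    name: str
    main_prefixes: tuple[str, ...]
    history_secondary_prefixes: tuple[str, ...] = ()


MI = DiseaseCodeset("MI", ("I21",), ("I25.2",))
STROKE = DiseaseCodeset("stroke", ("I60", "I61", "I62", "I63", "I64"))
CODESETS = {"MI": MI, "stroke": STROKE}


def normalize_icd(code: str) -> str:
    """Uppercase, whitespace-stripped ICD-10 code; raises on malformed input."""
    norm = str(code).strip().upper()
    if not _ICD_RE.match(norm):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return norm


def _normalize_column(codes: pd.Series, what: str) -> pd.Series:
    norm = codes.astype(str).str.strip().str.upper()
    bad = norm[~norm.str.match(_ICD_RE)]
    if len(bad):
        raise ValueError(
            f"malformed ICD-10 code in {what} at row {bad.index[0]}: "
            f"{codes.loc[bad.index[0]]!r}"
        )
    return norm


def _matches_prefix(codes: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    out = pd.Series(False, index=codes.index)
    for p in prefixes:
        out |= codes.str.startswith(p)
    return out


def find_index_cases(
    cases: pd.DataFrame, codeset: DiseaseCodeset, index_year: int
) -> pd.Series:
    """Earliest qualifying admission per person in the index year.

    A stay qualifies when its *main* diagnosis matches the codeset; history
    codes never create an index case.  Returns a Series mapping person_id to
    the first admission date.
    """
    adm = pd.to_datetime(cases["admission_date"])
    in_year = adm.dt.year == index_year
    main = _normalize_column(cases.loc[in_year, "main_dx"], "main_dx")
    hit = _matches_prefix(main, codeset.main_prefixes)
    sub = cases.loc[in_year].loc[hit]
    if sub.empty:
        return pd.Series(dtype="datetime64[ns]", name="first_event_date")
    first = (
        pd.to_datetime(sub["admission_date"])
        .groupby(sub["person_id"])
        .min()
        .rename("first_event_date")
    )
    return first


def find_lookback_events(
    cases: pd.DataFrame,
    codeset: DiseaseCodeset,
    index_year: int,
    lookback_years: int,
    use_secondary_history: bool = True,
    full_history: bool = False,
) -> pd.Index:
    """person_ids with a qualifying event during the lookback window.

    The window is the ``lookback_years`` calendar years immediately before
    the index year.  Flags persons with a main-diagnosis match, plus — when
    ``use_secondary_history`` and the codeset defines history prefixes —
    persons with a history code in *any* diagnosis position.  With
    ``full_history`` the search extends over all data before the index year
    instead of the lookback window only.
    """
    if lookback_years <= 0:
        raise ValueError("lookback_years must be positive")
    year = pd.to_datetime(cases["admission_date"]).dt.year
    if full_history:
        in_window = year < index_year
    else:
        in_window = (year >= index_year - lookback_years) & (year < index_year)
    sub = cases.loc[in_window]
    if sub.empty:
        return pd.Index([])
    main = _normalize_column(sub["main_dx"], "main_dx")
    flagged = _matches_prefix(main, codeset.main_prefixes)
    if use_secondary_history and codeset.history_secondary_prefixes:
        all_dx = main.str.cat(sub["secondary_dx"].fillna("").astype(str), sep=";")
        split = all_dx.str.split(";")
        hist = split.map(
            lambda codes: any(
                c.strip().upper().startswith(codeset.history_secondary_prefixes)
                for c in codes
                if c.strip()
            )
        )
        flagged |= hist
    return pd.Index(sub.loc[flagged, "person_id"].unique())


def washout_adjust(
    subpop_ids: pd.Index,
    index_cases: pd.Series,
    lookback_flagged: pd.Index,
) -> tuple[pd.Index, pd.Series]:
    """Remove lookback-flagged persons from numerator and denominator.

    Returns ``(at_risk_ids, incident_cases)`` where ``at_risk_ids`` is the
    subpopulation minus flagged persons and ``incident_cases`` keeps only
    index cases of at-risk persons (so incident ⊆ at-risk ⊆ subpopulation).
    """
    subpop_ids = pd.Index(subpop_ids)
    at_risk = subpop_ids.difference(pd.Index(lookback_flagged))
    incident = index_cases[index_cases.index.isin(at_risk)]
    return at_risk, incident


def person_years_in_year(
    spells: pd.DataFrame,
    index_year: int,
    person_ids: pd.Index | None = None,
    censor_dates: pd.Series | None = None,
    gap_tolerance_days: int = 0,
) -> pd.Series:
    """Insured person-years within the index year, per person.

    Person-years are covered days divided by the year's true length.  When
    ``censor_dates`` is given (person_id -> date), coverage after a person's
    date is not counted (their time at risk ends at the event).
    Persons in ``person_ids`` with no coverage get 0.
    """
    merged = merge_spells_frame(spells, gap_tolerance_days)
    if person_ids is not None:
        merged = merged[merged["person_id"].isin(pd.Index(person_ids))]
    ys = pd.Timestamp(dt.date(index_year, 1, 1))
    ye = pd.Timestamp(dt.date(index_year, 12, 31))
    year_len = (dt.date(index_year + 1, 1, 1) - dt.date(index_year, 1, 1)).days
    lo = merged["start_date"].clip(lower=ys)
    hi = merged["end_date"].clip(upper=ye)
    if censor_dates is not None and len(censor_dates):
        cd = merged["person_id"].map(censor_dates)
        hi = hi.where(cd.isna() | (hi <= cd), cd)
    days = ((hi - lo).dt.days + 1).clip(lower=0)
    py = days.groupby(merged["person_id"]).sum() / year_len
    if person_ids is not None:
        py = py.reindex(pd.Index(person_ids), fill_value=0.0)
    return py.rename("person_years")


def crude_rate(n_cases: int, person_years: float) -> float:
    """Events per 10,000 person-years; NaN when there is no person-time."""
    if person_years <= 0:
        return float("nan")
    return 1e4 * n_cases / person_years


def age_specific_rates(
    cases_by_bin: pd.Series, py_by_bin: pd.Series
) -> pd.DataFrame:
    """Per-bin cases, person-years and rate; bins aligned on the union."""
    idx = cases_by_bin.index.union(py_by_bin.index)
    c = cases_by_bin.reindex(idx, fill_value=0)
    y = py_by_bin.reindex(idx, fill_value=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = 1e4 * c / y
    return pd.DataFrame(
        {"n_cases": c, "person_years": y, "rate_per_10k": rate.where(y > 0)}
    )


def standardized_rate(
    rates: pd.DataFrame | pd.Series, weights: pd.Series
) -> float:
    """Directly age-standardized rate: weighted mean of age-specific rates.

    ``rates`` is a Series of per-bin rates or the frame from
    :func:`age_specific_rates`; ``weights`` the standard population's bin
    weights (any positive vector; normalized here).  Bins without person-time
    in the target are dropped and the remaining weights renormalized, with a
    logged warning.
    """
    if isinstance(rates, pd.DataFrame):
        rate = rates["rate_per_10k"]
    else:
        rate = rates
    w = weights.reindex(rate.index).fillna(0.0)
    usable = rate.notna()
    if not usable.all():
        dropped = list(rate.index[~usable & (w > 0)])
        if dropped:
            logger.warning(
                "standardized_rate: dropping bins with no person-time and "
                "renormalizing weights: %s", dropped,
            )
    w = w.where(usable, 0.0)
    total = w.sum()
    if total <= 0:
        return float("nan")
    return float((w / total * rate.fillna(0.0)).sum())


def income_gradient(rates_by_income: pd.Series) -> float:
    """Low-income minus high-income rate (the social-gradient summary)."""
    for needed in ("low", "high"):
        if needed not in rates_by_income.index:
            raise KeyError(f"income stratum {needed!r} missing from rates")
    return float(rates_by_income["low"] - rates_by_income["high"])


# ---------------------------------------------------------------------------
# Orchestration


def _weights_from_py(py_by_bin: pd.Series) -> pd.Series:
    total = py_by_bin.sum()
    return py_by_bin / total if total > 0 else py_by_bin


def rate_analysis(
    persons: pd.DataFrame,
    spells: pd.DataFrame,
    cases: pd.DataFrame,
    assignments: pd.DataFrame,
    codeset: DiseaseCodeset,
    index_year: int,
    lookbacks: tuple[int, ...] = (1, 3, 5),
    censor_at_event: bool = False,
    use_secondary_history: bool = True,
    full_history: bool = False,
    age_bins: AgeBinScheme = FIVE_YEAR_BINS,
    gap_tolerance_days: int = 0,
) -> dict[str, pd.DataFrame]:
    """Crude and base-standardized incidence rates across lookbacks.

    Runs, for the base population and every CONk: index-case finding,
    lookback washout (numerator *and* denominator), person-time accumulation
    and direct age standardization at the base population, stratified by sex
    and income group.

    Returns a dict with

    ``crude``
        per subpopulation x sex: n_at_risk, n_cases, person_years, crude
        rate per 10,000 PY;
    ``standardized``
        per subpopulation x sex x income group: standardized rate (base
        weights), with case and person-year totals;
    ``gradient``
        per subpopulation x sex: low-minus-high standardized-rate
        difference;
    ``by_age``
        the underlying bin-level detail (subpopulation x sex x income x
        age bin cases and person-years);
    ``weights``
        the per-sex standard weights used.
    """
    person_info = persons.set_index("person_id")
    ages = index_year - person_info["birth_year"]
    bin_labels = pd.Series(
        age_bins.assign_labels(ages.clip(lower=age_bins.min_age)),
        index=person_info.index,
    )
    index_cases = find_index_cases(cases, codeset, index_year)

    subpops: list[tuple[str, pd.Index, pd.Index]] = []
    base_ids = pd.Index(assignments.index[assignments["in_base"]])
    subpops.append(("BASE", base_ids, pd.Index([])))
    for k in sorted(lookbacks):
        ids = pd.Index(assignments.index[assignments[con_column(k)]])
        flagged = find_lookback_events(
            cases, codeset, index_year, k,
            use_secondary_history=use_secondary_history,
            full_history=full_history,
        )
        subpops.append((f"CON{k}", ids, flagged))

    crude_rows = []
    by_age_rows = []
    weights_by_sex: dict[str, pd.Series] = {}

    for label, ids, flagged in subpops:
        at_risk, incident = washout_adjust(ids, index_cases, flagged)
        censor = incident if censor_at_event else None
        py = person_years_in_year(
            spells, index_year, at_risk, censor_dates=censor,
            gap_tolerance_days=gap_tolerance_days,
        )
        info = person_info.loc[at_risk]
        df = pd.DataFrame(
            {
                "sex": info["sex"],
                "income_group": info["income_group"],
                "age_bin": bin_labels.loc[at_risk],
                "person_years": py.reindex(at_risk).to_numpy(),
                "is_case": at_risk.isin(incident.index),
            },
            index=at_risk,
        )
        for sex, sub in df.groupby("sex", observed=False):
            crude_rows.append(
                {
                    "subpopulation": label,
                    "sex": sex,
                    "n_at_risk": len(sub),
                    "n_cases": int(sub["is_case"].sum()),
                    "person_years": float(sub["person_years"].sum()),
                    "rate_per_10k": crude_rate(
                        int(sub["is_case"].sum()), float(sub["person_years"].sum())
                    ),
                }
            )
        detail = (
            df.groupby(["sex", "income_group", "age_bin"], observed=False)
            .agg(n_cases=("is_case", "sum"), person_years=("person_years", "sum"))
            .reset_index()
        )
        detail.insert(0, "subpopulation", label)
        by_age_rows.append(detail)
        if label == "BASE":
            for sex, sub in df.groupby("sex", observed=False):
                weights_by_sex[sex] = _weights_from_py(
                    sub.groupby("age_bin", observed=False)["person_years"].sum()
                )

    by_age = pd.concat(by_age_rows, ignore_index=True)

    std_rows = []
    grad_rows = []
    strata = by_age.groupby(
        ["subpopulation", "sex", "income_group"], observed=False
    )
    for (label, sex, group), sub in strata:
        rates = age_specific_rates(
            sub.set_index("age_bin")["n_cases"],
            sub.set_index("age_bin")["person_years"],
        )
        std = standardized_rate(rates, weights_by_sex[sex])
        std_rows.append(
            {
                "subpopulation": label,
                "sex": sex,
                "income_group": group,
                "n_cases": int(sub["n_cases"].sum()),
                "person_years": float(sub["person_years"].sum()),
                "standardized_rate_per_10k": std,
            }
        )
    standardized = pd.DataFrame(std_rows)

    # sex-level (all income groups pooled) standardized rates and gradients
    pooled = by_age.groupby(
        ["subpopulation", "sex", "age_bin"], observed=False
    )[["n_cases", "person_years"]].sum().reset_index()
    pooled_rows = []
    for (label, sex), sub in pooled.groupby(["subpopulation", "sex"], observed=False):
        rates = age_specific_rates(
            sub.set_index("age_bin")["n_cases"],
            sub.set_index("age_bin")["person_years"],
        )
        pooled_rows.append(
            {
                "subpopulation": label,
                "sex": sex,
                "standardized_rate_per_10k": standardized_rate(
                    rates, weights_by_sex[sex]
                ),
            }
        )
    standardized_pooled = pd.DataFrame(pooled_rows)

    for (label, sex), sub in standardized.groupby(
        ["subpopulation", "sex"], observed=False
    ):
        by_income = sub.set_index("income_group")["standardized_rate_per_10k"]
        try:
            grad = income_gradient(by_income)
        except KeyError:
            grad = float("nan")  # a stratum absent in tiny inputs
        grad_rows.append(
            {
                "subpopulation": label,
                "sex": sex,
                "gradient_low_minus_high": grad,
            }
        )

    crude = pd.DataFrame(crude_rows)
    gradient = pd.DataFrame(grad_rows)
    weights = pd.concat(
        {s: w for s, w in weights_by_sex.items()}, names=["sex", "age_bin"]
    ).rename("weight").reset_index()
    return {
        "crude": crude,
        "standardized": standardized,
        "standardized_pooled": standardized_pooled,
        "gradient": gradient,
        "by_age": by_age,
        "weights": weights,
    }


# ---------------------------------------------------------------------------
# Sampling-noise helpers for directional comparisons


def paired_rate_diff_se(
    cases_full: float, py_full: float, cases_restricted: float, py_restricted: float
) -> float:
    """Approximate SE of ``rate(full) - rate(restricted)`` (per 10,000 PY)
    when the restricted population is a subset of the full one.

    Cases are split into retained and excluded, treated as independent
    Poisson counts: ``r_F - r_R = c_E/Y_F + c_R (1/Y_F - 1/Y_R)``, giving
    ``Var = c_E / Y_F^2 + c_R (1/Y_F - 1/Y_R)^2``.
    """
    if py_full <= 0 or py_restricted <= 0:
        return float("nan")
    c_excl = max(cases_full - cases_restricted, 0.0)
    var = c_excl / py_full**2 + cases_restricted * (1 / py_full - 1 / py_restricted) ** 2
    return 1e4 * float(np.sqrt(var))


def gradient_narrowing(
    result: dict[str, pd.DataFrame], sex: str, k: int
) -> tuple[float, float]:
    """Change of the low-minus-high standardized gradient from BASE to CONk,
    with an approximate SE.

    Returns ``(narrowing, se)`` where ``narrowing = gradient(BASE) -
    gradient(CONk)``; positive values mean the social gradient shrank under
    the lookback.  The SE combines, over age bins and the low/high strata,
    the paired Poisson variance of each standardized-rate change (CONk cases
    are a subset of BASE cases).
    """
    grad = result["gradient"].set_index(["subpopulation", "sex"])
    g_base = grad.loc[("BASE", sex), "gradient_low_minus_high"]
    g_con = grad.loc[(f"CON{k}", sex), "gradient_low_minus_high"]

    by_age = result["by_age"]
    weights = result["weights"]
    w = weights[weights["sex"] == sex].set_index("age_bin")["weight"]
    var = 0.0
    for group in ("low", "high"):
        sel = (by_age["sex"] == sex) & (by_age["income_group"] == group)
        b = by_age[sel & (by_age["subpopulation"] == "BASE")].set_index("age_bin")
        c = by_age[sel & (by_age["subpopulation"] == f"CON{k}")].set_index("age_bin")
        bins = b.index.union(c.index)
        for bin_label in bins:
            cB = float(b["n_cases"].get(bin_label, 0))
            yB = float(b["person_years"].get(bin_label, 0))
            cC = float(c["n_cases"].get(bin_label, 0))
            yC = float(c["person_years"].get(bin_label, 0))
            if yB <= 0 or yC <= 0:
                continue
            se_bin = paired_rate_diff_se(cB, yB, cC, yC)
            var += (float(w.get(bin_label, 0.0)) * se_bin) ** 2
    return float(g_base - g_con), float(np.sqrt(var))
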