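"""Synthetic claims-data generator.

Produces the three flat tables the analysis pipeline consumes — persons,
insurance spells, hospital cases — from a seeded :class:`~washout.scenario.
ScenarioConfig`.  The generator simulates, per person and calendar year,

1. fund membership: everyone is enrolled at the start of the history window;
   each year a member may leave (annual churn probability from the logistic
   churn model) at a uniform-random day, and a former member may re-join
   (``entry_prob``) at a uniform-random day, opening a new spell.  Anyone
   still outside the fund when the index year arrives re-joins at a
   uniform-random day of the index year, so the generated population is the
   index-year fund population by construction (everyone is base-eligible);
   members may also leave during the index year.
2. hospitalizations: for each disease an annual event probability from the
   hazard model (age bin x income group x sex x latent precarious state),
   multiplied by ``recurrence_multiplier`` once a first event has occurred
   and by ``pre_index_hazard_scale`` before the index year.  Events are
   drawn only for insured years and dated uniformly within the insured part
   of the year, so no case falls outside coverage.
3. background (non-cardiovascular) admissions, which after a myocardial
   infarction may carry the "old MI" history code I25.2 as a secondary
   diagnosis with probability ``i252_prob``.

All draws come from one ``numpy`` generator seeded with ``config.seed``;
outputs are byte-identical for identical configurations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scenario import (
    INCOME_GROUPS,
    INCOME_VALUE_BOUNDS,
    QUALIFICATION_LEVELS,
    ScenarioConfig,
)

__all__ = ["generate_scenario", "write_tables"]

_MI_CODES = ("I21.0", "I21.1", "I21.2", "I21.3", "I21.4", "I21.9")
_STROKE_CODES = ("I60.7", "I61.9", "I63.3", "I63.5", "I63.9", "I64")
_EVENT_CODES = {"MI": _MI_CODES, "stroke": _STROKE_CODES}
_BACKGROUND_CODES = ("J18.9", "K80.2", "M17.1", "S72.0", "E11.9", "N39.0")
_EVENT_SECONDARY = ("", "I10", "E11.9", "I10;E11.9")
_EVENT_SECONDARY_P = (0.4, 0.3, 0.2, 0.1)


def _year_length(year: int) -> int:
    return (np.datetime64(f"{year + 1}-01-01") - np.datetime64(f"{year}-01-01")).astype(int)


def _date_from_doy(year: int, doy: np.ndarray) -> np.ndarray:
    """datetime64[D] dates from 1-based day-of-year numbers."""
    return np.datetime64(f"{year}-01-01") + (doy - 1).astype("timedelta64[D]")


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(persons, spells, cases)`` tables for a scenario.

    Returns
    -------
    persons : DataFrame
        ``person_id, birth_year, sex, qualification, income_group,
        income_value`` — one row per person, all base-eligible in the index
        year.
    spells : DataFrame
        ``person_id, start_date, end_date`` — closed intervals of coverage.
    cases : DataFrame
        ``person_id, admission_date, main_dx, secondary_dx`` — one row per
        inpatient stay; secondary diagnoses semicolon-joined.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    iy = cfg.index_year
    y0 = cfg.first_year
    bins = cfg.age_bins

    # --- person attributes -------------------------------------------------
    bin_idx = rng.choice(bins.n_bins, size=n, p=np.asarray(cfg.age_distribution))
    edges = np.asarray(bins.lower_edges)
    width = np.diff(np.append(edges, edges[-1] + 5))  # top bin spans 5 years too
    age_at_index = edges[bin_idx] + rng.integers(0, width[bin_idx])
    birth_year = iy - age_at_index
    female = rng.random(n) < cfg.sex_ratio_female
    employed = rng.random(n) < cfg.employment_prob
    qual_idx = rng.choice(len(QUALIFICATION_LEVELS), size=n,
                          p=np.asarray(cfg.qualification_probs))
    qualification = np.where(
        employed, np.asarray(QUALIFICATION_LEVELS)[qual_idx], "not_applicable"
    )
    income_idx = rng.choice(len(INCOME_GROUPS), size=n,
                            p=np.asarray(cfg.income_group_probs))
    income_group = np.asarray(INCOME_GROUPS)[income_idx]
    income_value = np.full(n, np.nan)
    for gi, g in enumerate(INCOME_GROUPS):
        if g == "unknown":
            continue
        lo, hi = INCOME_VALUE_BOUNDS[g]
        mask = income_idx == gi
        income_value[mask] = np.round(lo + rng.random(mask.sum()) * (hi - lo), 0)
    prec_p = np.array([cfg.precarious_probs[g] for g in INCOME_GROUPS])[income_idx]
    precarious = rng.random(n) < prec_p
    income_unknown = income_idx == INCOME_GROUPS.index("unknown")

    # --- membership spells -------------------------------------------------
    member = np.ones(n, dtype=bool)
    spell_start = np.full(n, np.datetime64(f"{y0}-01-01"), dtype="datetime64[D]")
    spell_pid: list[np.ndarray] = []
    spell_s: list[np.ndarray] = []
    spell_e: list[np.ndarray] = []
    year_lo: dict[int, np.ndarray] = {}
    year_hi: dict[int, np.ndarray] = {}

    for y in range(y0, iy + 1):
        ndays = _year_length(y)
        member_at_start = member.copy()
        lo = np.where(member_at_start, 1, 0)
        hi = np.where(member_at_start, ndays, 0)

        age_y = (y - birth_year).astype(float)
        p_exit = cfg.churn_model.annual_probability(age_y, income_unknown, precarious)
        exits = member_at_start & (rng.random(n) < p_exit)
        exit_doy = 1 + (rng.random(n) * ndays).astype(int)
        if exits.any():
            end = _date_from_doy(y, exit_doy[exits])
            spell_pid.append(np.where(exits)[0])
            spell_s.append(spell_start[exits])
            spell_e.append(end)
            hi[exits] = exit_doy[exits]
            member[exits] = False

        if y < iy:
            entries = (~member_at_start) & (rng.random(n) < cfg.entry_prob)
        else:
            # index year: everyone not currently enrolled re-joins, so every
            # generated person is insured at least one day of the index year
            entries = ~member_at_start
            rng.random(n)  # keep the draw count per year constant
        entry_doy = 1 + (rng.random(n) * ndays).astype(int)
        if entries.any():
            spell_start[entries] = _date_from_doy(y, entry_doy[entries])
            member[entries] = True
            lo[entries] = entry_doy[entries]
            hi[entries] = ndays

        year_lo[y] = lo
        year_hi[y] = hi

    still_open = member
    if still_open.any():
        spell_pid.append(np.where(still_open)[0])
        spell_s.append(spell_start[still_open])
        spell_e.append(
            np.full(still_open.sum(), np.datetime64(f"{iy}-12-31"), dtype="datetime64[D]")
        )

    pid_num = np.concatenate(spell_pid) if spell_pid else np.empty(0, int)
    spells = pd.DataFrame(
        {
            "person_id": pid_num,
            "start_date": pd.to_datetime(np.concatenate(spell_s))
            if spell_s else pd.to_datetime([]),
            "end_date": pd.to_datetime(np.concatenate(spell_e))
            if spell_e else pd.to_datetime([]),
        }
    )

    # --- hospital cases ----------------------------------------------------
    case_pid: list[np.ndarray] = []
    case_date: list[np.ndarray] = []
    case_main: list[np.ndarray] = []
    case_secondary: list[np.ndarray] = []

    epoch_nat = np.datetime64("NaT")
    first_mi_date = np.full(n, epoch_nat, dtype="datetime64[D]")
    prior_event = {d: np.zeros(n, dtype=bool) for d in cfg.hazard_models}

    for y in range(y0, iy + 1):
        ndays = _year_length(y)
        lo, hi = year_lo[y], year_hi[y]
        insured = lo > 0
        # annual probabilities apply to a full insured year; partial coverage
        # is prorated so the per-day hazard is constant
        exposure = np.where(insured, (hi - lo + 1) / ndays, 0.0)
        age_y = np.clip(y - birth_year, bins.min_age, None)
        scale = 1.0 if y == iy else cfg.pre_index_hazard_scale
        for disease in sorted(cfg.hazard_models):
            hz = cfg.hazard_models[disease]
            p = hz.annual_probability(age_y, income_idx, female, precarious)
            p = np.where(
                prior_event[disease],
                np.minimum(p * cfg.recurrence_multiplier, 1.0),
                p,
            ) * scale * exposure
            hit = insured & (rng.random(n) < p)
            span = np.maximum(hi - lo + 1, 1)
            doy = lo + (rng.random(n) * span).astype(int)
            if hit.any():
                idx = np.where(hit)[0]
                dates = _date_from_doy(y, doy[idx])
                codes = rng.choice(_EVENT_CODES[disease], size=idx.size)
                secondary = rng.choice(
                    _EVENT_SECONDARY, size=idx.size, p=_EVENT_SECONDARY_P
                )
                case_pid.append(idx)
                case_date.append(dates)
                case_main.append(codes)
                case_secondary.append(secondary)
                if disease == "MI":
                    newer = np.isnat(first_mi_date[idx]) | (dates < first_mi_date[idx])
                    upd = idx[newer]
                    first_mi_date[upd] = dates[newer]
            else:
                rng.choice(_EVENT_CODES[disease], size=0)
            prior_event[disease] |= hit

        # background admissions (non-cardiovascular main diagnosis)
        bg = insured & (rng.random(n) < cfg.background_admission_prob * exposure)
        span = np.maximum(hi - lo + 1, 1)
        doy = lo + (rng.random(n) * span).astype(int)
        i252_draw = rng.random(n)
        if bg.any():
            idx = np.where(bg)[0]
            dates = _date_from_doy(y, doy[idx])
            codes = rng.choice(_BACKGROUND_CODES, size=idx.size)
            had_mi = (~np.isnat(first_mi_date[idx])) & (first_mi_date[idx] < dates)
            secondary = np.where(
                had_mi & (i252_draw[idx] < cfg.i252_prob), "I25.2", ""
            )
            case_pid.append(idx)
            case_date.append(dates)
            case_main.append(codes)
            case_secondary.append(secondary)

    if case_pid:
        cases = pd.DataFrame(
            {
                "person_id": np.concatenate(case_pid),
                "admission_date": pd.to_datetime(np.concatenate(case_date)),
                "main_dx": np.concatenate(case_main),
                "secondary_dx": np.concatenate(case_secondary),
            }
        )
    else:
        cases = pd.DataFrame(
            columns=["person_id", "admission_date", "main_dx", "secondary_dx"]
        ).astype({"admission_date": "datetime64[ns]"})

    # --- assemble, stable ordering, readable ids ---------------------------
    ids = np.array([f"P{i:07d}" for i in range(n)])
    persons = pd.DataFrame(
        {
            "person_id": ids,
            "birth_year": birth_year,
            "sex": np.where(female, "female", "male"),
            "qualification": qualification,
            "income_group": income_group,
            "income_value": income_value,
        }
    )
    spells["person_id"] = ids[spells["person_id"].to_numpy(dtype=int)]
    spells = spells.sort_values(
        ["person_id", "start_date", "end_date"], kind="mergesort"
    ).reset_index(drop=True)
    if len(cases):
        cases["person_id"] = ids[cases["person_id"].to_numpy(dtype=int)]
        cases = cases.sort_values(
            ["person_id", "admission_date", "main_dx"], kind="mergesort"
        ).reset_index(drop=True)
    return persons, spells, cases


def write_tables(
    persons: pd.DataFrame,
    spells: pd.DataFrame,
    cases: pd.DataFrame,
    out_dir,
) -> dict[str, str]:
    """Write the three tables as CSV with ISO-8601 dates; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df, date_cols in (
        ("persons", persons, ()),
        ("spells", spells, ("start_date", "end_date")),
        ("cases", cases, ("admission_date",)),
    ):
        df = df.copy()
        for c in date_cols:
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)
    return paths
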