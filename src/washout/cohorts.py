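"""Construction of the base and lookback-restricted study populations.

For an index year Y the study populations are

* ``BASE`` — persons aged >= ``min_age`` (by birth-year arithmetic) insured
  at least one day in Y;
* ``CONk`` — BASE members additionally insured continuously throughout the k
  calendar years immediately preceding Y (for k = 1: all of Y-1; for k = 5:
  all of Y-5 .. Y-1).

Because continuous coverage of a longer window implies coverage of every
shorter one, the populations are nested: CON5 ⊆ CON3 ⊆ CON1 ⊆ BASE.
"""

from __future__ import annotations

import datetime as dt
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .spells import any_day_in_year_ids, covers_window_ids, merge_spells_frame

__all__ = [
    "build_cohorts",
    "cohort_sizes",
    "percent_excluded",
    "reduction_table",
    "con_column",
]


def con_column(k: int) -> str:
    return f"in_con_{k}"


def build_cohorts(
    persons: pd.DataFrame,
    spells: pd.DataFrame,
    index_year: int,
    lookbacks: tuple[int, ...] = (1, 3, 5),
    min_age: int = 25,
    gap_tolerance_days: int = 0,
) -> pd.DataFrame:
    """Assign every person to BASE and each CONk subpopulation.

    Returns a DataFrame indexed by ``person_id`` with boolean columns
    ``in_base`` and ``in_con_<k>`` for each requested lookback.  Persons
    appearing in ``spells`` but not in ``persons`` are a data error (their
    age cannot be established).
    """
    if any(k <= 0 for k in lookbacks):
        raise ValueError("lookbacks must be positive integers")
    known = set(persons["person_id"])
    spell_pids = set(spells["person_id"].unique())
    orphans = spell_pids - known
    if orphans:
        example = sorted(orphans)[:3]
        raise ValueError(
            f"{len(orphans)} person(s) appear in spells but not in the persons "
            f"table, e.g. {example}"
        )

    age = index_year - persons["birth_year"]
    eligible = persons.loc[age >= min_age, "person_id"]

    merged = merge_spells_frame(spells, gap_tolerance_days)
    base_ids = any_day_in_year_ids(merged, index_year)

    out = pd.DataFrame(index=pd.Index(persons["person_id"], name="person_id"))
    out["in_base"] = out.index.isin(base_ids) & out.index.isin(set(eligible))
    for k in sorted(lookbacks):
        window_start = dt.date(index_year - k, 1, 1)
        window_end = dt.date(index_year - 1, 12, 31)
        covered = covers_window_ids(merged, window_start, window_end)
        out[con_column(k)] = out["in_base"] & out.index.isin(covered)
    return out


def cohort_sizes(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts of BASE and each CONk, ordered by increasing lookback."""
    rows = [("BASE", int(assignments["in_base"].sum()))]
    ks = sorted(
        int(c.rsplit("_", 1)[1])
        for c in assignments.columns
        if c.startswith("in_con_")
    )
    for k in ks:
        rows.append((f"CON{k}", int(assignments[con_column(k)].sum())))
    return pd.DataFrame(rows, columns=["subpopulation", "n"])


def percent_excluded(n_reference: int, n_retained: int, decimals: int = 1) -> float:
    """Percentage excluded going from a reference count to a retained count,
    rounded half-up to ``decimals`` (the convention of printed reports)."""
    if n_reference <= 0:
        raise ZeroDivisionError("n_reference must be > 0")
    if not (0 <= n_retained <= n_reference):
        raise ValueError("need 0 <= n_retained <= n_reference")
    pct = Decimal(100) * (Decimal(n_reference) - Decimal(n_retained)) / Decimal(n_reference)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def reduction_table(assignments: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Cohort sizes with both exclusion conventions.

    ``pct_excluded_sequential`` compares each subpopulation with the previous
    (next-shorter) one; ``pct_excluded_cumulative`` compares it with BASE.
    The two are consistent: 1 - cumulative = product of (1 - sequential).
    """
    sizes = cohort_sizes(assignments)
    seq = [0.0]
    cum = [0.0]
    n_base = int(sizes["n"].iloc[0])
    for i in range(1, len(sizes)):
        prev = int(sizes["n"].iloc[i - 1])
        cur = int(sizes["n"].iloc[i])
        seq.append(percent_excluded(prev, cur, decimals) if prev else 0.0)
        cum.append(percent_excluded(n_base, cur, decimals) if n_base else 0.0)
    sizes["pct_excluded_sequential"] = seq
    sizes["pct_excluded_cumulative"] = cum
    return sizes
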