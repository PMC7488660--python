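"""Interval arithmetic on insurance enrollment spells.

An insurance spell is a closed interval of calendar days ``[start, end]``
(both endpoints covered) during which one person is continuously enrolled
with the insurance fund.  Every cohort definition in this package — "insured
at least one day in the index year", "insured continuously throughout the
k preceding calendar years" — reduces to the small set of predicates and
counters defined here.

Two API levels are provided:

* scalar functions (:func:`merge_spells`, :func:`is_continuously_insured`,
  :func:`insured_any_day`, :func:`person_days`) operating on the spells of a
  single person, given as ``(start, end)`` date pairs or :class:`Spell`
  objects — convenient for small fixtures and as the reference semantics;
* frame functions (:func:`merge_spells_frame`, :func:`covers_window_ids`,
  :func:`any_day_in_year_ids`, :func:`person_days_frame`) operating on a
  ``person_id / start_date / end_date`` DataFrame for whole populations.

Both levels share the same closed-interval convention: a gap exists between
two spells only if at least one uncovered day lies between them, so
``[..., 2016-06-30]`` followed by ``[2016-07-01, ...]`` is continuous
coverage.  ``gap_tolerance_days`` widens this: a gap of at most that many
uncovered days is bridged (claims extracts frequently contain one-day
administrative gaps between contiguous memberships; the default of 0 is the
literal reading of "continuously insured").
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spell",
    "SpellError",
    "merge_spells",
    "is_continuously_insured",
    "insured_any_day",
    "person_days",
    "person_years",
    "merge_spells_frame",
    "covers_window_ids",
    "any_day_in_year_ids",
    "person_days_frame",
]

DAY = dt.timedelta(days=1)


class SpellError(ValueError):
    """Raised for structurally invalid spells (end date before start date)."""


@dataclass(frozen=True)
class Spell:
    """One closed interval of continuous coverage for one person."""

    person_id: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise SpellError(
                f"spell for person {self.person_id!r} has end {self.end} "
                f"before start {self.start}"
            )


def _as_pairs(spells: Iterable) -> list[tuple[dt.date, dt.date]]:
    pairs = []
    for s in spells:
        if isinstance(s, Spell):
            start, end = s.start, s.end
        else:
            start, end = s
        start = pd.Timestamp(start).date() if not isinstance(start, dt.date) else start
        end = pd.Timestamp(end).date() if not isinstance(end, dt.date) else end
        if end < start:
            raise SpellError(f"spell ({start}, {end}) has end before start")
        pairs.append((start, end))
    return pairs


def merge_spells(
    spells: Iterable, gap_tolerance_days: int = 0
) -> list[tuple[dt.date, dt.date]]:
    """Merge the spells of one person into sorted, disjoint intervals.

    Spells that overlap, touch, or are separated by at most
    ``gap_tolerance_days`` uncovered days are unioned.  The result is sorted,
    pairwise disjoint and non-adjacent (under the same tolerance), covers
    every input day, and the operation is idempotent and independent of input
    order.

    Parameters
    ----------
    spells
        ``(start, end)`` date pairs or :class:`Spell` objects of one person.
    gap_tolerance_days
        Maximum number of uncovered days between two spells that still counts
        as continuous coverage.  0 means only overlapping or directly
        adjacent spells merge.
    """
    if gap_tolerance_days < 0:
        raise ValueError("gap_tolerance_days must be >= 0")
    pairs = sorted(_as_pairs(spells))
    if not pairs:
        return []
    bridge = dt.timedelta(days=gap_tolerance_days + 1)
    merged = [pairs[0]]
    for start, end in pairs[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + bridge:
            if end > last_end:
                merged[-1] = (last_start, end)
        else:
            merged.append((start, end))
    return merged


def is_continuously_insured(
    spells: Iterable,
    first_year: int,
    last_year: int,
    gap_tolerance_days: int = 0,
) -> bool:
    """True iff every day from Jan 1 of ``first_year`` through Dec 31 of
    ``last_year`` is covered (after merging under the gap tolerance)."""
    if first_year > last_year:
        raise ValueError("first_year must be <= last_year")
    window_start = dt.date(first_year, 1, 1)
    window_end = dt.date(last_year, 12, 31)
    for start, end in merge_spells(spells, gap_tolerance_days):
        if start <= window_start and end >= window_end:
            return True
    return False


def insured_any_day(spells: Iterable, year: int) -> bool:
    """True iff the person is covered on at least one day of ``year``."""
    year_start = dt.date(year, 1, 1)
    year_end = dt.date(year, 12, 31)
    return any(
        start <= year_end and end >= year_start for start, end in _as_pairs(spells)
    )


def person_days(
    spells: Iterable, window_start: dt.date, window_end: dt.date
) -> int:
    """Number of covered days within the closed window.

    Overlapping input spells are merged first, so double coverage is not
    double counted.
    """
    if window_end < window_start:
        raise ValueError("window_end must be >= window_start")
    total = 0
    for start, end in merge_spells(spells, gap_tolerance_days=0):
        lo = max(start, window_start)
        hi = min(end, window_end)
        if lo <= hi:
            total += (hi - lo).days + 1
    return total


def person_years(spells: Iterable, year: int) -> float:
    """Covered fraction of ``year`` in years, using the year's true length.

    A full-year spell contributes 1.0 in both common and leap years (365 or
    366 covered days divided by the year length).
    """
    n_days = person_days(spells, dt.date(year, 1, 1), dt.date(year, 12, 31))
    year_length = (dt.date(year + 1, 1, 1) - dt.date(year, 1, 1)).days
    return n_days / year_length


# ---------------------------------------------------------------------------
# Frame-level (vectorized) versions


def _validate_frame(spells: pd.DataFrame) -> pd.DataFrame:
    df = spells[["person_id", "start_date", "end_date"]].copy()
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    bad = df.index[df["end_date"] < df["start_date"]]
    if len(bad):
        row = df.loc[bad[0]]
        raise SpellError(
            f"{len(bad)} spell(s) with end before start; first offender: "
            f"person {row['person_id']!r}, {row['start_date'].date()} .. "
            f"{row['end_date'].date()}"
        )
    return df


def merge_spells_frame(
    spells: pd.DataFrame, gap_tolerance_days: int = 0
) -> pd.DataFrame:
    """Vectorized per-person spell merge for a whole population.

    Expects columns ``person_id``, ``start_date``, ``end_date`` (closed
    intervals); returns a frame of the same shape with each person's spells
    sorted, disjoint and non-adjacent under the tolerance.
    """
    if gap_tolerance_days < 0:
        raise ValueError("gap_tolerance_days must be >= 0")
    df = _validate_frame(spells)
    if df.empty:
        return df.reset_index(drop=True)
    df = df.sort_values(["person_id", "start_date", "end_date"], kind="mergesort")
    pid = df["person_id"].to_numpy()
    start = df["start_date"].to_numpy()
    end = df["end_date"].to_numpy()
    new_person = np.empty(len(df), dtype=bool)
    new_person[0] = True
    new_person[1:] = pid[1:] != pid[:-1]
    # per-person running maximum of spell ends (segmented cummax)
    run_end = (
        pd.Series(end).groupby(pd.Series(pid), sort=False).cummax().to_numpy()
    )
    bridge = np.timedelta64(gap_tolerance_days + 1, "D")
    starts_new_group = np.empty(len(df), dtype=bool)
    starts_new_group[0] = True
    starts_new_group[1:] = new_person[1:] | (start[1:] > run_end[:-1] + bridge)
    group_id = np.cumsum(starts_new_group) - 1
    out = pd.DataFrame(
        {
            "person_id": pid,
            "start_date": start,
            "end_date": run_end,
            "_g": group_id,
        }
    )
    merged = out.groupby("_g", sort=True).agg(
        person_id=("person_id", "first"),
        start_date=("start_date", "first"),
        end_date=("end_date", "max"),
    )
    return merged.reset_index(drop=True)


def covers_window_ids(
    merged: pd.DataFrame, window_start: dt.date, window_end: dt.date
) -> pd.Index:
    """person_ids having one merged spell covering the whole closed window."""
    ws = pd.Timestamp(window_start)
    we = pd.Timestamp(window_end)
    hit = merged[(merged["start_date"] <= ws) & (merged["end_date"] >= we)]
    return pd.Index(hit["person_id"].unique())


def any_day_in_year_ids(spells: pd.DataFrame, year: int) -> pd.Index:
    """person_ids covered on at least one day of the calendar year."""
    df = _validate_frame(spells)
    ys = pd.Timestamp(dt.date(year, 1, 1))
    ye = pd.Timestamp(dt.date(year, 12, 31))
    hit = df[(df["start_date"] <= ye) & (df["end_date"] >= ys)]
    return pd.Index(hit["person_id"].unique())


def person_days_frame(
    spells: pd.DataFrame,
    window_start: dt.date,
    window_end: dt.date,
    gap_tolerance_days: int = 0,
) -> pd.Series:
    """Covered days in the closed window, per person (vectorized).

    Returns a Series indexed by person_id; persons with no overlap are absent.
    """
    merged = merge_spells_frame(spells, gap_tolerance_days)
    ws = pd.Timestamp(window_start)
    we = pd.Timestamp(window_end)
    lo = merged["start_date"].clip(lower=ws)
    hi = merged["end_date"].clip(upper=we)
    days = (hi - lo).dt.days + 1
    days = days.clip(lower=0)
    out = days.groupby(merged["person_id"]).sum()
    return out[out > 0]
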