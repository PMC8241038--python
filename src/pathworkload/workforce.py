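"""Pathologist workforce estimation from sign-out activity.

Full-time-equivalent (FTE) service is inferred from final-signature dates
alone: for each pathologist and calendar year, the set of distinct ISO-8601
weeks containing at least one signed case is collected.  A pathologist
signing in more than 41 ISO weeks of a year counts as 1.0 FTE (full-timers
may take up to 8 weeks vacation plus 2 weeks CME); otherwise
``FTE = weeks / 48`` (temporary staff typically get 3 weeks vacation plus
1 week CME).  Example: signing in 24 distinct weeks -> 24/48 = 0.5 FTE.

Cases are bucketed by the *calendar* year of the sign-out date; the ISO
week label keeps its own ISO year (a late-December date may belong to ISO
week 1 of the following ISO year, and is counted as that distinct label
within the calendar-year bucket).
"""

from __future__ import annotations

import datetime as _dt
from collections import defaultdict
from dataclasses import dataclass

#: Signing in more than this many ISO weeks in a year counts as full time.
FULL_TIME_WEEKS = 41
#: Denominator for part-time FTE fractions.
REFERENCE_WEEKS = 48


@dataclass(frozen=True)
class PathologistYearActivity:
    """Distinct signing weeks and derived FTE for one pathologist-year."""

    pathologist_id: str
    year: int
    signing_weeks: frozenset[tuple[int, int]]
    fte: float


def iso_week(date: _dt.date) -> tuple[int, int]:
    """The ISO-8601 (iso_year, iso_week) of a date.

    Weeks run Monday–Sunday; week 1 is the week containing the year's first
    Thursday, so the ISO year can differ from the calendar year at both
    ends of the year.
    """
    cal = date.isocalendar()
    return cal[0], cal[1]


def fte_from_weeks(n_weeks: int) -> float:
    """FTE fraction for a count of distinct signing weeks."""
    if n_weeks <= 0:
        return 0.0
    if n_weeks > FULL_TIME_WEEKS:
        return 1.0
    return n_weeks / REFERENCE_WEEKS


def compute_fte(
    records: list[tuple[str, _dt.date]], year: int
) -> list[PathologistYearActivity]:
    """Per-pathologist activity for one calendar year.

    ``records`` are (pathologist_id, signout_date) pairs; entries outside
    ``year`` are ignored, and pathologists with no record in the year are
    omitted.  Signing another case in an already-counted week never changes
    the result.
    """
    weeks: dict[str, set[tuple[int, int]]] = defaultdict(set)
    for pathologist_id, date in records:
        if date.year != year:
            continue
        weeks[pathologist_id].add(iso_week(date))
    return [
        PathologistYearActivity(
            pathologist_id=pid,
            year=year,
            signing_weeks=frozenset(wk),
            fte=fte_from_weeks(len(wk)),
        )
        for pid, wk in sorted(weeks.items())
    ]


def total_fte(activities: list[PathologistYearActivity], year: int) -> float:
    """Arithmetic sum of per-pathologist FTEs for one year."""
    return sum(a.fte for a in activities if a.year == year)
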