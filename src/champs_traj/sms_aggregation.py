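"""Reduction of weekly SMS responses to the monthly panel the model uses.

Parents answer one weekly prompt per child with the number of organised
leisure-time sport sessions (0-7, or 8 meaning "more than seven") and the
sport types practised.  The trajectory model consumes a monthly average:
for each child-month, the sum of reported weekly sessions divided by the
number of weeks with a response; months with two responses or fewer are
treated as missing, and children left with fewer than two monthly values
are excluded altogether.  When several sport types are reported in a week
the sessions are allocated equally among them.

Week-to-month convention: an ISO week belongs to the calendar month that
contains its Monday.  Age convention: completed months of age at the first
day of the month, from the date of birth.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .synthetic_cohort import SPORT_CODES

__all__ = [
    "aggregate_weekly_to_monthly",
    "exclude_sparse_children",
    "allocate_sport_sessions",
    "sport_type_summary",
]

logger = logging.getLogger(__name__)


def _week_to_month(iso_year: int, iso_week: int) -> str:
    monday = dt.date.fromisocalendar(int(iso_year), int(iso_week), 1)
    return f"{monday.year}-{monday.month:02d}"


def _age_months(dob: dt.date, month: str) -> int:
    """Completed months of age at the first day of ``month`` (YYYY-MM)."""
    y, m = (int(p) for p in month.split("-"))
    months = (y - dob.year) * 12 + (m - dob.month)
    if dob.day > 1:
        months -= 1
    return months


def aggregate_weekly_to_monthly(
    responses: pd.DataFrame,
    roster: pd.DataFrame | None = None,
    calendar=None,
    min_weeks: int = 3,
) -> pd.DataFrame:
    """Aggregate weekly responses into the child-month panel.

    Parameters
    ----------
    responses
        Columns ``child_id``, ``iso_year``, ``iso_week``, ``sessions``
        (0-8).  Sessions outside 0-8 are rejected with a logged warning.
    roster
        Optional; needs ``child_id`` and ``dob`` (ISO date) to compute
        ``age_months``/``age``.  Responses from unknown children raise.
    calendar
        Optional list of valid ``(iso_year, iso_week)`` prompt weeks;
        responses outside it are dropped with a warning.
    min_weeks
        Minimum weekly responses for a month to yield a value; with the
        default 3, months with two responses or fewer are missing.

    Returns
    -------
    DataFrame with one row per child-month that has at least one response:
    ``child_id``, ``month``, ``y`` (mean weekly sessions or NaN),
    ``n_weeks_observed``, and, when a roster is given, ``age_months`` and
    ``age`` (= age_months / 12).
    """
    df = responses.copy()
    valid = df["sessions"].between(0, 8)
    if (~valid).any():
        logger.warning("rejecting %d responses with sessions outside 0-8", int((~valid).sum()))
        df = df[valid]
    if roster is not None:
        known = set(roster["child_id"])
        unknown = set(df["child_id"]) - known
        if unknown:
            raise ValueError(f"responses reference unknown children: {sorted(unknown)[:5]}")
    if calendar is not None:
        cal = set(map(tuple, calendar))
        in_cal = [
            (y, w) in cal for y, w in zip(df["iso_year"], df["iso_week"])
        ]
        in_cal = np.asarray(in_cal, dtype=bool)
        if (~in_cal).any():
            logger.warning("dropping %d responses outside the prompt calendar", int((~in_cal).sum()))
            df = df[in_cal]
    if len(df) == 0:
        return pd.DataFrame(columns=["child_id", "month", "y", "n_weeks_observed"])

    df = df.assign(month=[_week_to_month(y, w) for y, w in zip(df["iso_year"], df["iso_week"])])
    grouped = df.groupby(["child_id", "month"], as_index=False).agg(
        total=("sessions", "sum"), n_weeks_observed=("sessions", "size")
    )
    grouped["y"] = np.where(
        grouped["n_weeks_observed"] >= min_weeks,
        grouped["total"] / grouped["n_weeks_observed"],
        np.nan,
    )
    panel = grouped[["child_id", "month", "y", "n_weeks_observed"]]

    if roster is not None:
        dobs = {
            row.child_id: dt.date.fromisoformat(str(row.dob))
            for row in roster.itertuples()
        }
        panel = panel.assign(
            age_months=[
                _age_months(dobs[c], m) for c, m in zip(panel["child_id"], panel["month"])
            ]
        )
        panel = panel.assign(age=panel["age_months"] / 12.0)
    return panel.sort_values(["child_id", "month"]).reset_index(drop=True)


def exclude_sparse_children(panel: pd.DataFrame, min_months: int = 2):
    """Drop children with fewer than ``min_months`` non-missing monthly values.

    Returns the filtered panel and the list of excluded child ids.
    """
    counts = panel.dropna(subset=["y"]).groupby("child_id").size()
    keep = set(counts[counts >= min_months].index)
    excluded = sorted(set(panel["child_id"]) - keep)
    out = panel[panel["child_id"].isin(keep)].reset_index(drop=True)
    return out, excluded


def allocate_sport_sessions(sessions: float, sport_codes) -> dict:
    """Split a week's sessions equally among the reported sport types.

    A positive count with no reported sport is allocated to "other"
    (code 10) with a warning; totals are always conserved.
    """
    if sessions < 0:
        raise ValueError("sessions must be non-negative")
    codes = sorted({int(c) for c in sport_codes})
    for c in codes:
        if c not in SPORT_CODES:
            raise ValueError(f"unknown sport code {c}")
    if sessions == 0:
        return {}
    if not codes:
        logger.warning("positive sessions with no sport codes; allocating to 'other'")
        return {10: float(sessions)}
    share = float(sessions) / len(codes)
    return {c: share for c in codes}


def _parse_codes(cell) -> list[int]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    if isinstance(cell, (list, tuple, set)):
        return [int(c) for c in cell]
    return [int(c) for c in str(cell).split(";") if c != ""]


def sport_type_summary(responses: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    """Per trajectory group: mean cumulative allocated sessions per member
    and the percentage of each sport, plus an overall column.

    ``assignments`` maps child_id to group label.  Percentages within each
    group sum to 100.
    """
    groups = assignments.to_dict() if isinstance(assignments, pd.Series) else dict(assignments)
    unknown = set(responses["child_id"]) - set(groups)
    if unknown:
        raise ValueError(f"responses from children with no group label: {sorted(unknown)[:5]}")

    labels = sorted(set(groups.values()))
    totals = {g: {c: 0.0 for c in SPORT_CODES} for g in labels}
    members = {g: set() for g in labels}
    for cid, g in groups.items():
        members[g].add(cid)
    for row in responses.itertuples():
        alloc = allocate_sport_sessions(row.sessions, _parse_codes(row.sports))
        g = groups[row.child_id]
        for c, v in alloc.items():
            totals[g][c] += v

    records = []
    for code, name in SPORT_CODES.items():
        rec = {"sport": name}
        overall_sum = 0.0
        for g in labels:
            n_members = max(len(members[g]), 1)
            mean_sessions = totals[g][code] / n_members
            group_total = sum(totals[g].values()) / n_members
            rec[f"group_{g}_mean"] = mean_sessions
            rec[f"group_{g}_pct"] = 100.0 * mean_sessions / group_total if group_total else 0.0
            overall_sum += totals[g][code]
        n_all = max(sum(len(m) for m in members.values()), 1)
        all_total = sum(sum(t.values()) for t in totals.values()) / n_all
        rec["overall_mean"] = overall_sum / n_all
        rec["overall_pct"] = 100.0 * rec["overall_mean"] / all_total if all_total else 0.0
        records.append(rec)
    return pd.DataFrame(records)
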