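"""Daily headache diary: day classification, monthly aggregation, subtyping.

Patients record headache features each day.  A *migraine* day (ICHD-3 style
definition, aura ignored) is a headache of at least 30 minutes with

  A. at least 2 of 4 characteristics (unilateral, pulsating, moderate/severe
     pain, aggravation by or avoidance of routine activity), AND
  B. at least one associated symptom: nausea/vomiting, or photophobia together
     with phonophobia.

A *probable migraine* day misses exactly one of these features: either A falls
one characteristic short (exactly 1 of the 4) while B holds, or A holds while
B fails entirely.  Both migraine and probable migraine count as migraine
headache days (MHD).

Monthly MHD are counted over consecutive 30-day windows anchored at
randomization.  When x of the 30 days are recorded, the count is prorated by
30/x; if more than half the days are unrecorded the month is treated as
missing.  Headache days are prorated the same way (configurable).

Migraine subtype at baseline: chronic migraine (CM) is >= 8 MHD with >= 15
total headache days; episodic migraine (EM) is anything else with >= 4 MHD.
Fewer than 4 MHD is ineligible for this population.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import math

import numpy as np
import pandas as pd

__all__ = [
    "DayClass",
    "DiaryDay",
    "MonthlySummary",
    "classify_day",
    "summarize_month",
    "classify_subtype",
    "summarize_diary",
]


class DayClass(str, Enum):
    NONE = "none"
    MIGRAINE = "migraine"
    PROBABLE_MIGRAINE = "probable_migraine"
    NONMIGRAINE_HEADACHE = "nonmigraine_headache"


@dataclass(frozen=True)
class DiaryDay:
    """One recorded diary day. Feature flags only matter when headache=True."""

    headache: bool
    duration_ge_30min: bool = False
    unilateral: bool = False
    pulsating: bool = False
    mod_severe: bool = False
    aggravation: bool = False
    nausea_vomiting: bool = False
    photophobia: bool = False
    phonophobia: bool = False


@dataclass(frozen=True)
class MonthlySummary:
    """30-day aggregate of a subject's diary."""

    migraine_headache_days_raw: int
    headache_days_raw: int
    n_nonmissing_days: int
    period_length: int = 30
    mhd_adjusted: float = float("nan")
    headache_days_adjusted: float = float("nan")
    missing: bool = False


def classify_day(day: DiaryDay) -> DayClass:
    """Classify a recorded diary day.

    Migraine requires duration >= 30 min plus conditions A and B above;
    probable migraine is one feature short of the full definition.
    """
    if not day.headache:
        return DayClass.NONE
    if not day.duration_ge_30min:
        return DayClass.NONMIGRAINE_HEADACHE
    n_char = sum(
        (day.unilateral, day.pulsating, day.mod_severe, day.aggravation)
    )
    cond_a = n_char >= 2
    cond_b = day.nausea_vomiting or (day.photophobia and day.phonophobia)
    if cond_a and cond_b:
        return DayClass.MIGRAINE
    if cond_a != cond_b and (cond_a or n_char == 1):
        # exactly one condition fails, and a failing A fails by one feature only
        return DayClass.PROBABLE_MIGRAINE
    return DayClass.NONMIGRAINE_HEADACHE


def summarize_month(
    days: list[DiaryDay | None],
    period_length: int = 30,
    prorate_headache_days: bool = True,
) -> MonthlySummary:
    """Aggregate one 30-day window of diary days (None = unrecorded day).

    Counts migraine headache days (migraine + probable migraine) and all
    headache days among the x recorded days, prorates by period_length/x, and
    marks the month missing when more than half its days are unrecorded.
    """
    if period_length <= 0:
        raise ValueError(f"period_length must be positive, got {period_length}")
    if len(days) > period_length:
        raise ValueError(
            f"{len(days)} days supplied for a {period_length}-day period"
        )
    recorded = [d for d in days if d is not None]
    x = len(recorded)
    classes = [classify_day(d) for d in recorded]
    mhd_raw = sum(
        c in (DayClass.MIGRAINE, DayClass.PROBABLE_MIGRAINE) for c in classes
    )
    hd_raw = sum(c is not DayClass.NONE for c in classes)

    missing = (period_length - x) > period_length / 2
    if missing:
        return MonthlySummary(mhd_raw, hd_raw, x, period_length, missing=True)
    factor = period_length / x
    hd_adj = hd_raw * factor if prorate_headache_days else float(hd_raw)
    return MonthlySummary(
        mhd_raw, hd_raw, x, period_length,
        mhd_adjusted=mhd_raw * factor,
        headache_days_adjusted=hd_adj,
    )


def classify_subtype(baseline: MonthlySummary) -> str:
    """Assign EM/CM from the baseline monthly summary.

    CM: mhd_adjusted >= 8 and headache days >= 15.  EM: otherwise, provided
    mhd_adjusted >= 4.  Below 4 MHD the subject is ineligible.
    """
    if baseline.missing or math.isnan(baseline.mhd_adjusted):
        raise ValueError("cannot subtype from a missing baseline summary")
    if baseline.mhd_adjusted < 4:
        raise ValueError(
            f"ineligible subject: baseline MHD {baseline.mhd_adjusted:.2f} < 4"
        )
    if baseline.mhd_adjusted >= 8 and baseline.headache_days_adjusted >= 15:
        return "CM"
    return "EM"


_FEATURE_COLS = [
    "duration_ge_30min", "unilateral", "pulsating", "mod_severe",
    "aggravation", "nausea_vomiting", "photophobia", "phonophobia",
]


def summarize_diary(
    diary: pd.DataFrame,
    anchor_date: str | pd.Timestamp,
    periods: dict[str, tuple[int, int]] | None = None,
    period_length: int = 30,
    prorate_headache_days: bool = True,
) -> pd.DataFrame:
    """Aggregate a ``diary.csv`` table into per-subject monthly summaries.

    ``periods`` maps a label to (start, end) day offsets relative to the
    anchor (randomization) date, end inclusive; the default is the 30-day
    baseline window ending the day before randomization and the Month-3
    window (days 61-90).  Days absent from the table count as unrecorded.
    """
    if periods is None:
        periods = {"baseline": (-period_length, -1), "month3": (61, 90)}
    anchor = pd.Timestamp(anchor_date)
    diary = diary.copy()
    diary["date"] = pd.to_datetime(diary["date"])
    diary["offset"] = (diary["date"] - anchor).dt.days

    rows = []
    for sid, sub in diary.groupby("subject_id", sort=True):
        by_offset = sub.set_index("offset")
        for label, (start, end) in periods.items():
            days: list[DiaryDay | None] = []
            for off in range(start, end + 1):
                if off not in by_offset.index:
                    days.append(None)
                    continue
                rec = by_offset.loc[off]
                days.append(DiaryDay(
                    headache=bool(rec["headache"]),
                    **{c: bool(rec[c]) for c in _FEATURE_COLS},
                ))
            s = summarize_month(days, end - start + 1, prorate_headache_days)
            rows.append({
                "subject_id": sid,
                "period": label,
                "mhd_raw": s.migraine_headache_days_raw,
                "headache_days_raw": s.headache_days_raw,
                "n_nonmissing_days": s.n_nonmissing_days,
                "mhd_adjusted": s.mhd_adjusted,
                "headache_days_adjusted": s.headache_days_adjusted,
                "missing": s.missing,
            })
    return pd.DataFrame(rows)
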