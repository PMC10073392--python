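"""WPAI:SHP v2 scoring.

The Work Productivity and Activity Impairment questionnaire (Specific Health
Problem version 2) asks six items over a 7-day recall:

* Q1  currently employed (yes/no)
* Q2  hours of work missed because of the health problem
* Q3  hours of work missed for other reasons (carried, not scored)
* Q4  hours actually worked
* Q5  degree the problem affected productivity while working (0-10)
* Q6  degree the problem affected regular non-work activities (0-10)

Four impairment percentages are derived, each the share of time lost in its
domain (higher = worse):

* absenteeism                    = 100 * Q2 / (Q2 + Q4)
* presenteeism                   = 100 * Q5 / 10            (requires Q4 > 0)
* overall work productivity loss = 100 * [Q2/(Q2+Q4) + (1 - Q2/(Q2+Q4)) * Q5/10]
* activity impairment            = 100 * Q6 / 10

Work scores (the first three) are only defined for employed respondents with
all required items present; activity impairment is defined for everyone with
Q6 present.  A domain score is left undefined (NaN) when any item it needs is
missing — a complete-case policy applied per domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WpaiItems", "WpaiScores", "score_wpai", "score_visits"]

_NAN = float("nan")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class WpaiItems:
    """Raw responses to the six WPAI items; any field may be None (missing)."""

    employed: bool | None = None
    hours_missed_migraine: float | None = None  # Q2
    hours_missed_other: float | None = None  # Q3, unused in scoring
    hours_worked: float | None = None  # Q4
    presenteeism_degree: int | None = None  # Q5, 0-10
    activity_degree: int | None = None  # Q6, 0-10

    def validate(self) -> None:
        for name, value in (
            ("hours_missed_migraine", self.hours_missed_migraine),
            ("hours_missed_other", self.hours_missed_other),
            ("hours_worked", self.hours_worked),
        ):
            if not _missing(value) and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")
        for name, value in (
            ("presenteeism_degree", self.presenteeism_degree),
            ("activity_degree", self.activity_degree),
        ):
            if _missing(value):
                continue
            if not float(value).is_integer() or not 0 <= value <= 10:
                raise ValueError(f"{name} must be an integer in 0..10, got {value!r}")


@dataclass(frozen=True)
class WpaiScores:
    """The four derived WPAI percentages; NaN marks an undefined score."""

    absenteeism_pct: float
    presenteeism_pct: float
    overall_work_productivity_loss_pct: float
    activity_impairment_pct: float


def score_wpai(items: WpaiItems) -> WpaiScores:
    """Derive the four WPAI domain scores from a validated item set.

    Work scores are undefined if the respondent is not employed or a required
    item is missing.  With no work time at all (Q2 + Q4 = 0) absenteeism and
    overall loss are undefined; presenteeism additionally requires Q4 > 0
    (the item is only asked about time actually at work).  Any missed work
    with zero hours worked counts as total loss (absenteeism = overall = 100).
    """
    items.validate()

    q2, q4 = items.hours_missed_migraine, items.hours_worked
    q5, q6 = items.presenteeism_degree, items.activity_degree

    activity = _NAN if _missing(q6) else 100.0 * q6 / 10.0

    if items.employed is not True:
        return WpaiScores(_NAN, _NAN, _NAN, activity)

    absenteeism = overall = presenteeism = _NAN

    if not _missing(q4) and q4 > 0 and not _missing(q5):
        presenteeism = 100.0 * q5 / 10.0

    have_hours = not (_missing(q2) or _missing(q4))
    if have_hours and q2 + q4 > 0:
        frac_missed = q2 / (q2 + q4)
        absenteeism = 100.0 * frac_missed
        if q4 > 0 and not _missing(q5):
            overall = 100.0 * (frac_missed + (1.0 - frac_missed) * q5 / 10.0)
        elif q4 == 0:
            # worked nothing but missed work: total productivity loss
            overall = 100.0

    return WpaiScores(absenteeism, presenteeism, overall, activity)


_ITEM_COLS = {
    "employed": "q1_employed",
    "hours_missed_migraine": "q2_hours_missed_migraine",
    "hours_missed_other": "q3_hours_missed_other",
    "hours_worked": "q4_hours_worked",
    "presenteeism_degree": "q5_presenteeism_0_10",
    "activity_degree": "q6_activity_0_10",
}

SCORE_COLS = [
    "absenteeism_pct",
    "presenteeism_pct",
    "overall_work_productivity_loss_pct",
    "activity_impairment_pct",
]


def score_visits(visits: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a visit table, appending the four score columns.

    Expects the ``visits.csv`` schema (q1_employed .. q6_activity_0_10).
    Raises ValueError naming the offending column and row on invalid items.
    """
    out = visits.copy()
    scores = np.full((len(out), 4), np.nan)
    for i, (idx, row) in enumerate(out.iterrows()):
        kwargs = {}
        for field, col in _ITEM_COLS.items():
            val = row.get(col)
            if pd.isna(val):
                kwargs[field] = None
            elif field == "employed":
                kwargs[field] = bool(val)
            elif field in ("presenteeism_degree", "activity_degree"):
                kwargs[field] = int(val)
            else:
                kwargs[field] = float(val)
        try:
            s = score_wpai(WpaiItems(**kwargs))
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        scores[i] = (
            s.absenteeism_pct,
            s.presenteeism_pct,
            s.overall_work_productivity_loss_pct,
            s.activity_impairment_pct,
        )
    out[SCORE_COLS] = scores
    return out
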