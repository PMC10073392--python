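"""Test-retest reliability via a two-level random-intercept model.

The stable subgroup for test-retest assessment consists of placebo-arm
subjects whose monthly migraine headache days changed by at most one day
between the baseline and Month-3 diary periods — subjects in whom the
underlying condition, and hence the true score, is assumed unchanged.

For each WPAI domain the model

    y_ij = beta0 + u_j + e_ij,   u_j ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

is fitted by restricted maximum likelihood to the baseline and Month-3 scores
(subject j, occasion i), and the intraclass correlation is the
between-subject share of total variance:

    ICC = sigma_u^2 / (sigma_u^2 + sigma_e^2)

Interpretation bands (on the ICC rounded to 2 decimals): 0.01-0.20 slightly
fair, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80 substantial, 0.81-1.00
almost perfect agreement; below 0.01 the agreement is negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "IccModelFit", "select_stable_subgroup", "fit_random_intercept", "icc_band",
]

_BANDS = [
    (0.81, "almost perfect agreement"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (0.01, "slightly fair"),
    (0.00, "negligible"),
]


@dataclass(frozen=True)
class IccModelFit:
    beta0: float
    sigma_u2: float
    sigma_e2: float
    icc: float
    n_subjects: int
    n_observations: int
    band: str


def icc_band(icc: float) -> str:
    """Label an ICC per the five agreement bands (rounded to 2 dp first)."""
    if not 0 <= icc <= 1:
        raise ValueError(f"ICC must be in [0, 1], got {icc}")
    r = round(icc, 2)
    for lower, label in _BANDS:
        if r >= lower:
            return label
    return "negligible"


def select_stable_subgroup(
    summary: pd.DataFrame,
    arms: pd.DataFrame,
    max_change_days: float = 1.0,
) -> list:
    """Subject ids of placebo patients with |ΔMHD| <= 1 day over 3 months.

    ``summary`` is the per-subject-per-period diary summary (columns
    subject_id, period, mhd_adjusted, missing); ``arms`` maps subject_id to
    arm ("placebo"/"active").  Stability is judged on prorated MHD, inclusive
    of the boundary.
    """
    wide = (
        summary[~summary["missing"]]
        .pivot(index="subject_id", columns="period", values="mhd_adjusted")
    )
    if not {"baseline", "month3"} <= set(wide.columns):
        return []
    wide = wide.dropna(subset=["baseline", "month3"])
    delta = (wide["month3"] - wide["baseline"]).abs()
    placebo = set(arms.loc[arms["arm"] == "placebo", "subject_id"])
    return sorted(sid for sid in delta.index[delta <= max_change_days]
                  if sid in placebo)


def fit_random_intercept(observations: pd.DataFrame) -> IccModelFit:
    """REML fit of the random-intercept-only model to repeated scores.

    ``observations`` has columns ``subject_id`` and ``score`` (one row per
    measurement occasion).  Requires at least two subjects and at least one
    subject with two observations.  Negative variance estimates are truncated
    at zero by the optimizer's parameterization; a degenerate fit with zero
    total variance yields a NaN ICC with a warning.
    """
    obs = observations.dropna(subset=["score"])
    counts = obs.groupby("subject_id").size()
    if len(counts) < 2 or counts.max() < 2:
        raise ValueError(
            "need >= 2 subjects and >= 1 subject with repeated measurements"
        )
    y = obs["score"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("all scores identical: ICC undefined", stacklevel=2)
        return IccModelFit(float(y[0]), 0.0, 0.0, float("nan"),
                           len(counts), len(obs), "")

    model = sm.MixedLM(
        y, np.ones((len(obs), 1)), groups=obs["subject_id"].to_numpy()
    )
    fit = None
    last_exc: Exception | None = None
    for method, kwargs in (
        ("bfgs", {"gtol": 1e-10}), ("lbfgs", {}), ("powell", {})
    ):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=True, method=method, **kwargs)
            break
        except Exception as exc:  # an optimizer can fail near the boundary
            last_exc = exc
    if fit is None:
        raise ValueError(f"random-intercept fit failed: {last_exc}")

    sigma_u2 = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
    sigma_e2 = max(float(fit.scale), 0.0)
    total = sigma_u2 + sigma_e2
    if total == 0:
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        icc = float("nan")
        band = ""
    else:
        icc = sigma_u2 / total
        band = icc_band(icc)
    return IccModelFit(float(fit.params[0]), sigma_u2, sigma_e2, icc,
                       len(counts), len(obs), band)
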