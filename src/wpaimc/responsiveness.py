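"""Responsiveness: ANCOVA of WPAI change by anchor responder status.

For each WPAI domain and anchor, the change from baseline to Month 3 is
modelled as

    change = intercept + b1 * responder + b2 * baseline + error

by ordinary least squares on complete cases.  Least-squares means (LSM) are
the model-predicted changes for each responder group evaluated at the grand
mean of baseline over included cases, with standard errors from the fit's
covariance.  A significant between-group difference (two-sided t test of the
responder coefficient, df = n - 3) indicates the instrument detects change.
The LSM difference is reported as non-responder minus responder, so a positive
value means responders improved (decreased) more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AncovaResult", "fit_ancova", "responsiveness_table"]


@dataclass(frozen=True)
class AncovaResult:
    n_nonresponder: int
    n_responder: int
    pct_nonresponder: float
    pct_responder: float
    lsm_change_nonresponder: float
    se_nonresponder: float
    p_nonresponder: float
    lsm_change_responder: float
    se_responder: float
    p_responder: float
    lsm_difference: float  # non-responder minus responder
    se_difference: float
    between_group_p: float


def fit_ancova(change, responder, baseline) -> AncovaResult:
    """Fit change ~ responder + baseline and derive group LS-means.

    All three inputs are aligned 1-d arrays over complete cases.  Both groups
    must be non-empty and n must exceed the 3 model parameters.
    """
    change = np.asarray(change, dtype=float)
    responder = np.asarray(responder, dtype=bool)
    baseline = np.asarray(baseline, dtype=float)
    if np.isnan(change).any() or np.isnan(baseline).any():
        raise ValueError("fit_ancova expects complete cases (no NaN)")
    n = change.size
    n_resp = int(responder.sum())
    n_non = n - n_resp
    if n_resp == 0 or n_non == 0:
        raise ValueError("both responder groups must be non-empty")
    if n <= 3:
        raise ValueError(f"need more than 3 observations, got {n}")

    X = np.column_stack([np.ones(n), responder.astype(float), baseline])
    beta, _, _, _ = np.linalg.lstsq(X, change, rcond=None)
    resid = change - X @ beta
    df = n - 3
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = s2 * xtx_inv

    bl_mean = baseline.mean()
    lsm = {}
    for grp, flag in (("non", 0.0), ("resp", 1.0)):
        c = np.array([1.0, flag, bl_mean])
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        p = 2 * stats.t.sf(abs(est / se), df)
        lsm[grp] = (est, se, p)

    diff = -float(beta[1])  # non-responder minus responder
    se_diff = float(np.sqrt(cov[1, 1]))
    p_between = 2 * stats.t.sf(abs(beta[1] / se_diff), df)

    return AncovaResult(
        n_nonresponder=n_non,
        n_responder=n_resp,
        pct_nonresponder=100.0 * n_non / n,
        pct_responder=100.0 * n_resp / n,
        lsm_change_nonresponder=lsm["non"][0],
        se_nonresponder=lsm["non"][1],
        p_nonresponder=lsm["non"][2],
        lsm_change_responder=lsm["resp"][0],
        se_responder=lsm["resp"][1],
        p_responder=lsm["resp"][2],
        lsm_difference=diff,
        se_difference=se_diff,
        between_group_p=float(p_between),
    )


def responsiveness_table(
    scored: pd.DataFrame,
    statuses: pd.DataFrame,
    domains: list[str],
) -> pd.DataFrame:
    """One ANCOVA per domain x anchor; returns a long results table.

    ``scored`` has one row per subject with ``<domain>_baseline`` and
    ``<domain>_change`` columns; ``statuses`` is the long anchor-status table.
    Complete-case selection is per domain x anchor cell.
    """
    rows = []
    for domain in domains:
        for anchor, sub in statuses.groupby("anchor", sort=True):
            merged = sub.merge(scored, on="subject_id")
            merged = merged.dropna(
                subset=[f"{domain}_baseline", f"{domain}_change"]
            )
            if merged.empty or merged["responder"].nunique() < 2:
                continue
            res = fit_ancova(
                merged[f"{domain}_change"],
                merged["responder"],
                merged[f"{domain}_baseline"],
            )
            rows.append({"domain": domain, "anchor": anchor,
                         **res.__dict__})
    return pd.DataFrame(rows)
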