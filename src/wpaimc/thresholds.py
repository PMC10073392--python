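"""Meaningful within-patient change (MWPC) threshold estimation.

A meaningful-change threshold for a WPAI domain is calibrated against each
anchor's responder classification.  Improvement is a *negative* change score,
and a subject is predicted a responder when their change is at or below a
cut-off c (change <= c).  For each candidate c the 2x2 classification table
against the anchor yields sensitivity, specificity, PPV, NPV, the Youden
index YI(c) = sensitivity + specificity - 1, and the phi coefficient.  The
per-anchor optimal cut-off maximizes YI; the cross-anchor consensus threshold
is the grid candidate maximizing the *minimum* YI across anchors ("YI high
for all anchors").  Discrimination is summarized by logistic regression of
responder status on the change score and the concordance AUC, and eCDF curves
of change by responder group provide the graphical counterpart (the vertical
gap between group eCDFs at c equals YI(c)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RocRow", "fit_logistic_auc", "roc_grid", "optimal_cutoff",
    "consensus_threshold", "misclassification_rate", "ecdf_by_group",
    "auc_band", "default_cutoff_grid",
]


@dataclass(frozen=True)
class RocRow:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden: float
    phi: float


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(tp: int, fp: int, tn: int, fn: int,
                           cutoff: float = float("nan")) -> RocRow:
    """All 2x2 metrics from raw counts (building block for roc_grid)."""
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    phi_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    phi = (tp * tn - fp * fn) / np.sqrt(phi_den) if phi_den > 0 else float("nan")
    return RocRow(
        cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        ppv=_ratio(tp, tp + fp), npv=_ratio(tn, tn + fn),
        youden=sens + spec - 1.0, phi=float(phi),
    )


def auc_band(auc: float) -> str:
    """Discrimination label for an ROC AUC."""
    if not 0 <= auc <= 1:
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    if auc >= 0.9:
        return "outstanding"
    if auc >= 0.8:
        return "excellent"
    if auc >= 0.7:
        return "good"
    return "poor"


def fit_logistic_auc(responder, change):
    """Logistic fit of anchor response on change, plus concordance AUC.

    Returns (intercept, slope, auc, band, converged).  The AUC is the
    probability that a random responder has a *lower* (more improved) change
    than a random non-responder, ties counting one half — well-defined even
    under complete separation, where the ML coefficients diverge and are
    flagged non-converged.
    """
    responder = np.asarray(responder, dtype=bool)
    change = np.asarray(change, dtype=float)
    if responder.size < 10:
        raise ValueError("need at least 10 observations")
    if responder.all() or (~responder).all():
        raise ValueError("both classes must be present")

    # concordance over all responder/non-responder pairs via midranks
    ranks = stats.rankdata(change)
    n1 = int(responder.sum())
    n0 = responder.size - n1
    # responders are expected at *low* change: count pairs where responder < non
    auc = (ranks[~responder].sum() - n0 * (n0 + 1) / 2) / (n0 * n1)

    converged = True
    with np.errstate(all="ignore"):
        try:
            fit = sm.Logit(
                responder.astype(float),
                sm.add_constant(change),
            ).fit(disp=0, method="newton", tol=1e-8, maxiter=200)
            intercept, slope = float(fit.params[0]), float(fit.params[1])
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            intercept = slope = float("nan")
            converged = False
    if np.isfinite(auc) and auc in (0.0, 1.0):
        converged = False  # complete separation
    return intercept, slope, float(auc), auc_band(float(auc)), converged


def default_cutoff_grid(change, step: float = 10.0,
                        lo: float = -60.0, hi: float = 0.0) -> np.ndarray:
    """Candidate cut-offs: observed change values plus a fixed coarse grid."""
    coarse = np.arange(lo, hi + step / 2, step)
    return np.unique(np.concatenate([np.asarray(change, float), coarse]))


def roc_grid(responder, change, cutoffs=None) -> pd.DataFrame:
    """Classification metrics at every candidate cut-off.

    Predicted responder iff change <= cutoff (equality counts as predicted
    response).  Both anchor classes must be present.
    """
    responder = np.asarray(responder, dtype=bool)
    change = np.asarray(change, dtype=float)
    if responder.all() or (~responder).all():
        raise ValueError("both anchor classes must be present")
    if cutoffs is None:
        cutoffs = default_cutoff_grid(change)
    rows = []
    for c in np.asarray(cutoffs, dtype=float):
        pred = change <= c
        rows.append(classification_metrics(
            tp=int((pred & responder).sum()),
            fp=int((pred & ~responder).sum()),
            tn=int((~pred & ~responder).sum()),
            fn=int((~pred & responder).sum()),
            cutoff=float(c),
        ).__dict__)
    return pd.DataFrame(rows)


def optimal_cutoff(rows: pd.DataFrame) -> float:
    """Cut-off with maximal Youden index; ties go to smallest |cutoff|."""
    if len(rows) == 0:
        raise ValueError("empty ROC grid")
    best = rows[rows["youden"] == rows["youden"].max()]
    return float(best.loc[best["cutoff"].abs().idxmin(), "cutoff"])


def _round_to_grid(values: np.ndarray, step: float) -> np.ndarray:
    return np.round(np.asarray(values, float) / step) * step


def consensus_threshold(
    grids: dict[str, pd.DataFrame], grid_step: float = 10.0
) -> tuple[float, pd.DataFrame]:
    """Cross-anchor consensus MWPC by the max-min Youden rule.

    Each anchor's cut-offs are rounded to the grid step; a candidate must be
    supported by every anchor.  For each candidate, an anchor contributes the
    YI of its grid row nearest the candidate, and the selected candidate
    maximizes the minimum YI across anchors, ties going to the smallest
    absolute threshold.  Returns the consensus value and a per-anchor table
    of YI/phi/sensitivity at the selection, the "overlapping data"
    justification.
    """
    if not grids:
        raise ValueError("at least one anchor grid is required")
    rounded = {}
    for anchor, g in grids.items():
        g = g.copy()
        g["candidate"] = _round_to_grid(g["cutoff"].to_numpy(), grid_step)
        rounded[anchor] = g
    supports = [set(g["candidate"]) for g in rounded.values()]
    common = set.intersection(*supports)
    if not common:
        detail = {a: sorted(set(g["candidate"])) for a, g in rounded.items()}
        raise ValueError(f"disjoint candidate supports across anchors: {detail}")

    def _row_at(g: pd.DataFrame, cand: float) -> pd.Series:
        dist = (g["cutoff"] - cand).abs()
        at = g[dist == dist.min()]
        return at.loc[at["cutoff"].abs().idxmin()]

    best_value, best_min = None, -np.inf
    for cand in sorted(common, key=lambda v: (abs(v), v)):
        min_yi = min(_row_at(g, cand)["youden"] for g in rounded.values())
        if min_yi > best_min:
            best_min, best_value = min_yi, cand

    detail_rows = []
    for anchor, g in rounded.items():
        row = _row_at(g, best_value)
        detail_rows.append({
            "anchor": anchor, "cutoff": row["cutoff"],
            "youden": row["youden"], "phi": row["phi"],
            "sensitivity": row["sensitivity"],
            "specificity": row["specificity"],
        })
    return float(best_value), pd.DataFrame(detail_rows)


def misclassification_rate(rows: pd.DataFrame, threshold: float) -> float:
    """Share of anchor non-responders classified improved at the threshold.

    This is 1 - specificity at the grid row nearest the threshold (exact when
    the threshold is in the grid).
    """
    if len(rows) == 0:
        raise ValueError("empty ROC grid")
    idx = (rows["cutoff"] - threshold).abs().idxmin()
    return float(1.0 - rows.loc[idx, "specificity"])


def ecdf_by_group(change, responder) -> dict[bool, pd.DataFrame]:
    """Right-continuous eCDF points of change for each responder group.

    Returns {True: responder curve, False: non-responder curve}, each a
    DataFrame with columns x (sorted unique change values) and F (cumulative
    proportion at x).  The vertical gap between the curves at any x equals
    the Youden index of the cut-off x.
    """
    change = np.asarray(change, dtype=float)
    responder = np.asarray(responder, dtype=bool)
    out = {}
    for flag in (False, True):
        vals = np.sort(change[responder == flag])
        if vals.size == 0:
            raise ValueError("both groups must be non-empty")
        x, counts = np.unique(vals, return_counts=True)
        out[flag] = pd.DataFrame(
            {"x": x, "F": np.cumsum(counts) / vals.size}
        )
    return out
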