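"""Construct validity: Spearman correlations of WPAI scores with anchors.

Spearman's rank correlation (midranks for ties) is used because the scores are
not assumed normal.  Two interpretation band schemes are implemented: the
seven-level scheme used for reporting validity results, and the slightly
different scheme used when screening candidate anchors.  A candidate anchor is
considered adequate for a domain when |rho| >= 0.30; the absolute value is
used because WPAI (higher = worse) is scored opposite to MSQ (higher =
better).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_rho", "correlation_band", "anchor_eligibility",
    "correlation_matrix",
]

ELIGIBILITY_THRESHOLD = 0.30

# (lower bound on |rho|, label); boundary values go to the upper band
_SCHEMES = {
    "validity_report": [
        (0.70, "high"),
        (0.60, "moderate high"),
        (0.50, "moderate"),
        (0.40, "moderate low"),
        (0.30, "low"),
        (0.20, "negligible"),
        (0.00, "negligible-low"),
    ],
    "anchor_selection": [
        (0.90, "very high"),
        (0.70, "high"),
        (0.60, "moderate high"),
        (0.50, "moderate"),
        (0.40, "moderate low"),
        (0.30, "low"),
        (0.00, "negligible"),
    ],
}


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with midranks; NaN pairs are dropped.

    Returns NaN for constant input (correlation undefined) and requires at
    least 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def correlation_band(rho: float, scheme: str = "validity_report") -> str:
    """Interpretation label for |rho| under the chosen band scheme."""
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown band scheme {scheme!r}")
    a = abs(rho)
    if a > 1:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    for lower, label in _SCHEMES[scheme]:
        if a >= lower:
            return label
    raise AssertionError("unreachable: schemes cover [0, 1]")


def anchor_eligibility(correlations: pd.DataFrame) -> pd.DataFrame:
    """Flag anchor-domain pairs with |rho| >= 0.30 as eligible.

    ``correlations`` is a matrix (rows: WPAI domains, cols: anchors) of
    Spearman rhos; the result has the same shape with boolean entries.
    Configured anchors falling below threshold are flagged, not dropped.
    """
    return correlations.abs() >= ELIGIBILITY_THRESHOLD


def correlation_matrix(
    data: pd.DataFrame,
    domain_cols: list[str],
    anchor_cols: list[str],
    scheme: str = "validity_report",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman matrix of baseline domains vs anchors, plus bands.

    Returns (rho matrix, band-label matrix); pairs with < 3 complete
    observations are NaN / blank.
    """
    rho = pd.DataFrame(index=domain_cols, columns=anchor_cols, dtype=float)
    bands = pd.DataFrame(index=domain_cols, columns=anchor_cols, dtype=object)
    for d in domain_cols:
        for a in anchor_cols:
            try:
                r = spearman_rho(data[d], data[a])
            except ValueError:
                r = float("nan")
            rho.loc[d, a] = r
            bands.loc[d, a] = "" if np.isnan(r) else correlation_band(r, scheme)
    return rho, bands
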