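"""Published reference values from the CONQUER WPAI meaningful-change analysis.

The subject-level CONQUER (NCT03559257) data are access-restricted, but the
published analysis prints its operating-characteristic grids, responder
counts, and ANCOVA least-squares means for the overall population.  Those
printed values are inputs here: they let the classification arithmetic
(Youden index, PPV/NPV, phi, misclassification, consensus selection) be
checked for internal consistency and drive the consensus-threshold
computation on real grids without the raw data.

Domains: presenteeism, overall work productivity loss (owpl), non-work
activity impairment (activity).  Anchors: MHD50 (50% reduction in monthly
migraine headache days), MSQ_RFP, MSQ_RFR.  Cut-offs are WPAI change scores
in % units (negative = improvement).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["roc_reference", "ancova_reference", "responder_counts"]

_ROC_COLS = ["domain", "anchor", "cutoff", "sensitivity", "specificity",
             "ppv", "npv", "youden", "phi"]

_ROC_ROWS = [
    ("presenteeism", "MHD50", -39.96, 0.4085, 0.9014, 0.5800, 0.8205, 0.3099, 0.3523),
    ("presenteeism", "MHD50", -29.97, 0.4789, 0.8216, 0.4722, 0.8255, 0.3005, 0.2991),
    ("presenteeism", "MHD50", -19.98, 0.6197, 0.7230, 0.4272, 0.8508, 0.3427, 0.3087),
    ("presenteeism", "MSQ_RFP", -30.00, 0.4943, 0.8528, 0.5972, 0.7925, 0.3470, 0.3677),
    ("presenteeism", "MSQ_RFP", -20.00, 0.6207, 0.7513, 0.5243, 0.8177, 0.3720, 0.3566),
    ("presenteeism", "MSQ_RFP", -10.00, 0.7471, 0.5888, 0.4452, 0.8406, 0.3360, 0.3099),
    ("presenteeism", "MSQ_RFR", -29.99, 0.4875, 0.8382, 0.5417, 0.8066, 0.3257, 0.3368),
    ("presenteeism", "MSQ_RFR", -19.99, 0.6625, 0.7549, 0.5146, 0.8508, 0.4174, 0.3905),
    ("presenteeism", "MSQ_RFR", -10.00, 0.7250, 0.5686, 0.3973, 0.8406, 0.2936, 0.2643),
    ("owpl", "MHD50", -20.09, 0.5541, 0.8093, 0.5000, 0.8406, 0.3634, 0.3518),
    ("owpl", "MHD50", -19.79, 0.6216, 0.7488, 0.4600, 0.8519, 0.3705, 0.3399),
    ("owpl", "MHD50", -19.37, 0.6216, 0.7442, 0.4554, 0.8511, 0.3658, 0.3348),
    ("owpl", "MSQ_RFP", -22.17, 0.5730, 0.8550, 0.6375, 0.8182, 0.4280, 0.4416),
    ("owpl", "MSQ_RFP", -22.02, 0.5730, 0.8500, 0.6296, 0.8173, 0.4230, 0.4348),
    ("owpl", "MSQ_RFP", -20.12, 0.5730, 0.8450, 0.6220, 0.8164, 0.4180, 0.4281),
    ("owpl", "MSQ_RFR", -20.01, 0.6463, 0.7778, 0.5354, 0.8474, 0.4241, 0.4029),
    ("owpl", "MSQ_RFR", -19.39, 0.6585, 0.7729, 0.5347, 0.8511, 0.4315, 0.4080),
    ("owpl", "MSQ_RFR", -19.16, 0.6585, 0.7681, 0.5294, 0.8503, 0.4267, 0.4025),
    ("activity", "MHD50", -29.95, 0.5040, 0.7555, 0.4468, 0.7954, 0.2595, 0.2507),
    ("activity", "MHD50", -19.97, 0.6480, 0.6270, 0.4050, 0.8197, 0.2750, 0.2485),
    ("activity", "MHD50", -9.98, 0.8000, 0.4796, 0.3759, 0.8596, 0.2796, 0.2566),
    ("activity", "MSQ_RFP", -29.98, 0.4901, 0.7713, 0.5248, 0.7459, 0.2614, 0.2660),
    ("activity", "MSQ_RFP", -19.99, 0.6358, 0.6451, 0.4800, 0.7746, 0.2808, 0.2674),
    ("activity", "MSQ_RFP", -10.00, 0.7815, 0.4949, 0.4436, 0.8146, 0.2763, 0.2671),
    ("activity", "MSQ_RFR", -40.01, 0.4296, 0.8770, 0.6042, 0.7787, 0.3067, 0.3427),
    ("activity", "MSQ_RFR", -30.01, 0.5630, 0.7896, 0.5390, 0.8053, 0.3526, 0.3484),
    ("activity", "MSQ_RFR", -20.00, 0.6741, 0.6472, 0.4550, 0.8197, 0.3213, 0.2971),
]

_ANCOVA_COLS = [
    "domain", "anchor", "n_nonresponder", "pct_nonresponder",
    "n_responder", "pct_responder",
    "lsm_change_nonresponder", "se_nonresponder",
    "lsm_change_responder", "se_responder",
    "lsm_difference", "se_difference",
]

_ANCOVA_ROWS = [
    ("presenteeism", "MSQ_RFP", 197, 69.4, 87, 30.6, -1.211, 1.591, -24.269, 2.396, 23.058, 2.878),
    ("presenteeism", "MSQ_RFR", 204, 71.8, 80, 28.2, -1.742, 1.569, -24.933, 2.506, 23.191, 2.957),
    ("presenteeism", "MHD50", 213, 75.0, 71, 25.0, -2.450, 1.546, -25.750, 2.678, 23.300, 3.092),
    ("owpl", "MSQ_RFP", 200, 69.2, 89, 30.8, -1.872, 1.715, -25.459, 2.574, 23.587, 3.096),
    ("owpl", "MSQ_RFR", 207, 71.6, 82, 28.4, -2.246, 1.683, -26.529, 2.674, 24.283, 3.160),
    ("owpl", "MHD50", 215, 74.4, 74, 25.6, -3.343, 1.682, -25.968, 2.868, 22.626, 3.326),
    ("activity", "MSQ_RFP", 293, 66.0, 151, 34.0, -7.470, 1.445, -24.710, 2.015, 17.239, 2.484),
    ("activity", "MSQ_RFR", 309, 69.6, 135, 30.4, -6.353, 1.352, -29.310, 2.045, 22.957, 2.452),
    ("activity", "MHD50", 319, 71.8, 125, 28.2, -7.616, 1.364, -27.923, 2.179, 20.307, 2.571),
]


def roc_reference() -> pd.DataFrame:
    """Published ROC grid rows (overall population), one row per cut-off."""
    return pd.DataFrame(_ROC_ROWS, columns=_ROC_COLS)


def ancova_reference() -> pd.DataFrame:
    """Published ANCOVA responder counts and least-squares means."""
    return pd.DataFrame(_ANCOVA_ROWS, columns=_ANCOVA_COLS)


def responder_counts(domain: str, anchor: str) -> tuple[int, int]:
    """(n_responder, n_nonresponder) for a domain x anchor cell."""
    t = ancova_reference()
    row = t[(t["domain"] == domain) & (t["anchor"] == anchor)].iloc[0]
    return int(row["n_responder"]), int(row["n_nonresponder"])
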