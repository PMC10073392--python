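"""Anchor-based responder classification.

Three external anchors with established meaningful-change definitions are used
to classify each subject as responder or non-responder over baseline to
Month 3:

* MSQ-RFR: improvement (increase) of >= 25.71 points
* MSQ-RFP: improvement (increase) of >= 20.00 points
* MHD50:   a >= 50% reduction in monthly migraine headache days

Boundary equality counts as response.  Worsening or no change is a
non-response, never an exclusion; a subject is excluded from an anchor's
analyses only when a baseline or Month-3 value is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AnchorDefinition", "AnchorStatus", "DEFAULT_ANCHORS",
    "classify_responder", "anchor_status_table",
]


@dataclass(frozen=True)
class AnchorDefinition:
    name: str
    kind: str  # "absolute_change" | "relative_reduction"
    threshold: float  # points (absolute) or proportion (relative)
    improvement_sign: int = 1  # +1: improvement is an increase; -1: a decrease

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("anchor threshold must be positive")
        if self.kind not in ("absolute_change", "relative_reduction"):
            raise ValueError(f"unknown anchor kind {self.kind!r}")


DEFAULT_ANCHORS = {
    "MSQ_RFR": AnchorDefinition("MSQ_RFR", "absolute_change", 25.71, +1),
    "MSQ_RFP": AnchorDefinition("MSQ_RFP", "absolute_change", 20.00, +1),
    "MHD50": AnchorDefinition("MHD50", "relative_reduction", 0.5, -1),
}


@dataclass(frozen=True)
class AnchorStatus:
    subject_id: object
    anchor: str
    responder: bool
    change: float


def classify_responder(
    defn: AnchorDefinition, baseline: float, month3: float, subject_id=None
) -> AnchorStatus | None:
    """Classify one subject on one anchor; None when a value is missing.

    Absolute-change anchors respond when the improvement-signed change meets
    the threshold; relative-reduction anchors (MHD50) when the fractional
    reduction from baseline does.
    """
    if any(v is None or (isinstance(v, float) and math.isnan(v))
           for v in (baseline, month3)):
        return None
    change = month3 - baseline
    if defn.kind == "absolute_change":
        responder = defn.improvement_sign * change >= defn.threshold
    else:
        if baseline <= 0:
            raise ValueError("relative-reduction anchor requires baseline > 0")
        responder = (baseline - month3) / baseline >= defn.threshold
    return AnchorStatus(subject_id, defn.name, bool(responder), change)


def anchor_status_table(
    values: pd.DataFrame,
    anchors: dict[str, AnchorDefinition] | None = None,
) -> pd.DataFrame:
    """Long-format responder table from per-subject anchor values.

    ``values`` has one row per subject with columns ``subject_id`` and
    ``<anchor>_baseline`` / ``<anchor>_month3`` for each anchor.  Subjects
    with a missing value for an anchor are omitted from that anchor's rows.
    """
    anchors = anchors or DEFAULT_ANCHORS
    rows = []
    for _, row in values.iterrows():
        for name, defn in anchors.items():
            if (defn.kind == "relative_reduction"
                    and not pd.isna(row.get(f"{name}_baseline"))
                    and row[f"{name}_baseline"] <= 0):
                continue  # no defined relative change from a zero baseline
            status = classify_responder(
                defn, row.get(f"{name}_baseline"), row.get(f"{name}_month3"),
                subject_id=row["subject_id"],
            )
            if status is not None:
                rows.append({
                    "subject_id": status.subject_id,
                    "anchor": name,
                    "responder": status.responder,
                    "change": status.change,
                })
    return pd.DataFrame(rows, columns=["subject_id", "anchor", "responder", "change"])
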