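"""Sample-specific sectioning-point metric sex classification.

Long-bone measurements are sexually dimorphic: male means exceed female
means for humeral and femoral breadths, lengths and head diameters. With no
population-specific discriminant functions available, each measurement is
split at the *sample mean* (the sectioning point): a value strictly greater
than the mean votes male, a value equal to or below it votes female. Votes
across the available measurements are combined by simple majority; an exact
tie is indeterminate.

An externally produced morphological estimate (e.g. pelvic and cranial trait
scoring classified by a trained model) can be reconciled against the metric
call: when the two disagree and the morphological estimate rests on cranial
traits only, the post-cranial metric call is preferred (post-cranial
estimates outperform skull-only ones); when the pelvis was scored, the
morphological call stands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MEASUREMENTS",
    "SexEstimate",
    "sectioning_points",
    "classify_metric",
    "reconcile",
    "classify_table",
]

#: Post-cranial measurement panel (all in mm).
MEASUREMENTS = (
    "humerus_epicondylar_breadth",
    "humerus_max_length",
    "humerus_vertical_head_diameter",
    "humerus_transverse_head_diameter",
    "femur_vertical_head_diameter",
    "femur_bicondylar_width",
)

MALE, FEMALE, INDETERMINATE = "male", "female", "indeterminate"
_CODE = {MALE: 0, FEMALE: 1}


@dataclass(frozen=True)
class SexEstimate:
    """A sex call with its provenance and (when determinate) the 0/1 code."""

    call: str  # male / female / indeterminate
    source: str = "metric"  # metric / morphological / reconciled
    votes: dict = field(default_factory=dict)  # measurement -> vote (metric calls)
    reason: str = ""

    def __post_init__(self) -> None:
        if self.call not in (MALE, FEMALE, INDETERMINATE):
            raise ValueError(f"invalid call {self.call!r}")

    @property
    def code(self):
        """0 (male) / 1 (female); None when indeterminate."""
        return _CODE.get(self.call)

    @property
    def determinate(self) -> bool:
        return self.call != INDETERMINATE


def sectioning_points(panel_table: pd.DataFrame, measurements=MEASUREMENTS) -> dict:
    """Sample-specific sectioning point (arithmetic mean) per measurement.

    Missing values are skipped; a measurement with fewer than two non-missing
    values is excluded with a warning. Present values must be positive.
    """
    points = {}
    for m in measurements:
        if m not in panel_table.columns:
            continue
        vals = pd.to_numeric(panel_table[m], errors="coerce").dropna()
        if (vals <= 0).any():
            raise ValueError(f"measurement {m}: non-positive value present")
        if len(vals) < 2:
            warnings.warn(f"measurement {m}: fewer than 2 values, excluded from sectioning")
            continue
        points[m] = float(vals.mean())
    return points


def classify_metric(individual, points: dict) -> SexEstimate:
    """Classify one individual from its measurement panel.

    Per measurement: male if value > sectioning point, female if value <= it
    (values exactly at the mean classify female). The combined call is the
    majority of votes; an exact tie or no usable measurement is indeterminate.
    """
    if isinstance(individual, pd.Series):
        individual = individual.to_dict()
    votes = {}
    for m, point in points.items():
        v = individual.get(m)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        v = float(v)
        if v <= 0:
            raise ValueError(f"measurement {m}: non-positive value {v}")
        votes[m] = MALE if v > point else FEMALE
    if not votes:
        return SexEstimate(call=INDETERMINATE, source="metric",
                           reason="no usable measurement")
    n_m = sum(1 for v in votes.values() if v == MALE)
    n_f = len(votes) - n_m
    if n_m == n_f:
        return SexEstimate(call=INDETERMINATE, source="metric", votes=votes,
                           reason="tied votes")
    return SexEstimate(call=MALE if n_m > n_f else FEMALE, source="metric", votes=votes)


def reconcile(morph: SexEstimate, metric: SexEstimate,
              pelvis_scored: bool = False, cranium_scored: bool = False) -> SexEstimate:
    """Reconcile a morphological and a metric sex estimate.

    Agreement keeps the shared call. On disagreement, the metric (post-
    cranial) call wins when only cranial morphological traits were scored;
    a pelvis-backed morphological call wins otherwise. A single determinate
    input is returned as-is; two indeterminate inputs stay indeterminate.
    """
    if not morph.determinate and not metric.determinate:
        return SexEstimate(call=INDETERMINATE, source="reconciled",
                           reason="both estimates indeterminate")
    if not morph.determinate:
        return SexEstimate(call=metric.call, source="reconciled", votes=metric.votes)
    if not metric.determinate:
        return SexEstimate(call=morph.call, source="reconciled")
    if morph.call == metric.call:
        return SexEstimate(call=morph.call, source="reconciled", votes=metric.votes)
    if cranium_scored and not pelvis_scored:
        return SexEstimate(call=metric.call, source="reconciled", votes=metric.votes,
                           reason="disagreement; cranium-only morphology, metric prioritised")
    return SexEstimate(call=morph.call, source="reconciled",
                       reason="disagreement; pelvis-backed morphology retained")


def classify_table(panel_table: pd.DataFrame, morph_col: str | None = None,
                   pelvis_col: str = "pelvis_scored",
                   cranium_col: str = "cranium_scored") -> pd.DataFrame:
    """Classify every row of a measurement table; optionally reconcile.

    Returns a frame with columns call, code, source and the per-measurement
    vote detail. When ``morph_col`` is given (values male/female/
    indeterminate) the result is the reconciled call using the pelvis/cranium
    availability flags.
    """
    points = sectioning_points(panel_table)
    rows = []
    for _, row in panel_table.iterrows():
        est = classify_metric(row, points)
        if morph_col is not None:
            morph_call = row.get(morph_col, INDETERMINATE)
            if isinstance(morph_call, float) and np.isnan(morph_call):
                morph_call = INDETERMINATE
            morph = SexEstimate(call=str(morph_call), source="morphological")
            est = reconcile(morph, est,
                            pelvis_scored=bool(row.get(pelvis_col, False)),
                            cranium_scored=bool(row.get(cranium_col, False)))
        rows.append({"call": est.call, "code": est.code, "source": est.source,
                     "votes": ";".join(f"{k}={v}" for k, v in est.votes.items()),
                     "reason": est.reason})
    return pd.DataFrame(rows, index=panel_table.index)
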