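"""Decision-timepoint detection and early-treatment cohort selection.

An encounter enters the analysis cohort when its hourly respiratory-failure
risk score first meets the high-risk threshold (T0) and the first
respiratory-support event strictly after T0 is either NIV or HFNC.  The risk
model itself is a pluggable input — scores arrive as a column, not a model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import InputError

TREATMENT_LABELS = ("NIV", "HFNC", "IMV", "other")


@dataclass
class RiskTrajectory:
    encounter_id: object
    scores: np.ndarray  # hourly risk scores
    threshold: float


@dataclass
class TreatmentTimeline:
    encounter_id: object
    events: List[Tuple[float, str]]  # (timestamp hours, label), non-decreasing

    def validate(self) -> None:
        ts = [t for t, _ in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise InputError(f"timeline timestamps decrease in {self.encounter_id}")


def find_t0(traj: RiskTrajectory) -> Optional[int]:
    """First hour at which the score meets or exceeds the threshold; None if never."""
    scores = np.asarray(traj.scores, dtype=float)
    if scores.size == 0:
        raise InputError("empty risk trajectory")
    hits = np.flatnonzero(scores >= traj.threshold)
    return int(hits[0]) if hits.size else None


def select_early_treatment(t0: float, timeline: TreatmentTimeline
                           ) -> Tuple[bool, Optional[str]]:
    """Cohort membership at T0: include iff the first respiratory-support
    event strictly after t0 is NIV or HFNC; that event's label is the
    assigned treatment.  A first post-T0 event of IMV (or no event) excludes
    the encounter.
    """
    timeline.validate()
    post = [(t, lab) for t, lab in timeline.events
            if t > t0 and lab in ("NIV", "HFNC", "IMV")]
    if not post:
        return False, None
    first_label = post[0][1]
    if first_label in ("NIV", "HFNC"):
        return True, first_label
    return False, None


def calibrate_threshold(trajectories: Sequence[RiskTrajectory],
                        labels: Sequence[int],
                        target_sensitivity: float = 0.60) -> float:
    """Scan score thresholds to hit a target encounter-level sensitivity.

    An encounter is flagged when its max hourly score meets the threshold;
    sensitivity is computed over label-positive encounters.  Returns the
    largest threshold whose sensitivity is >= the target (fewest false
    positives subject to the sensitivity floor).
    """
    max_scores = np.array([np.max(np.asarray(t.scores, dtype=float))
                           for t in trajectories])
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise InputError("no positive encounters to calibrate against")
    pos = max_scores[labels == 1]
    candidates = np.unique(pos)[::-1]  # high to low
    for thr in candidates:
        if np.mean(pos >= thr) >= target_sensitivity:
            return float(thr)
    return float(candidates[-1])


def build_cohort_membership(trajectories: Sequence[RiskTrajectory],
                            timelines: Sequence[TreatmentTimeline]) -> pd.DataFrame:
    """Apply T0 detection and early-treatment selection to paired inputs."""
    tl_by_id = {tl.encounter_id: tl for tl in timelines}
    rows = []
    for traj in trajectories:
        t0 = find_t0(traj)
        included, treatment = False, None
        if t0 is not None and traj.encounter_id in tl_by_id:
            included, treatment = select_early_treatment(t0, tl_by_id[traj.encounter_id])
        rows.append({"encounter_id": traj.encounter_id, "t0_hour": t0,
                     "included": included, "treatment": treatment})
    return pd.DataFrame(rows)


def read_trajectories(path, threshold: float) -> List[RiskTrajectory]:
    """Read hourly risk scores (encounter_id, hour, score) from delimited text."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for enc, grp in df.groupby("encounter_id", sort=True):
        grp = grp.sort_values("hour")
        out.append(RiskTrajectory(enc, grp["score"].to_numpy(float), threshold))
    return out


def read_timelines(path) -> List[TreatmentTimeline]:
    """Read treatment events (encounter_id, timestamp_hours, label)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for enc, grp in df.groupby("encounter_id", sort=True):
        grp = grp.sort_values("timestamp_hours")
        out.append(TreatmentTimeline(
            enc, list(zip(grp["timestamp_hours"].astype(float),
                          grp["label"].astype(str)))))
    return out
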