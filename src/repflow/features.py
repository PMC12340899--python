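"""EHR preprocessing: hourly binning, bounded carry-forward, imputation, and
per-variable derived features.

Irregular timestamped measurements are resampled onto an hourly grid (median
per bin), missing hours are filled by carrying the last observation forward
for at most 24 hours, and anything still missing is mean-imputed with means
computed on the training split only.  From the grid, each variable yields
four features at the decision hour: the current value, a 72-hour baseline
mean, the change between the last two measurements (delta), and the time
since the variable was last measured (TSLM, capped).

Conventions (the raw records do not pin these down):

* hour bins are half-open ``[h, h+1)`` hours from admission;
* the baseline window covers the 72 hours strictly preceding the reference
  hour, over actually-observed bins only; if empty it falls back to the
  variable's training mean;
* delta is computed between the last two *observed* hourly bins and is 0
  when fewer than two exist;
* TSLM is capped at 72 h, which is also the sentinel for never-measured
  variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

TSLM_CAP_HOURS = 72.0
BASELINE_WINDOW_HOURS = 72
FEATURE_KINDS = ("value", "baseline", "delta", "tslm")


@dataclass
class EventStream:
    """Irregular measurements for one encounter: (variable, minutes, value)."""

    encounter_id: object
    records: pd.DataFrame  # columns: variable, timestamp_minutes, value

    def validate(self) -> None:
        ts = self.records["timestamp_minutes"].to_numpy(float)
        vals = self.records["value"].to_numpy(float)
        if len(ts) and ts.min() < 0:
            raise InputError(f"negative timestamp in encounter {self.encounter_id}")
        if len(vals) and not np.all(np.isfinite(vals)):
            raise InputError(f"non-finite value in encounter {self.encounter_id}")

    @staticmethod
    def from_frame(streams: pd.DataFrame) -> List["EventStream"]:
        return [EventStream(enc, grp.drop(columns=["encounter_id"]))
                for enc, grp in streams.groupby("encounter_id", sort=True)]


@dataclass
class HourlyGrid:
    """Hour x variable grid: values (NaN = missing), observed flags, TSLM.

    ``observed`` marks hours with an actual (non-carried) measurement;
    ``tslm_hours`` is hours since the last actual measurement (0 at observed
    hours, +inf before the first measurement).
    """

    encounter_id: object
    variables: List[str]
    values: np.ndarray      # (n_hours, n_vars) float, NaN where missing
    observed: np.ndarray    # (n_hours, n_vars) bool
    tslm_hours: np.ndarray  # (n_hours, n_vars) float, inf if never measured

    @property
    def n_hours(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "HourlyGrid":
        return HourlyGrid(self.encounter_id, list(self.variables),
                          self.values.copy(), self.observed.copy(),
                          self.tslm_hours.copy())


def bin_hourly(stream: EventStream, variables: Sequence[str],
               n_hours: Optional[int] = None) -> HourlyGrid:
    """Resample a stream onto hourly bins, taking the median within each bin."""
    stream.validate()
    rec = stream.records
    if n_hours is None:
        if len(rec):
            n_hours = int(math.floor(rec["timestamp_minutes"].max() / 60.0)) + 1
        else:
            n_hours = 1
    nv = len(variables)
    values = np.full((n_hours, nv), np.nan)
    observed = np.zeros((n_hours, nv), dtype=bool)
    var_index = {v: j for j, v in enumerate(variables)}

    if len(rec):
        hours = np.floor(rec["timestamp_minutes"].to_numpy(float) / 60.0).astype(int)
        for (var, h), grp in rec.assign(_hour=hours).groupby(["variable", "_hour"]):
            j = var_index.get(var)
            if j is None or h >= n_hours:
                continue
            values[h, j] = float(np.median(grp["value"].to_numpy(float)))
            observed[h, j] = True

    tslm = _tslm_from_observed(observed)
    return HourlyGrid(stream.encounter_id, list(variables), values, observed, tslm)


def _tslm_from_observed(observed: np.ndarray) -> np.ndarray:
    n_hours, nv = observed.shape
    tslm = np.full((n_hours, nv), np.inf)
    last = np.full(nv, -np.inf)
    hours = np.arange(n_hours, dtype=float)
    for h in range(n_hours):
        last = np.where(observed[h], hours[h], last)
        tslm[h] = hours[h] - last
    return tslm


def carry_forward(grid: HourlyGrid, max_hours: int = 24) -> HourlyGrid:
    """Fill missing hours with the most recent observation aged <= max_hours.

    Observed flags are untouched; hours whose last measurement is older than
    ``max_hours`` stay missing.  Idempotent.
    """
    out = grid.copy()
    n_hours, nv = out.values.shape
    last_val = np.full(nv, np.nan)
    for h in range(n_hours):
        last_val = np.where(out.observed[h], out.values[h], last_val)
        age = out.tslm_hours[h]
        fill = (~out.observed[h]) & (age <= max_hours) & np.isfinite(last_val)
        out.values[h] = np.where(fill, last_val, out.values[h])
    return out


def compute_training_means(grids: Sequence[HourlyGrid]) -> Dict[str, float]:
    """Per-variable mean of observed bin values across training encounters."""
    sums: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for g in grids:
        for j, v in enumerate(g.variables):
            obs = g.observed[:, j]
            sums[v] = sums.get(v, 0.0) + float(np.nansum(np.where(obs, g.values[:, j], 0.0)))
            counts[v] = counts.get(v, 0) + int(obs.sum())
    return {v: (sums[v] / counts[v]) if counts[v] else float("nan") for v in sums}


def impute_mean(grid: HourlyGrid, training_means: Dict[str, float]) -> HourlyGrid:
    """Replace remaining missing values with training-split means."""
    out = grid.copy()
    for j, v in enumerate(out.variables):
        if v not in training_means:
            raise ConfigurationError(f"variable {v!r} absent from training means")
        col = out.values[:, j]
        col[np.isnan(col)] = training_means[v]
    return out


@dataclass
class EncounterFeatures:
    """Per-variable (value, baseline, delta, tslm) plus untransformed statics."""

    encounter_id: object
    variables: List[str]
    value: np.ndarray
    baseline: np.ndarray
    delta: np.ndarray
    tslm: np.ndarray
    static: Dict[str, float] = field(default_factory=dict)

    def vector(self) -> np.ndarray:
        parts = [self.value, self.baseline, self.delta, self.tslm,
                 np.array([self.static[k] for k in sorted(self.static)])]
        return np.concatenate(parts)

    def manifest(self) -> pd.DataFrame:
        rows = [(v, kind) for kind in FEATURE_KINDS for v in self.variables]
        rows += [(k, "static") for k in sorted(self.static)]
        return pd.DataFrame(rows, columns=["variable", "feature_kind"])


def derive_features(grid: HourlyGrid, at_hour: int,
                    training_means: Optional[Dict[str, float]] = None,
                    static: Optional[Dict[str, float]] = None) -> EncounterFeatures:
    """Derive the four per-variable features at the decision hour.

    ``grid`` should already be carried forward (and imputed, if a dense
    current-value column is required).  Baseline and delta are computed over
    *observed* bins only, so they never see carried or imputed values.
    """
    if not (0 <= at_hour < grid.n_hours):
        raise InputError(f"at_hour {at_hour} outside grid of {grid.n_hours} hours")
    nv = len(grid.variables)
    value = grid.values[at_hour].copy()
    baseline = np.full(nv, np.nan)
    delta = np.zeros(nv)
    tslm = np.minimum(grid.tslm_hours[at_hour], TSLM_CAP_HOURS)

    lo = max(0, at_hour - BASELINE_WINDOW_HOURS)
    for j, v in enumerate(grid.variables):
        obs_hours = np.flatnonzero(grid.observed[:at_hour + 1, j])
        window = obs_hours[(obs_hours >= lo) & (obs_hours < at_hour)]
        if len(window):
            baseline[j] = grid.values[window, j].mean()
        elif training_means is not None and v in training_means:
            baseline[j] = training_means[v]
        if len(obs_hours) >= 2:
            delta[j] = (grid.values[obs_hours[-1], j]
                        - grid.values[obs_hours[-2], j])
        if np.isnan(value[j]) and training_means is not None and v in training_means:
            value[j] = training_means[v]

    return EncounterFeatures(grid.encounter_id, list(grid.variables),
                             value, baseline, delta, tslm, static or {})


def preprocess_streams(streams: pd.DataFrame, at_hours: Dict[object, int],
                       variables: Optional[Sequence[str]] = None,
                       training_means: Optional[Dict[str, float]] = None,
                       max_carry_hours: int = 24) -> pd.DataFrame:
    """Full pipeline: bin -> carry-forward -> impute -> derive, per encounter.

    ``at_hours`` maps encounter id to its decision hour (T0).  If
    ``training_means`` is None, means are computed from all given encounters
    (appropriate only when they form the training split).  Returns a wide
    table, one row per encounter, columns named ``<variable>__<kind>``.
    """
    all_streams = EventStream.from_frame(streams)
    if variables is None:
        variables = sorted(streams["variable"].unique())
    n_hours = max(at_hours.values()) + 1 if at_hours else 1
    grids = [bin_hourly(s, variables, n_hours=max(
        n_hours, int(math.floor(s.records["timestamp_minutes"].max() / 60.0)) + 1
        if len(s.records) else 1)) for s in all_streams]
    grids = [carry_forward(g, max_hours=max_carry_hours) for g in grids]
    if training_means is None:
        training_means = compute_training_means(grids)

    rows = []
    for g in grids:
        if g.encounter_id not in at_hours:
            continue
        g = impute_mean(g, training_means)
        feats = derive_features(g, at_hours[g.encounter_id],
                                training_means=training_means)
        row = {"encounter_id": g.encounter_id}
        for kind in FEATURE_KINDS:
            arr = getattr(feats, kind if kind != "value" else "value")
            for j, v in enumerate(variables):
                row[f"{v}__{kind}"] = arr[j]
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(table: pd.DataFrame, path, manifest_path=None) -> None:
    table.to_csv(path, sep="\t", index=False)
    if manifest_path is not None:
        cols = [c for c in table.columns if "__" in c]
        manifest = pd.DataFrame(
            [c.rsplit("__", 1) for c in cols], columns=["variable", "feature_kind"])
        manifest.to_csv(manifest_path, sep="\t", index=False)
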