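"""Feature-vector construction at arbitrary query times.

A snapshot takes, for each registry variable, the last measurement at or
before the query time whose staleness does not exceed the variable's
forward-fill limit (2 h for vitals, 26 h for labs and ventilator
settings). Expired or never-measured variables fall back to their
imputation policy: training-population mean for most, 0.21 for FiO2, and
left missing for MAWP and PIP. Shock index is recomputed as heart rate /
systolic blood pressure. A snapshot is only valid for scoring when both
heart rate and systolic blood pressure are available (measured or
forward-filled).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import (
    IMPUTE_CONSTANT,
    IMPUTE_LEAVE_ABSENT,
    IMPUTE_POPULATION_MEAN,
    REQUIRED_VARIABLES,
    Registry,
    default_registry,
)

PROV_MEASURED = "measured"
PROV_FORWARD_FILLED = "forward_filled"
PROV_IMPUTED = "imputed"
PROV_ABSENT = "absent"
PROV_MASKED = "masked"

#: invasive/noninvasive pairs merged into a single series (invasive wins)
_BP_MERGE = {
    "systolic_bp": ("systolic_bp_invasive", "systolic_bp_noninvasive"),
    "diastolic_bp": ("diastolic_bp_invasive", "diastolic_bp_noninvasive"),
    "mean_bp": ("mean_bp_invasive", "mean_bp_noninvasive"),
}
#: timestamps rounded to this many hours when testing simultaneity
_BP_TIME_BIN = 1.0 / 60.0


@dataclass
class PopulationStats:
    """Per-variable summaries of raw measured training values.

    ``means`` backs mean imputation; ``samples`` (a bounded subsample of
    measured values) backs empirical-marginal redraws for feature
    uncertainty.
    """

    means: dict[str, float] = field(default_factory=dict)
    samples: dict[str, list[float]] = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"means": self.means, "samples": self.samples}, fh)

    @classmethod
    def load(cls, path) -> "PopulationStats":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(means=doc["means"], samples=doc["samples"])


@dataclass
class FeatureVector:
    stay_id: str
    time: float
    values: dict[str, float]  # NaN where absent
    provenance: dict[str, str]
    valid: bool


def merge_blood_pressure(observations: pd.DataFrame) -> pd.DataFrame:
    """Collapse invasive/noninvasive BP series into single variables.

    When both routes are charted in the same one-minute bin, the invasive
    value is kept. Other variables pass through untouched.
    """
    if observations.empty:
        return observations.copy()
    out = observations.copy()
    for merged, (inv, noninv) in _BP_MERGE.items():
        mask = out["variable"].isin((inv, noninv))
        if not mask.any():
            continue
        sub = out[mask].copy()
        sub["_bin"] = np.round(sub["time"] / _BP_TIME_BIN).astype(np.int64)
        # invasive sorts first -> kept by drop_duplicates
        sub["_prio"] = np.where(sub["variable"] == inv, 0, 1)
        sub = (sub.sort_values(["stay_id", "_bin", "_prio"])
                  .drop_duplicates(["stay_id", "_bin"], keep="first"))
        sub["variable"] = merged
        out = pd.concat([out[~mask], sub.drop(columns=["_bin", "_prio"])],
                        ignore_index=True)
    return out.sort_values(["stay_id", "variable", "time"]).reset_index(drop=True)


def compute_population_stats(observations: pd.DataFrame,
                             stays: pd.DataFrame,
                             registry: Registry | None = None,
                             max_samples: int = 512,
                             seed: int = 0) -> PopulationStats:
    """Means and marginal subsamples from raw measured values only.

    Forward-filled copies are never included, so stale measurements do not
    bias the mean. ``age`` is summarized from the stay table.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    stats = PopulationStats()
    for name in registry.names:
        if name == "age":
            vals = stays["age"].to_numpy(dtype=float)
        elif name == "shock_index":
            continue  # derived after the fact, below
        else:
            vals = observations.loc[observations["variable"] == name,
                                    "value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        stats.means[name] = float(vals.mean())
        k = min(max_samples, vals.size)
        pick = rng.choice(vals, size=k, replace=False)
        stats.samples[name] = [float(v) for v in pick]
    if "heart_rate" in stats.means and "systolic_bp" in stats.means:
        si = stats.means["heart_rate"] / stats.means["systolic_bp"]
        stats.means["shock_index"] = float(si)
        hr = np.asarray(stats.samples["heart_rate"])
        sbp = np.asarray(stats.samples["systolic_bp"])
        k = min(hr.size, sbp.size)
        stats.samples["shock_index"] = [float(v) for v in hr[:k] / sbp[:k]]
    return stats


class StayObservations:
    """Per-variable sorted (times, values) index for one stay's observations."""

    def __init__(self, observations: pd.DataFrame, registry: Registry):
        self._series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, grp in observations.groupby("variable", sort=False):
            if name not in registry:
                raise ValueError(f"unknown variable {name!r} in observations")
            grp = grp.sort_values("time")
            self._series[str(name)] = (grp["time"].to_numpy(dtype=float),
                                       grp["value"].to_numpy(dtype=float))

    def last_before(self, name: str, t: float) -> tuple[float, float] | None:
        """(time, value) of the latest measurement at time <= t, if any."""
        if name not in self._series:
            return None
        times, values = self._series[name]
        idx = np.searchsorted(times, t, side="right") - 1
        if idx < 0:
            return None
        return float(times[idx]), float(values[idx])


def snapshot(stay_obs: StayObservations,
             stats: PopulationStats,
             t: float,
             *,
             stay_id: str = "",
             age: float | None = None,
             mode: str = "all",
             registry: Registry | None = None) -> FeatureVector:
    """Build the feature vector for one stay at query time ``t``."""
    if t < 0:
        raise ValueError("query time must be >= 0")
    registry = registry or default_registry()
    visible = registry.mode_variables(mode)

    values: dict[str, float] = {}
    prov: dict[str, str] = {}

    def impute(spec):
        if spec.impute == IMPUTE_CONSTANT:
            return float(spec.impute_value), PROV_IMPUTED
        if spec.impute == IMPUTE_LEAVE_ABSENT:
            return math.nan, PROV_ABSENT
        mean = stats.means.get(spec.name)
        if mean is None:
            return math.nan, PROV_ABSENT
        return float(mean), PROV_IMPUTED

    for spec in registry.specs:
        name = spec.name
        if name == "shock_index":
            continue  # derived last
        if name not in visible:
            values[name], prov[name] = impute(spec)
            if prov[name] == PROV_IMPUTED:
                prov[name] = PROV_MASKED
            continue
        if name == "age":
            if age is not None and math.isfinite(age):
                values[name], prov[name] = float(age), PROV_MEASURED
            else:
                values[name], prov[name] = impute(spec)
            continue
        found = stay_obs.last_before(name, t)
        if found is not None:
            obs_t, obs_v = found
            staleness = t - obs_t
            if staleness <= spec.fill_limit:
                obs_v = min(max(obs_v, spec.low), spec.high)
                values[name] = obs_v
                prov[name] = PROV_MEASURED if staleness == 0 else PROV_FORWARD_FILLED
                continue
        values[name], prov[name] = impute(spec)

    hr_ok = prov.get("heart_rate") in (PROV_MEASURED, PROV_FORWARD_FILLED)
    sbp_ok = prov.get("systolic_bp") in (PROV_MEASURED, PROV_FORWARD_FILLED)
    valid = hr_ok and sbp_ok

    if "shock_index" in registry:
        if valid and values["systolic_bp"] > 0:
            values["shock_index"] = values["heart_rate"] / values["systolic_bp"]
            prov["shock_index"] = PROV_MEASURED
        else:
            si_spec = registry["shock_index"]
            values["shock_index"], prov["shock_index"] = impute(si_spec)
            if "shock_index" not in registry.mode_variables(mode) \
                    and prov["shock_index"] == PROV_IMPUTED:
                prov["shock_index"] = PROV_MASKED

    return FeatureVector(stay_id=stay_id, time=float(t), values=values,
                         provenance=prov, valid=valid)


def hr_sbp_available(stay_obs: StayObservations, t: float,
                     registry: Registry | None = None) -> bool:
    """Cheap validity probe used by the sampler before full featurization."""
    registry = registry or default_registry()
    for name in REQUIRED_VARIABLES:
        found = stay_obs.last_before(name, t)
        if found is None or t - found[0] > registry[name].fill_limit:
            return False
    return True


def build_feature_matrix(observations: pd.DataFrame,
                         stays: pd.DataFrame,
                         stats: PopulationStats,
                         queries: pd.DataFrame,
                         mode: str = "all",
                         registry: Registry | None = None) -> pd.DataFrame:
    """Snapshot every (stay_id, time) row of ``queries``.

    Returns a wide frame: stay_id, time, valid, one column per variable and
    a ``<variable>_prov`` provenance column, in registry order.
    """
    registry = registry or default_registry()
    ages = dict(zip(stays["stay_id"].astype(str), stays["age"].astype(float)))
    obs_by_stay = {str(k): g for k, g in observations.groupby("stay_id", sort=False)}
    empty = observations.iloc[0:0]

    index_cache: dict[str, StayObservations] = {}
    rows = []
    for q in queries.itertuples(index=False):
        sid = str(q.stay_id)
        if sid not in index_cache:
            index_cache[sid] = StayObservations(obs_by_stay.get(sid, empty), registry)
        fv = snapshot(index_cache[sid], stats, float(q.time), stay_id=sid,
                      age=ages.get(sid), mode=mode, registry=registry)
        row = {"stay_id": sid, "time": fv.time, "valid": fv.valid}
        for name in registry.names:
            row[name] = fv.values.get(name, math.nan)
            row[f"{name}_prov"] = fv.provenance.get(name, PROV_ABSENT)
        rows.append(row)
    cols = ["stay_id", "time", "valid"]
    for name in registry.names:
        cols += [name, f"{name}_prov"]
    return pd.DataFrame(rows, columns=cols)
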