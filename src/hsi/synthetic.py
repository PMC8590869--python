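"""Seeded synthetic ICU cohort with planted stable/unstable structure.

Each generated stay gets an archetype: ``stable`` (no triggering
treatments, at most a couple of sub-threshold fluid boluses) or one of
``pressor`` / ``fluid`` / ``prbc``. Unstable stays carry a deterioration
window — heart rate drifting up, blood pressures drifting down, plus
archetype-specific laboratory drift — that ends at the first treatment
record, whose dose is chosen to unambiguously satisfy a trigger
criterion. The archetype column is generator ground truth for evaluation
only and is never an input to the model.

Vitals are emitted on a regular sub-hour grid with per-record dropout and
occasional multi-hour blackout intervals (so forward-fill limits bind);
labs arrive every 8–16 h; ventilator settings only for ventilated stays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import Registry, default_registry

ARCHETYPES = ("stable", "pressor", "fluid", "prbc")
UNIT_TYPES = ("med-surg", "cardiac", "neuro", "stepdown", "other")
ADMISSION_SOURCES = ("floor", "ED", "OR", "other-ICU")

_PRESSOR_DRUGS = ("dobutamine", "dopamine", "epinephrine",
                  "norepinephrine", "phenylephrine", "vasopressin")

# per-variable (population mean, between-stay sd, within-stay sd)
_BASELINES = {
    "heart_rate": (82.0, 8.0, 5.0),
    "systolic_bp": (122.0, 10.0, 7.0),
    "diastolic_bp": (68.0, 7.0, 5.0),
    "mean_bp": (86.0, 8.0, 5.0),
    "respiratory_rate": (17.0, 2.5, 1.8),
    "spo2": (97.0, 1.2, 0.8),
    "temperature": (36.9, 0.35, 0.15),
    "hematocrit": (37.0, 3.5, 1.0),
    "hemoglobin": (12.3, 1.2, 0.35),
    "wbc": (9.0, 2.2, 0.7),
    "platelets": (230.0, 55.0, 12.0),
    "sodium": (139.0, 2.5, 1.2),
    "potassium": (4.1, 0.35, 0.15),
    "chloride": (103.0, 3.0, 1.5),
    "bicarbonate": (24.0, 2.5, 1.0),
    "bun": (18.0, 6.0, 1.5),
    "creatinine": (1.0, 0.25, 0.08),
    "glucose": (130.0, 25.0, 12.0),
    "lactate": (1.3, 0.35, 0.2),
    "albumin": (3.6, 0.4, 0.12),
    "total_bilirubin": (0.8, 0.3, 0.08),
    "calcium": (9.2, 0.45, 0.15),
    "magnesium": (2.0, 0.25, 0.08),
    "inr": (1.1, 0.15, 0.05),
    "ph": (7.40, 0.03, 0.015),
    "pao2": (95.0, 12.0, 7.0),
    "paco2": (40.0, 4.0, 2.0),
    "base_excess": (0.0, 1.8, 0.8),
    "fio2": (0.40, 0.06, 0.03),  # ventilated stays only
    "mawp": (10.0, 1.8, 0.8),
    "pip": (20.0, 3.5, 1.5),
}

# deterioration slopes per hour, applied from onset to first treatment
_COMMON_DRIFT = {
    "heart_rate": 3.0,
    "systolic_bp": -4.0,
    "diastolic_bp": -2.0,
    "mean_bp": -2.5,
    "respiratory_rate": 0.8,
    "spo2": -0.3,
    "lactate": 0.15,
    "wbc": 0.5,
    "bun": 0.8,
    "creatinine": 0.04,
    "bicarbonate": -0.35,
    "base_excess": -0.35,
    "mawp": 0.3,
    "pip": 0.6,
    "fio2": 0.015,
}
_ARCHETYPE_DRIFT = {
    "pressor": {"temperature": 0.10, "ph": -0.004},
    "fluid": {"glucose": 4.0, "sodium": -0.3},
    "prbc": {"hematocrit": -0.55, "hemoglobin": -0.18, "inr": 0.02},
}

# laboratory drift starts hours before the vital-sign ramp: slow markers
# move first, vitals decompensate just before the intervention
_EARLY_DRIFT_VARS = frozenset({
    "lactate", "wbc", "bun", "creatinine", "bicarbonate", "base_excess",
    "hematocrit", "hemoglobin", "inr", "glucose", "sodium", "ph",
})

_VITAL_VARS = ("heart_rate", "systolic_bp", "diastolic_bp", "mean_bp",
               "respiratory_rate", "spo2", "temperature")
_LAB_VARS = tuple(v for v in _BASELINES
                  if v not in _VITAL_VARS and v not in ("fio2", "mawp", "pip"))
_VENT_VARS = ("fio2", "mawp", "pip")


@dataclass
class GeneratorConfig:
    n_stays: int = 1000
    unstable_fraction: float = 0.18
    seed: int = 0
    vital_interval: float = 0.25  # hours between scheduled vital records
    lab_interval: tuple[float, float] = (6.0, 12.0)
    vent_interval: float = 4.0
    vital_dropout: float = 0.12
    lab_dropout: float = 0.15
    dnr_rate: float = 0.02
    ramp_hours: tuple[float, float] = (2.0, 6.0)
    drift_scale: float = 1.0
    attenuated_drift_scale: float = 0.35  # neuro / stepdown units
    unit_probs: dict = field(default_factory=lambda: {
        "med-surg": 0.45, "cardiac": 0.20, "neuro": 0.12,
        "stepdown": 0.13, "other": 0.10})
    source_probs: dict = field(default_factory=lambda: {
        "floor": 0.30, "ED": 0.40, "OR": 0.20, "other-ICU": 0.10})
    ventilated_rate: float = 0.30

    def validate(self) -> None:
        if self.n_stays < 0:
            raise ValueError("n_stays must be >= 0")
        if not 0.0 <= self.unstable_fraction <= 1.0:
            raise ValueError("unstable_fraction must be in [0, 1]")
        for name in ("vital_interval", "vent_interval", "vital_dropout",
                     "lab_dropout", "dnr_rate", "drift_scale",
                     "attenuated_drift_scale", "ventilated_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _categorical(rng, probs: dict):
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _drift_profile(times: np.ndarray, onset: float, t_treat: float,
                   slope: float) -> np.ndarray:
    """Linear drift from onset to treatment, then held (no recovery)."""
    ramp = np.clip(times - onset, 0.0, t_treat - onset)
    return slope * ramp


def generate_cohort(config: GeneratorConfig,
                    registry: Registry | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (stays, observations, treatments) tables.

    Identical configs produce identical tables. Roughly
    ``unstable_fraction`` of stays (binomial draw) receive treatment
    records that satisfy a trigger criterion; the rest receive none.
    """
    config.validate()
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)

    stay_rows = []
    obs_sid, obs_var, obs_time, obs_val = [], [], [], []
    trt_rows = []

    for i in range(config.n_stays):
        sid = f"s{i:05d}"
        unstable = rng.random() < config.unstable_fraction
        archetype = ("stable" if not unstable
                     else ("pressor", "fluid", "prbc")[rng.choice(3, p=[0.5, 0.3, 0.2])])
        age = int(rng.integers(18, 95))
        unit = _categorical(rng, config.unit_probs)
        source = _categorical(rng, config.source_probs)
        ventilated = bool(rng.random() < config.ventilated_rate)
        dnr = bool(rng.random() < config.dnr_rate)
        if unstable:
            los = float(24.0 + rng.gamma(2.0, 28.0))
        else:
            los = float(16.0 + rng.gamma(2.0, 16.0))

        # deterioration geometry
        if unstable:
            ramp = float(rng.uniform(*config.ramp_hours))
            t_treat = float(rng.uniform(6.0 + ramp + 1.5, los - 2.0))
            onset = t_treat - ramp
            lab_lead = float(rng.uniform(4.0, 10.0))
            scale = (config.attenuated_drift_scale
                     if unit in ("neuro", "stepdown") else config.drift_scale)
            scale *= float(rng.uniform(0.75, 1.25))
        else:
            t_treat = onset = np.inf
            lab_lead = 0.0
            scale = 0.0

        drift = dict(_COMMON_DRIFT)
        if archetype in _ARCHETYPE_DRIFT:
            drift.update(_ARCHETYPE_DRIFT[archetype])

        # vital blackout intervals so forward-fill limits actually bind
        n_black = rng.poisson(los / 48.0)
        blackouts = []
        for _ in range(n_black):
            b0 = rng.uniform(0, los)
            blackouts.append((b0, b0 + rng.uniform(1.0, 4.0)))

        def emit(var: str, times: np.ndarray, dropout: float) -> None:
            if times.size == 0:
                return
            keep = rng.random(times.size) >= dropout
            mean, sd_between, sd_within = _BASELINES[var]
            base = mean + rng.normal(0.0, sd_between)
            noise = rng.normal(0.0, sd_within, times.size)
            vals = base + noise
            if var in drift and np.isfinite(onset):
                start = onset - lab_lead if var in _EARLY_DRIFT_VARS else onset
                vals = vals + scale * _drift_profile(times, start, t_treat, drift[var])
            if var in _VITAL_VARS:
                for b0, b1 in blackouts:
                    keep &= ~((times >= b0) & (times <= b1))
            if not keep.any():
                return
            spec = registry[var] if var in registry else None
            out = vals[keep]
            if spec is not None:
                out = np.clip(out, spec.low, spec.high)
            n = int(keep.sum())
            obs_sid.extend([sid] * n)
            obs_var.extend([var] * n)
            obs_time.extend(np.round(times[keep], 6).tolist())
            obs_val.extend(np.round(out, 4).tolist())

        vital_grid = np.arange(0.0, los, config.vital_interval)
        for var in _VITAL_VARS:
            emit(var, vital_grid, config.vital_dropout)

        lo, hi = config.lab_interval
        lab_times = []
        t = float(rng.uniform(0.5, 6.0))
        while t < los:
            lab_times.append(t)
            t += float(rng.uniform(lo, hi))
        lab_grid = np.array(lab_times)
        for var in _LAB_VARS:
            emit(var, lab_grid, config.lab_dropout)

        if ventilated:
            vent_grid = np.arange(rng.uniform(0.0, 2.0), los, config.vent_interval)
            for var in _VENT_VARS:
                emit(var, vent_grid, config.lab_dropout)

        # treatments
        if archetype == "stable":
            if rng.random() < 0.25:
                n_bolus = int(rng.integers(1, 3))
                t = float(rng.uniform(2.0, max(3.0, los - 12.0)))
                for _ in range(n_bolus):
                    if t >= los:
                        break
                    trt_rows.append({"stay_id": sid, "category": "fluid",
                                     "drug": "", "time": round(t, 6),
                                     "volume": float(rng.integers(250, 450))})
                    t += float(rng.uniform(5.0, 9.0))
        elif archetype == "pressor":
            drug = _PRESSOR_DRUGS[rng.choice(len(_PRESSOR_DRUGS))]
            t = t_treat
            for _ in range(int(1 + rng.poisson(2.0))):
                if t > los:
                    break
                trt_rows.append({"stay_id": sid, "category": "pressor",
                                 "drug": drug, "time": round(t, 6), "volume": 0.0})
                t += float(rng.uniform(2.0, 8.0))
        elif archetype == "fluid":
            trt_rows.append({"stay_id": sid, "category": "fluid", "drug": "",
                             "time": round(t_treat, 6),
                             "volume": float(rng.integers(750, 1100))})
            t = t_treat + float(rng.uniform(2.0, 6.0))
            for _ in range(int(rng.integers(1, 3))):
                if t > los:
                    break
                trt_rows.append({"stay_id": sid, "category": "fluid", "drug": "",
                                 "time": round(t, 6),
                                 "volume": float(rng.integers(400, 650))})
                t += float(rng.uniform(2.0, 6.0))
        else:  # prbc
            trt_rows.append({"stay_id": sid, "category": "prbc", "drug": "",
                             "time": round(t_treat, 6),
                             "volume": float(rng.integers(500, 650))})
            t2 = t_treat + float(rng.uniform(2.5, 4.0))
            if t2 < los:
                trt_rows.append({"stay_id": sid, "category": "prbc", "drug": "",
                                 "time": round(t2, 6),
                                 "volume": float(rng.integers(300, 450))})

        stay_rows.append({
            "stay_id": sid, "age": age, "unit_type": unit,
            "admission_source": source, "ventilated": ventilated,
            "dnr": dnr, "los": round(los, 6), "archetype": archetype,
        })

    stays = pd.DataFrame(stay_rows, columns=[
        "stay_id", "age", "unit_type", "admission_source", "ventilated",
        "dnr", "los", "archetype"])
    observations = pd.DataFrame({
        "stay_id": obs_sid, "variable": obs_var,
        "time": obs_time, "value": obs_val,
    })
    treatments = pd.DataFrame(trt_rows, columns=[
        "stay_id", "category", "drug", "time", "volume"])
    return stays, observations, treatments


# ---------------------------------------------------------------------------
# CSV round trip

_SCHEMAS = {
    "stays.csv": ["stay_id", "age", "unit_type", "admission_source",
                  "ventilated", "dnr", "los", "archetype"],
    "observations.csv": ["stay_id", "variable", "time", "value"],
    "treatments.csv": ["stay_id", "category", "drug", "time", "volume"],
}


def write_cohort(tables, directory) -> dict[str, Path]:
    """Write (stays, observations, treatments) as CSV; returns file paths."""
    stays, observations, treatments = tables
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("stays.csv", stays), ("observations.csv", observations),
                        ("treatments.csv", treatments)):
        path = directory / name
        frame.to_csv(path, index=False, columns=_SCHEMAS[name])
        paths[name] = path
    return paths


def read_cohort(directory) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read a cohort directory back; header-driven, order-insensitive."""
    directory = Path(directory)
    out = []
    for name in ("stays.csv", "observations.csv", "treatments.csv"):
        frame = pd.read_csv(directory / name,
                            dtype={"stay_id": str, "drug": str,
                                   "variable": str} if name != "stays.csv"
                            else {"stay_id": str})
        missing = set(_SCHEMAS[name]) - set(frame.columns)
        if missing:
            raise ValueError(f"{name} missing required columns: {sorted(missing)}")
        frame = frame[_SCHEMAS[name]]
        if name == "treatments.csv":
            frame["drug"] = frame["drug"].fillna("")
        out.append(frame)
    registry = default_registry()
    obs_vars = set(out[1]["variable"].unique())
    allowed = set(registry.names) | {
        f"{v}_{suffix}" for v in ("systolic_bp", "diastolic_bp", "mean_bp")
        for suffix in ("invasive", "noninvasive")}
    unknown = obs_vars - allowed
    if unknown:
        raise ValueError(f"unknown observation variables: {sorted(unknown)}")
    return tuple(out)
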