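"""Behavioral recovery of the pipeline's labeling/preprocessing constants.

Each probe constructs synthetic inputs and searches for the boundary at
which the system changes behavior — e.g. the smallest fluid bolus that
opens an intervention segment, or the largest staleness at which a vital
is still forward-filled. Useful as an end-to-end self-check that the
implemented rules match their documented constants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import PopulationStats, StayObservations, snapshot
from .labeler import TreatmentRecord, evaluate_criteria, label_stay
from .registry import default_registry
from .sampler import draw_samples


def _fluid(t: float, vol: float) -> TreatmentRecord:
    return TreatmentRecord("probe", "fluid", t, vol)


def _prbc(t: float, vol: float) -> TreatmentRecord:
    return TreatmentRecord("probe", "prbc", t, vol)


def _bisect_min_true(predicate, lo: int, hi: int, step: int = 1) -> int:
    """Smallest v in {lo, lo+step, ...} <= hi with predicate(v) true.

    Assumes monotonicity (false below the boundary, true above).
    """
    lo_k, hi_k = 0, (hi - lo) // step
    if not predicate(lo + hi_k * step):
        raise ValueError("predicate never true in search range")
    while lo_k < hi_k:
        mid = (lo_k + hi_k) // 2
        if predicate(lo + mid * step):
            hi_k = mid
        else:
            lo_k = mid + 1
    return lo + hi_k * step


def min_single_bolus_trigger(max_volume: int = 2000) -> int:
    """Smallest single fluid bolus (cc) that opens a segment."""
    def triggers(v):
        return label_stay([_fluid(10.0, float(v))])[0] == "unstable"
    return _bisect_min_true(triggers, 1, max_volume)


def min_hourly_fluid_total(n_boluses: int, grid_cc: int,
                           max_total: int = 6000) -> int:
    """Smallest total volume over ``n_boluses`` hourly boluses that opens a
    segment, searched on a ``grid_cc`` grid of the total."""
    def triggers(total):
        per = total / n_boluses
        records = [_fluid(10.0 + k, per) for k in range(n_boluses)]
        return label_stay(records)[0] == "unstable"
    return _bisect_min_true(triggers, grid_cc, max_total, grid_cc)


def min_twice_bolus_trigger(gap_hours: float = 3.0, max_volume: int = 700) -> int:
    """Smallest per-bolus volume for two boluses ``gap_hours`` apart."""
    def triggers(v):
        records = [_fluid(10.0, float(v)), _fluid(10.0 + gap_hours, float(v))]
        return label_stay(records)[0] == "unstable"
    return _bisect_min_true(triggers, 1, max_volume)


def max_pressor_gap_one_segment(max_gap: int = 48) -> int:
    """Largest whole-hour gap between two pressors kept in one segment."""
    best = 0
    for g in range(1, max_gap + 1):
        records = [TreatmentRecord("probe", "pressor", 10.0, 0.0, "norepinephrine"),
                   TreatmentRecord("probe", "pressor", 10.0 + g, 0.0,
                                   "norepinephrine")]
        _, segments = label_stay(records)
        if len(segments) == 1:
            best = g
    return best


def min_prbc_24h_total(max_total: int = 2000) -> int:
    """Smallest 24-h cumulative PRBC total (24 hourly aliquots, 1-cc grid)
    at which the 24-h PRBC criterion itself reports satisfied."""
    def triggers(total):
        per = total / 24.0
        records = [_prbc(10.0 + k, per) for k in range(24)]
        hits = evaluate_criteria(records)
        return any(h.criterion_id == "PRBC_24H_800" for h in hits)
    return _bisect_min_true(triggers, 1, max_total)


# ---------------------------------------------------------------------------
# preprocessing probes

def _probe_stats() -> PopulationStats:
    registry = default_registry()
    return PopulationStats(means={name: 1.0 for name in registry.names},
                           samples={name: [1.0] for name in registry.names})


def _snapshot_for(rows, t):
    registry = default_registry()
    obs = pd.DataFrame(rows, columns=["stay_id", "variable", "time", "value"])
    so = StayObservations(obs, registry)
    return snapshot(so, _probe_stats(), t, stay_id="probe", age=50.0,
                    registry=registry)


def max_forward_fill_staleness(variable: str, grid: np.ndarray) -> float:
    """Largest staleness on ``grid`` at which ``variable`` is still carried
    forward rather than imputed/absent."""
    best = float("nan")
    for s in grid:
        t = 1.0 + float(s)
        rows = [("probe", variable, 1.0, 5.0),
                ("probe", "heart_rate", t, 80.0),
                ("probe", "systolic_bp", t, 120.0)]
        if variable in ("heart_rate", "systolic_bp"):
            rows = [("probe", "heart_rate", 1.0, 80.0),
                    ("probe", "systolic_bp", 1.0, 120.0)]
        fv = _snapshot_for(rows, t)
        if fv.provenance[variable] in ("measured", "forward_filled"):
            best = float(s)
    return best


def fio2_imputation_value() -> float:
    """FiO2 value substituted when never measured for the stay."""
    fv = _snapshot_for([("probe", "heart_rate", 1.0, 80.0),
                        ("probe", "systolic_bp", 1.0, 120.0)], 1.0)
    return fv.values["fio2"]


def sampler_min_emitted_time(seed: int = 0) -> float:
    """Infimum of sample times over segment-start sweeps and negative draws."""
    registry = default_registry()
    times = []

    obs_rows = []
    stay_rows = []
    seg_rows = []
    starts = np.arange(5.0, 10.01, 0.25)
    for i, start in enumerate(starts):
        sid = f"pos{i}"
        for t in np.arange(0.0, 40.0, 0.5):
            obs_rows.append((sid, "heart_rate", float(t), 80.0))
            obs_rows.append((sid, "systolic_bp", float(t), 120.0))
        stay_rows.append({"stay_id": sid, "age": 50, "unit_type": "med-surg",
                          "admission_source": "ED", "ventilated": False,
                          "dnr": False, "los": 40.0, "archetype": "pressor"})
        seg_rows.append({"stay_id": sid, "start": float(start),
                         "end": float(start) + 1.0, "criteria": "PRESSOR_ANY"})
    for i in range(50):
        sid = f"neg{i}"
        for t in np.arange(0.0, 7.0, 0.25):
            obs_rows.append((sid, "heart_rate", float(t), 80.0))
            obs_rows.append((sid, "systolic_bp", float(t), 120.0))
        stay_rows.append({"stay_id": sid, "age": 50, "unit_type": "med-surg",
                          "admission_source": "ED", "ventilated": False,
                          "dnr": False, "los": 7.0, "archetype": "stable"})

    stays = pd.DataFrame(stay_rows)
    observations = pd.DataFrame(obs_rows,
                                columns=["stay_id", "variable", "time", "value"])
    segments = pd.DataFrame(seg_rows)
    for s in range(seed, seed + 20):
        samples = draw_samples(stays, segments, observations, lead=1.0,
                               seed=s, registry=registry)
        times.extend(samples["time"].tolist())
    return float(min(times))


def all_targets(seed: int = 0) -> dict[str, dict[str, float]]:
    """Recompute every recoverable constant; values in printed units."""
    fine = np.arange(0.0, 6.001, 0.05)
    coarse = np.arange(0.0, 30.001, 0.25)
    return {
        "t1": {"value": float(min_single_bolus_trigger()), "n": 2000},
        "t2": {"value": float(min_hourly_fluid_total(8, 8)), "n": 6000 // 8},
        "t3": {"value": float(min_hourly_fluid_total(12, 12)), "n": 6000 // 12},
        "t4": {"value": float(min_hourly_fluid_total(4, 4)), "n": 6000 // 4},
        "t5": {"value": float(min_twice_bolus_trigger()), "n": 700},
        "t6": {"value": float(max_pressor_gap_one_segment()), "n": 48},
        "t7": {"value": max_forward_fill_staleness("heart_rate", fine),
               "n": fine.size},
        "t8": {"value": max_forward_fill_staleness("lactate", coarse),
               "n": coarse.size},
        "t9": {"value": fio2_imputation_value(), "n": 1},
        "t10": {"value": sampler_min_emitted_time(seed), "n": 20 * 71},
        "t11": {"value": float(min_prbc_24h_total()), "n": 2000},
    }
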