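"""Supervised sample construction and the patient-level stratified split.

One positive per unstable stay, taken ``lead`` hours before its first
intervention segment; one random negative per stable stay. No sample is
drawn from the first 6 h of any stay, DNR stays and minors are excluded,
and every emitted sample time has heart rate and systolic blood pressure
available under the forward-fill limits.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .features import StayObservations, hr_sbp_available
from .registry import Registry, default_registry

log = logging.getLogger(__name__)

#: no samples from the first hours of the ICU stay
EXCLUSION_HOURS = 6.0
MIN_AGE = 18
_NEGATIVE_ATTEMPTS = 10

SUBGROUP_KEYS = ("unit_type", "admission_source", "ventilated")


def draw_samples(stays: pd.DataFrame,
                 segments: pd.DataFrame,
                 observations: pd.DataFrame,
                 lead: float = 1.0,
                 seed: int = 0,
                 label_filter: str | None = None,
                 registry: Registry | None = None) -> pd.DataFrame:
    """Build the sample table (stay_id, time, label, lead, subgroup columns).

    ``label_filter`` restricts positives to segments whose criteria include
    the given id (e.g. ``PRESSOR_ANY`` for a pressor-only outcome); stays
    whose segments all fail the filter contribute nothing.
    """
    if lead <= 0:
        raise ValueError("lead must be > 0")
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)

    seg_by_stay: dict[str, list] = {}
    if not segments.empty:
        subset = segments
        if label_filter is not None:
            subset = segments[segments["criteria"].str.split(";")
                              .map(lambda ids: label_filter in ids)]
        for row in subset.sort_values(["stay_id", "start"]).itertuples(index=False):
            seg_by_stay.setdefault(str(row.stay_id), []).append(float(row.start))

    obs_by_stay = {str(k): g for k, g in observations.groupby("stay_id", sort=False)}
    empty_obs = observations.iloc[0:0]
    segmented_stays = (set(segments["stay_id"].astype(str))
                       if not segments.empty else set())

    rows = []
    for stay in stays.itertuples(index=False):
        sid = str(stay.stay_id)
        if bool(stay.dnr) or int(stay.age) < MIN_AGE:
            continue
        stay_obs = StayObservations(obs_by_stay.get(sid, empty_obs), registry)
        sub = {k: getattr(stay, k) for k in SUBGROUP_KEYS}
        starts = seg_by_stay.get(sid)
        if starts:
            t = starts[0] - lead
            if t < EXCLUSION_HOURS:
                log.warning("dropped positive %s: time %.2f inside first-%g-h "
                            "exclusion", sid, t, EXCLUSION_HOURS)
                continue
            if not hr_sbp_available(stay_obs, t, registry):
                log.warning("dropped positive %s: HR/SBP unavailable at %.2f",
                            sid, t)
                continue
            rows.append({"stay_id": sid, "time": float(t), "label": 1,
                         "lead": float(lead), **sub})
        else:
            # negatives come only from stays with no segments at all
            if sid in segmented_stays:
                continue  # unstable stay whose segments failed label_filter
            los = float(stay.los)
            if los <= EXCLUSION_HOURS:
                continue
            for _ in range(_NEGATIVE_ATTEMPTS):
                t = float(rng.uniform(EXCLUSION_HOURS, los))
                if hr_sbp_available(stay_obs, t, registry):
                    rows.append({"stay_id": sid, "time": t, "label": 0,
                                 "lead": float("nan"), **sub})
                    break
            else:
                log.warning("dropped stable stay %s: no valid negative draw "
                            "in %d attempts", sid, _NEGATIVE_ATTEMPTS)

    out = pd.DataFrame(rows, columns=["stay_id", "time", "label", "lead",
                                      *SUBGROUP_KEYS])
    if out.empty and len(stays) > 0:
        raise ValueError("no eligible samples could be drawn")
    return out


def split_patients(samples: pd.DataFrame,
                   test_fraction: float = 0.2,
                   seed: int = 0) -> dict[str, str]:
    """Label-stratified, patient-disjoint train/test assignment.

    Returns a mapping stay_id -> 'train' | 'test'. Each stay appears in
    exactly one split; stratification is by the stay's label.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    per_stay = samples.groupby("stay_id")["label"].max()
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in sorted(per_stay.unique()):
        ids = sorted(per_stay.index[per_stay == label].astype(str))
        if len(ids) < 2:
            raise ValueError(f"need at least 2 stays with label {label} to split")
        n_test = int(round(test_fraction * len(ids)))
        if n_test < 1 or n_test >= len(ids):
            raise ValueError(
                f"test_fraction={test_fraction} starves a split for label {label}")
        order = rng.permutation(len(ids))
        for rank, idx in enumerate(order):
            assignment[ids[idx]] = "test" if rank < n_test else "train"
    return assignment


def save_split(assignment: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        json.dump(assignment, fh, indent=0, sort_keys=True)


def load_split(path) -> dict[str, str]:
    with open(path) as fh:
        return json.load(fh)
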