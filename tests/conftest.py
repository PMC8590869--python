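from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hsi import labeler, model, sampler, synthetic
from hsi.features import (build_feature_matrix, compute_population_stats,
                          merge_blood_pressure)
from hsi.registry import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """250-stay cohort used by unit tests that need realistic tables."""
    cfg = synthetic.GeneratorConfig(n_stays=250, unstable_fraction=0.18, seed=5)
    stays, observations, treatments = synthetic.generate_cohort(cfg)
    observations = merge_blood_pressure(observations)
    segments = labeler.label_cohort(treatments)
    return {"stays": stays, "observations": observations,
            "treatments": treatments, "segments": segments, "config": cfg}


def build_training_setup(n_stays=2000, seed=11, n_rounds=200,
                         calibration_fraction=0.2):
    """Cohort -> samples -> split -> stats -> features -> fitted model.

    In-memory mirror of the pipeline stages, shared by acceptance tests.
    """
    registry = default_registry()
    cfg = synthetic.GeneratorConfig(n_stays=n_stays, unstable_fraction=0.18,
                                    seed=seed)
    stays, observations, treatments = synthetic.generate_cohort(cfg)
    observations = merge_blood_pressure(observations)
    segments = labeler.label_cohort(treatments)
    samples = sampler.draw_samples(stays, segments, observations, lead=1.0,
                                   seed=seed)
    split = sampler.split_patients(samples, 0.2, seed=seed)

    train_ids = {sid for sid, part in split.items() if part == "train"}
    stats = compute_population_stats(
        observations[observations["stay_id"].isin(train_ids)],
        stays[stays["stay_id"].isin(train_ids)], registry, seed=seed)
    features = build_feature_matrix(observations, stays, stats,
                                    samples[["stay_id", "time"]],
                                    mode="all", registry=registry)
    merged = features.merge(samples[["stay_id", "time", "label"]],
                            on=["stay_id", "time"])

    rng = np.random.default_rng(seed + 17)
    ordered = sorted(train_ids)
    order = rng.permutation(len(ordered))
    n_cal = max(1, int(round(calibration_fraction * len(ordered))))
    cal_ids = {ordered[i] for i in order[:n_cal]}
    boost_ids = {ordered[i] for i in order[n_cal:]}

    X = merged[registry.names].to_numpy(dtype=float)
    y = merged["label"].to_numpy(dtype=int)
    in_boost = merged["stay_id"].isin(boost_ids).to_numpy()
    in_cal = merged["stay_id"].isin(cal_ids).to_numpy()
    in_test = merged["stay_id"].map(split).eq("test").to_numpy()

    ens = model.fit(X[in_boost], y[in_boost], registry.names,
                    model.BoostConfig(n_rounds=n_rounds),
                    registry_hash=registry.content_hash())
    model.calibrate(ens, X[in_cal], y[in_cal])

    return {
        "registry": registry, "stays": stays, "observations": observations,
        "treatments": treatments, "segments": segments, "samples": samples,
        "split": split, "stats": stats, "features": features,
        "merged": merged, "X": X, "y": y, "in_boost": in_boost,
        "in_cal": in_cal, "in_test": in_test, "model": ens, "seed": seed,
    }


@pytest.fixture(scope="session")
def acceptance_setup():
    """The fixed-seed n=2000 cohort + trained model behind criteria 4-6."""
    return build_training_setup(n_stays=2000, seed=11, n_rounds=200)
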