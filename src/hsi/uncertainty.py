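"""Confidence intervals and abstention for stump-ensemble predictions.

Uncertainty decomposes into a model term — the spread of raw scores
across patient-level bootstrap refits — and a feature term — the spread
of the primary ensemble's score when every imputed/absent/masked
variable is jointly redrawn from its training empirical marginal.
The confidence interval is ``raw_score +/- z * sqrt(sigma_model^2 +
sigma_feature^2)``; the default abstention rule abstains whenever the
decision threshold falls inside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .features import PROV_ABSENT, PROV_IMPUTED, PROV_MASKED, PopulationStats
from .model import BoostConfig, StumpEnsemble, fit

REDRAWABLE_PROVENANCE = (PROV_IMPUTED, PROV_ABSENT, PROV_MASKED)


@dataclass
class UncertaintyConfig:
    n_bootstrap: int = 50
    n_feature_draws: int = 20
    z: float = 1.96
    seed: int = 0
    # extended overlap rule: abstain when the normal mass within +/- delta
    # of the threshold exceeds alpha; None selects the plain CI rule
    overlap_alpha: float | None = None
    overlap_delta: float = 0.25

    def validate(self) -> None:
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")
        if self.n_feature_draws < 2:
            raise ValueError("n_feature_draws must be >= 2")
        if self.z < 0:
            raise ValueError("z must be >= 0")


@dataclass
class IntervalPrediction:
    raw_score: float
    sigma_model: float
    sigma_feature: float
    ci_low: float
    ci_high: float
    abstain: bool


def fit_bootstrap_ensembles(X: np.ndarray, y: np.ndarray,
                            stay_ids: np.ndarray,
                            feature_names: list[str],
                            config: UncertaintyConfig,
                            boost_config: BoostConfig | None = None
                            ) -> list[StumpEnsemble]:
    """Fit B ensembles on patient-level bootstrap resamples of the data."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    stay_ids = np.asarray(stay_ids)
    y = np.asarray(y, dtype=float)
    unique_ids = np.unique(stay_ids)
    by_stay = {sid: np.flatnonzero(stay_ids == sid) for sid in unique_ids}

    ensembles = []
    for _ in range(config.n_bootstrap):
        for _attempt in range(20):
            picked = rng.choice(unique_ids, size=unique_ids.size, replace=True)
            idx = np.concatenate([by_stay[sid] for sid in picked])
            if 0 < y[idx].sum() < idx.size:
                break
        else:
            raise ValueError("could not draw a two-class bootstrap resample")
        ensembles.append(fit(X[idx], y[idx], feature_names, boost_config))
    return ensembles


def predict_with_ci_batch(primary: StumpEnsemble,
                          ensembles: list[StumpEnsemble],
                          X: np.ndarray,
                          redrawable: np.ndarray,
                          stats: PopulationStats,
                          config: UncertaintyConfig) -> dict[str, np.ndarray]:
    """Raw scores with model/feature sigmas and CI bounds for a matrix.

    ``redrawable`` is a boolean (n, d) mask marking entries whose
    provenance is imputed/absent/masked; those entries are jointly
    resampled from the training marginals in each feature draw.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    redrawable = np.asarray(redrawable, dtype=bool)
    rng = np.random.default_rng(config.seed + 1)

    raw = primary.raw_scores(X)

    boot = np.stack([e.raw_scores(X) for e in ensembles])
    sigma_model = boot.std(axis=0, ddof=0)

    draws = np.empty((config.n_feature_draws, X.shape[0]))
    pools = {}
    for j, name in enumerate(primary.feature_names):
        if redrawable[:, j].any():
            pool = stats.samples.get(name)
            if not pool:
                raise ValueError(f"no training marginal available for {name!r}")
            pools[j] = np.asarray(pool, dtype=float)
    for k in range(config.n_feature_draws):
        Xk = X.copy()
        for j, pool in pools.items():
            rows = np.flatnonzero(redrawable[:, j])
            Xk[rows, j] = pool[rng.integers(0, pool.size, rows.size)]
        draws[k] = primary.raw_scores(Xk)
    sigma_feature = draws.std(axis=0, ddof=0)
    # entries with nothing to redraw have exactly zero feature uncertainty
    sigma_feature[~redrawable.any(axis=1)] = 0.0

    half = config.z * np.sqrt(sigma_model ** 2 + sigma_feature ** 2)
    return {
        "raw_score": raw,
        "sigma_model": sigma_model,
        "sigma_feature": sigma_feature,
        "ci_low": raw - half,
        "ci_high": raw + half,
    }


def predict_with_ci(primary: StumpEnsemble,
                    ensembles: list[StumpEnsemble],
                    x: np.ndarray,
                    redrawable: np.ndarray,
                    stats: PopulationStats,
                    config: UncertaintyConfig,
                    threshold: float | None = None) -> IntervalPrediction:
    """Single-sample convenience wrapper around the batch routine."""
    out = predict_with_ci_batch(primary, ensembles,
                                np.asarray(x, dtype=float)[None, :],
                                np.asarray(redrawable, dtype=bool)[None, :],
                                stats, config)
    abstain = False
    if threshold is not None:
        abstain = bool(decide_abstain(out["raw_score"], out["ci_low"],
                                      out["ci_high"], out["sigma_model"],
                                      out["sigma_feature"], threshold,
                                      config)[0])
    return IntervalPrediction(
        raw_score=float(out["raw_score"][0]),
        sigma_model=float(out["sigma_model"][0]),
        sigma_feature=float(out["sigma_feature"][0]),
        ci_low=float(out["ci_low"][0]),
        ci_high=float(out["ci_high"][0]),
        abstain=abstain)


def decide_abstain(raw_score, ci_low, ci_high, sigma_model, sigma_feature,
                   threshold: float,
                   config: UncertaintyConfig | None = None) -> np.ndarray:
    """Vectorized abstention decision against a raw-score threshold.

    Default rule: abstain iff the threshold lies inside the confidence
    interval. Extended rule (``overlap_alpha`` set): abstain iff the
    normal mass of N(raw, sigma_total^2) within ``overlap_delta`` of the
    threshold exceeds ``overlap_alpha``.
    """
    config = config or UncertaintyConfig()
    raw_score = np.asarray(raw_score, dtype=float)
    if config.overlap_alpha is None:
        return (np.asarray(ci_low) <= threshold) & (threshold <= np.asarray(ci_high))
    sigma = np.sqrt(np.asarray(sigma_model) ** 2 + np.asarray(sigma_feature) ** 2)
    sigma = np.maximum(sigma, 1e-12)
    mass = (norm.cdf((threshold + config.overlap_delta - raw_score) / sigma)
            - norm.cdf((threshold - config.overlap_delta - raw_score) / sigma))
    return mass > config.overlap_alpha
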