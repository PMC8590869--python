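"""Gradient-boosted decision stumps with additive per-variable risks.

The model is an ordered list of depth-1 rules fitted by logistic-loss
gradient boosting. Grouping stumps by variable yields one univariate risk
function per input; the raw score is the training-prevalence baseline
plus the sum of these risks, so every prediction decomposes exactly into
per-variable contributions. Samples missing a stump's variable receive a
zero contribution from it and are excluded from that split's search.
Scores are mapped to probabilities with Platt scaling, and the
hemodynamic stability index is ``100 * (1 - p_unstable)`` — higher means
more stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

_SCHEMA_VERSION = 1
_LEAF_CLIP = 4.0


@dataclass(frozen=True)
class Stump:
    feature: str
    feature_index: int
    threshold: float
    left_value: float  # applied when x < threshold
    right_value: float  # applied when x >= threshold
    round: int


@dataclass
class BoostConfig:
    n_rounds: int = 200
    learning_rate: float = 0.1
    max_bins: int = 256
    leaf_clip: float = _LEAF_CLIP

    def validate(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_bins < 2:
            raise ValueError("max_bins must be >= 2")


@dataclass
class Prediction:
    raw_score: float
    p_unstable: float
    hsi: float
    per_feature_risk: dict[str, float]
    top_features: list[str]


@dataclass
class StumpEnsemble:
    feature_names: list[str]
    baseline: float
    stumps: list[Stump] = field(default_factory=list)
    learning_rate: float = 0.1
    platt_a: float = -1.0
    platt_b: float = 0.0
    registry_hash: str = ""
    train_log_loss: list[float] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.stumps)

    # -- scoring ------------------------------------------------------------

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        """Vectorized raw scores for a (n, d) matrix; NaN means absent."""
        X = np.asarray(X, dtype=float)
        scores = np.full(X.shape[0], self.baseline, dtype=float)
        for st in self.stumps:
            x = X[:, st.feature_index]
            present = ~np.isnan(x)
            contrib = np.where(x >= st.threshold, st.right_value, st.left_value)
            scores[present] += contrib[present]
        return scores

    def per_feature_risks(self, x: np.ndarray) -> dict[str, float]:
        """Summed stump contributions per variable for one sample row."""
        risks = {name: 0.0 for name in self.feature_names}
        for st in self.stumps:
            v = x[st.feature_index]
            if math.isnan(v):
                continue
            risks[st.feature] += st.right_value if v >= st.threshold else st.left_value
        return risks

    def calibrated_probability(self, raw: np.ndarray) -> np.ndarray:
        return expit(-(self.platt_a * np.asarray(raw, dtype=float) + self.platt_b))

    def predict(self, x: np.ndarray, top_k: int = 5) -> Prediction:
        x = np.asarray(x, dtype=float)
        risks = self.per_feature_risks(x)
        raw = self.baseline + sum(risks.values())
        p = float(self.calibrated_probability(np.array([raw]))[0])
        top = sorted(risks, key=lambda n: abs(risks[n]), reverse=True)[:top_k]
        return Prediction(raw_score=float(raw), p_unstable=p,
                          hsi=100.0 * (1.0 - p), per_feature_risk=risks,
                          top_features=top)

    def risk_curve(self, variable: str, grid: np.ndarray) -> np.ndarray:
        """Piecewise-constant univariate risk over ``grid`` (>= branch at
        threshold points)."""
        if variable not in self.feature_names:
            raise KeyError(f"unknown variable {variable!r}")
        grid = np.asarray(grid, dtype=float)
        curve = np.zeros_like(grid)
        for st in self.stumps:
            if st.feature != variable:
                continue
            curve += np.where(grid >= st.threshold, st.right_value, st.left_value)
        return curve


# ---------------------------------------------------------------------------
# fitting

def _candidate_thresholds(values: np.ndarray, max_bins: int) -> np.ndarray:
    """Midpoints between adjacent distinct (quantile-binned) values."""
    uniq = np.unique(values)
    if uniq.size > max_bins:
        qs = np.linspace(0.0, 1.0, max_bins + 1)[1:-1]
        uniq = np.unique(np.quantile(values, qs, method="nearest"))
    if uniq.size < 2:
        return np.empty(0)
    return (uniq[:-1] + uniq[1:]) / 2.0


def _log_loss(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit(X: np.ndarray, y: np.ndarray, feature_names: list[str],
        config: BoostConfig | None = None,
        registry_hash: str = "") -> StumpEnsemble:
    """Fit the stump ensemble by logistic-loss gradient boosting.

    Each round scans every feature; candidate splits are midpoints of up
    to ``max_bins`` quantile bins of the present values, gain is the
    squared-error reduction on the negative gradients, and leaf values
    are Newton steps scaled by the learning rate. Fully deterministic
    given the input order; ties prefer the lowest feature index, then the
    lowest threshold.
    """
    config = config or BoostConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) aligned with y")
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names must match X columns")
    if X.shape[1] == 0:
        raise ValueError("empty feature set")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("training labels must contain both classes")

    prevalence = n_pos / y.size
    baseline = math.log(prevalence / (1.0 - prevalence))
    ens = StumpEnsemble(feature_names=list(feature_names), baseline=baseline,
                        learning_rate=config.learning_rate,
                        registry_hash=registry_hash)

    # static per-feature structures: present mask, thresholds, bin position
    feats = []
    for j in range(X.shape[1]):
        present = ~np.isnan(X[:, j])
        cand = (_candidate_thresholds(X[present, j], config.max_bins)
                if present.any() else np.empty(0))
        pos = (np.searchsorted(cand, X[present, j], side="right")
               if cand.size else None)
        feats.append((present, cand, pos))

    F = np.full(y.size, baseline, dtype=float)
    for rnd in range(config.n_rounds):
        p = expit(F)
        g = y - p  # negative gradient of logistic loss
        h = p * (1.0 - p)

        best = None  # (gain, j, k)
        for j, (present, cand, pos) in enumerate(feats):
            if cand.size == 0:
                continue
            gp, hp = g[present], h[present]
            n_tot = gp.size
            cnt = np.bincount(pos, minlength=cand.size + 1)[:cand.size]
            gs = np.bincount(pos, weights=gp, minlength=cand.size + 1)[:cand.size]
            n_l = np.cumsum(cnt)
            g_l = np.cumsum(gs)
            valid = (n_l > 0) & (n_l < n_tot)
            if not valid.any():
                continue
            g_tot = gp.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                gain = np.where(
                    valid,
                    g_l ** 2 / np.maximum(n_l, 1)
                    + (g_tot - g_l) ** 2 / np.maximum(n_tot - n_l, 1),
                    -np.inf)
            # tolerance absorbs summation-order float noise so exact gain
            # ties resolve to the lowest feature index / lowest threshold
            gmax = float(gain.max())
            tol = 1e-9 * max(1.0, abs(gmax))
            k = int(np.argmax(gain >= gmax - tol))
            if best is None or gain[k] > best[0] + tol:
                best = (float(gain[k]), j, k)

        if best is None:
            raise ValueError("no valid split found (all features constant?)")
        _, j, k = best
        present, cand, pos = feats[j]
        thr = float(cand[k])
        left = pos <= k
        gp, hp = g[present], h[present]
        eps = 1e-12
        v_left = float(np.clip(gp[left].sum() / max(hp[left].sum(), eps),
                               -config.leaf_clip, config.leaf_clip))
        v_right = float(np.clip(gp[~left].sum() / max(hp[~left].sum(), eps),
                                -config.leaf_clip, config.leaf_clip))
        v_left *= config.learning_rate
        v_right *= config.learning_rate

        upd = np.zeros(y.size)
        idx = np.flatnonzero(present)
        upd[idx[left]] = v_left
        upd[idx[~left]] = v_right
        F += upd
        ens.stumps.append(Stump(feature=feature_names[j], feature_index=j,
                                threshold=thr, left_value=v_left,
                                right_value=v_right, round=rnd))
        ens.train_log_loss.append(_log_loss(y, expit(F)))
    return ens


# ---------------------------------------------------------------------------
# Platt calibration

def calibrate(ensemble: StumpEnsemble, X: np.ndarray,
              y: np.ndarray) -> StumpEnsemble:
    """Fit (platt_a, platt_b) on a held-out calibration set.

    Minimizes the log loss of ``sigmoid(-(a*s + b))`` against Platt's
    smoothed targets; in-place update, returns the ensemble.
    """
    y = np.asarray(y, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("calibration set must contain both classes")
    s = ensemble.raw_scores(np.asarray(X, dtype=float))
    t = np.where(y > 0.5, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(params):
        a, b = params
        z = a * s + b
        nll = np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z)
        p = expit(-z)
        resid = t - p
        return nll, np.array([np.sum(resid * s), np.sum(resid)])

    res = minimize(objective, x0=np.array([-1.0, 0.0]), jac=True,
                   method="L-BFGS-B")
    ensemble.platt_a, ensemble.platt_b = (float(res.x[0]), float(res.x[1]))
    return ensemble


# ---------------------------------------------------------------------------
# persistence

def save_model(ensemble: StumpEnsemble, path) -> None:
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "feature_names": ensemble.feature_names,
        "baseline": ensemble.baseline,
        "learning_rate": ensemble.learning_rate,
        "platt_a": ensemble.platt_a,
        "platt_b": ensemble.platt_b,
        "registry_hash": ensemble.registry_hash,
        "stumps": [
            {"feature": s.feature, "feature_index": s.feature_index,
             "threshold": s.threshold, "left_value": s.left_value,
             "right_value": s.right_value, "round": s.round}
            for s in ensemble.stumps
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path, expected_registry_hash: str | None = None) -> StumpEnsemble:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {doc.get('schema_version')!r} is not "
            f"supported (expected {_SCHEMA_VERSION})")
    if expected_registry_hash is not None and \
            doc.get("registry_hash") != expected_registry_hash:
        raise ValueError("model was trained against a different variable "
                         "registry (hash mismatch)")
    ens = StumpEnsemble(
        feature_names=list(doc["feature_names"]),
        baseline=float(doc["baseline"]),
        learning_rate=float(doc["learning_rate"]),
        platt_a=float(doc["platt_a"]),
        platt_b=float(doc["platt_b"]),
        registry_hash=doc.get("registry_hash", ""),
    )
    ens.stumps = [Stump(feature=s["feature"], feature_index=int(s["feature_index"]),
                        threshold=float(s["threshold"]),
                        left_value=float(s["left_value"]),
                        right_value=float(s["right_value"]), round=int(s["round"]))
                  for s in doc["stumps"]]
    return ens
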