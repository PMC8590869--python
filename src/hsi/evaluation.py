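"""Discrimination metrics, operating points, and protocol sweeps.

AUC is computed from the midrank statistic, AUPRC by step-wise
precision-recall integration over distinct thresholds. Operating points
are reported at the breakeven threshold (precision closest to recall)
and at the smallest thresholds reaching 90% and 95% specificity.
Protocol sweeps evaluate one trained model under restricted operating
modes, at earlier prediction lead times, and within patient subgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import PopulationStats, build_feature_matrix
from .model import StumpEnsemble
from .registry import OPERATING_MODES, Registry, default_registry
from .sampler import SUBGROUP_KEYS, draw_samples

log = logging.getLogger(__name__)


@dataclass
class OperatingPoint:
    name: str
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    degenerate: bool = False


@dataclass
class EvalReport:
    auc: float
    auprc: float
    operating_points: dict[str, OperatingPoint]
    prevalence: float
    n_pos: int
    n_neg: int
    group: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {**self.group, "auc": self.auc, "auprc": self.auprc,
               "prevalence": self.prevalence, "n_pos": self.n_pos,
               "n_neg": self.n_neg}
        for name, op in self.operating_points.items():
            row[f"se_{name}"] = op.sensitivity
            row[f"sp_{name}"] = op.specificity
            row[f"ppv_{name}"] = op.ppv
        return row


def _check_two_class(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    return n_pos, n_neg


def roc_pr(scores, labels):
    """(auc, auprc, roc_points, pr_points); ties handled by midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_two_class(labels)

    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
    tpr = tp[distinct] / n_pos
    fpr = fp[distinct] / n_neg
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tpr
    # step-wise PR integration (average precision)
    auprc = float(np.sum(np.diff(recall, prepend=0.0) * precision))

    roc_points = pd.DataFrame({"threshold": s_sorted[distinct],
                               "fpr": fpr, "tpr": tpr})
    pr_points = pd.DataFrame({"threshold": s_sorted[distinct],
                              "recall": recall, "precision": precision})
    return float(auc), auprc, roc_points, pr_points


def operating_points(scores, labels,
                     specificity_targets=(0.90, 0.95)) -> dict[str, OperatingPoint]:
    """Breakeven and fixed-specificity operating points.

    A sample is predicted positive when its score is >= the threshold;
    candidate thresholds are the distinct observed scores. Unreachable
    specificity targets yield degenerate points with NaN metrics.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_two_class(labels)

    thresholds = np.unique(scores)  # ascending
    pred_pos = scores[None, :] >= thresholds[:, None]
    tp = (pred_pos & (labels == 1)).sum(axis=1)
    fp = (pred_pos & (labels == 0)).sum(axis=1)
    se = tp / n_pos
    sp = 1.0 - fp / n_neg
    n_pred = tp + fp
    ppv = np.where(n_pred > 0, tp / np.maximum(n_pred, 1), np.nan)

    points = {}
    feasible = n_pred > 0
    gap = np.where(feasible, np.abs(ppv - se), np.inf)
    best_gap = gap.min()
    cand = np.flatnonzero(gap == best_gap)
    k = cand[np.argmax(sp[cand])]  # ties -> higher specificity
    points["breakeven"] = OperatingPoint("breakeven", float(thresholds[k]),
                                         float(se[k]), float(sp[k]),
                                         float(ppv[k]))
    for target in specificity_targets:
        name = f"sp{int(round(target * 100))}"
        ok = np.flatnonzero((sp >= target) & feasible)
        if ok.size == 0:
            log.warning("specificity target %.2f unreachable; degenerate "
                        "score distribution", target)
            points[name] = OperatingPoint(name, float("nan"), float("nan"),
                                          float("nan"), float("nan"),
                                          degenerate=True)
            continue
        k = ok[0]  # smallest qualifying threshold -> maximal sensitivity
        points[name] = OperatingPoint(name, float(thresholds[k]), float(se[k]),
                                      float(sp[k]), float(ppv[k]))
    return points


def make_report(scores, labels, group: dict | None = None) -> EvalReport:
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_two_class(labels)
    auc, auprc, _, _ = roc_pr(scores, labels)
    return EvalReport(auc=auc, auprc=auprc,
                      operating_points=operating_points(scores, labels),
                      prevalence=n_pos / (n_pos + n_neg),
                      n_pos=n_pos, n_neg=n_neg, group=group or {})


def baseline_scores(features: pd.DataFrame) -> dict[str, np.ndarray]:
    """Single-parameter baselines: shock index and (negated) systolic BP."""
    return {
        "shock_index": features["shock_index"].to_numpy(dtype=float),
        "systolic_bp": -features["systolic_bp"].to_numpy(dtype=float),
    }


# ---------------------------------------------------------------------------
# protocol sweeps (one trained model, test-split inputs only)

def _score_samples(ensemble: StumpEnsemble, observations, stays,
                   stats: PopulationStats, samples: pd.DataFrame,
                   mode: str, registry: Registry) -> tuple[np.ndarray, pd.DataFrame]:
    feats = build_feature_matrix(observations, stays, stats,
                                 samples[["stay_id", "time"]], mode=mode,
                                 registry=registry)
    X = feats[ensemble.feature_names].to_numpy(dtype=float)
    return ensemble.raw_scores(X), feats


def evaluate_modes(ensemble: StumpEnsemble, observations, stays,
                   stats: PopulationStats, samples: pd.DataFrame,
                   modes=OPERATING_MODES,
                   registry: Registry | None = None) -> dict[str, EvalReport]:
    """Re-snapshot the test samples under each operating mode and score."""
    registry = registry or default_registry()
    labels = samples["label"].to_numpy(dtype=int)
    reports = {}
    for mode in modes:
        scores, _ = _score_samples(ensemble, observations, stays, stats,
                                   samples, mode, registry)
        reports[mode] = make_report(scores, labels, {"mode": mode})
    return reports


def evaluate_leads(ensemble: StumpEnsemble, stays, segments, observations,
                   stats: PopulationStats, leads=tuple(range(1, 13)),
                   seed: int = 0, mode: str = "all",
                   registry: Registry | None = None) -> dict[float, EvalReport]:
    """Score one model at snapshots taken ``lead`` hours before segments.

    Negatives are redrawn with the same seed each time: the stable-stay
    random draws consume the identical generator stream, so every lead is
    evaluated against the same negative samples.
    """
    registry = registry or default_registry()
    reports = {}
    for lead in leads:
        samples = draw_samples(stays, segments, observations, lead=float(lead),
                               seed=seed, registry=registry)
        scores, _ = _score_samples(ensemble, observations, stays, stats,
                                   samples, mode, registry)
        reports[float(lead)] = make_report(scores, samples["label"],
                                           {"lead": float(lead)})
    return reports


def evaluate_subgroups(scores, samples: pd.DataFrame,
                       keys=SUBGROUP_KEYS) -> dict[tuple, EvalReport]:
    """Per-subgroup reports; groups lacking either class are omitted."""
    scores = np.asarray(scores, dtype=float)
    reports = {}
    for key in keys:
        for value, idx in samples.groupby(key).groups.items():
            loc = samples.index.get_indexer(idx)
            labels = samples["label"].to_numpy(dtype=int)[loc]
            if len(set(labels)) < 2:
                log.warning("subgroup %s=%s omitted (single class or empty)",
                            key, value)
                continue
            reports[(key, value)] = make_report(
                scores[loc], labels, {"subgroup": f"{key}={value}"})
    return reports


def reports_to_frame(reports) -> pd.DataFrame:
    """Flatten a report mapping into one row per report."""
    if isinstance(reports, dict):
        reports = list(reports.values())
    return pd.DataFrame([r.to_row() for r in reports])
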