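"""Independent brute-force oracles used to cross-check the package.

Everything here is written naively (pure-python loops, exhaustive
enumeration) and must stay independent of the implementations it checks.
"""

from __future__ import annotations

import math


def criterion_hits_oracle(records) -> set[tuple[str, float]]:
    """All (criterion_id, time) pairs by exhaustive window enumeration.

    ``records`` are labeler.TreatmentRecord-likes sorted by time. Windows
    are (t - W, t] anchored at every record time.
    """
    hits: set[tuple[str, float]] = set()
    times = [r.time for r in records]

    for r in records:
        if r.category == "pressor":
            hits.add(("PRESSOR_ANY", r.time))

    fluid_rules = [("FLUID_1H_700", 1.0, 700.0), ("FLUID_4H_1500", 4.0, 1500.0),
                   ("FLUID_8H_2400", 8.0, 2400.0), ("FLUID_12H_3000", 12.0, 3000.0)]
    for crit, window, threshold in fluid_rules:
        for t in times:
            total = sum(r.volume for r in records
                        if r.category == "fluid" and t - window < r.time <= t)
            if total >= threshold - 1e-6:
                if any(r.category == "fluid" and r.time == t for r in records):
                    hits.add((crit, t))

    bigs = [r for r in records if r.category == "fluid" and r.volume >= 500.0 - 1e-6]
    for a in bigs:
        for b in bigs:
            if a is not b and abs(a.time - b.time) <= 4.0:
                hits.add(("FLUID_TWICE_500_4H", max(a.time, b.time)))

    for t in times:
        if not any(r.category == "prbc" and r.time == t for r in records):
            continue
        total24 = sum(r.volume for r in records
                      if r.category == "prbc" and t - 24.0 < r.time <= t)
        if total24 >= 800.0 - 1e-6:
            hits.add(("PRBC_24H_800", t))

    fluid_hit_times = {t for crit, t in hits if crit.startswith("FLUID")}
    for t in times:
        if not any(r.category == "prbc" and r.time == t for r in records):
            continue
        total2 = sum(r.volume for r in records
                     if r.category == "prbc" and t - 2.0 < r.time <= t)
        if total2 < 500.0 - 1e-6:
            continue
        if any(t <= tf <= t + 12.0 for tf in fluid_hit_times):
            hits.add(("PRBC_500_2H_THEN_FLUID_12H", t))
        if not any(t <= tf <= t + 24.0 for tf in fluid_hit_times):
            hits.add(("PRBC_500_NO_FLUID_24H", t))
    return hits


def segments_oracle(records, hit_times) -> list[tuple[float, float]]:
    """(start, end) spans from the >12 h gap rule, given hit times."""
    if not records or not hit_times:
        return []
    clusters = [[records[0]]]
    for rec in records[1:]:
        if rec.time - clusters[-1][-1].time > 12.0:
            clusters.append([rec])
        else:
            clusters[-1].append(rec)
    spans = []
    for cluster in clusters:
        inside = [t for t in hit_times
                  if cluster[0].time <= t <= cluster[-1].time]
        if inside:
            spans.append((min(inside), cluster[-1].time))
    return spans


def auc_pairwise_oracle(scores, labels) -> float:
    """Concordance probability over all positive/negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def best_stump_oracle(X, y, learning_rate=0.1, leaf_clip=4.0):
    """Exhaustive first-round stump search on a tiny dense problem.

    Gain is the squared-error reduction of fitting the negative logistic
    gradient with per-side means; leaf values are Newton steps. Returns
    (feature_index, threshold, left_value, right_value).
    """
    n = len(y)
    prevalence = sum(y) / n
    base = math.log(prevalence / (1 - prevalence))
    p = 1.0 / (1.0 + math.exp(-base))
    g = [yi - p for yi in y]
    h = [p * (1 - p)] * n

    best = None
    for j in range(len(X[0])):
        col = sorted(set(row[j] for row in X))
        for lo, hi in zip(col, col[1:]):
            thr = (lo + hi) / 2.0
            left = [i for i in range(n) if X[i][j] < thr]
            right = [i for i in range(n) if X[i][j] >= thr]
            if not left or not right:
                continue
            gl = sum(g[i] for i in left)
            gr = sum(g[i] for i in right)
            gain = gl ** 2 / len(left) + gr ** 2 / len(right)
            if best is None or gain > best[0] + 1e-9 * max(1.0, abs(gain)):
                vl = max(-leaf_clip, min(leaf_clip, gl / sum(h[i] for i in left)))
                vr = max(-leaf_clip, min(leaf_clip, gr / sum(h[i] for i in right)))
                best = (gain, j, thr, vl * learning_rate, vr * learning_rate)
    assert best is not None
    return best[1:]
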