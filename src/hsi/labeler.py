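"""Rule-based labeling of hemodynamic-intervention segments.

Treatment records (pressor/inotrope doses, fluid administrations, PRBC
transfusions) are scanned for the trigger criteria below; triggered stays
are carved into intervention segments, where a segment runs across
consecutive treatment records until a gap of more than ``GAP_HOURS``
separates two of them.

Trigger criteria
----------------
* any dose of one of the six pressor/inotrope drugs;
* cumulative fluid volume over a trailing window: 700 cc / 1 h,
  1500 cc / 4 h, 2400 cc / 8 h, 3000 cc / 12 h;
* two distinct fluid administrations of >= 500 cc each within 4 h;
* cumulative PRBC >= 800 cc over a trailing 24 h window;
* cumulative PRBC >= 500 cc over a trailing 2 h window followed by
  fluid therapy (a fluid criterion hit) within 12 h;
* cumulative PRBC >= 500 cc over a trailing 2 h window *not* followed by
  fluid therapy within 24 h (absence until end of stay qualifies).

All windows are half-open ``(t - W, t]`` anchored at record times; a
criterion fires at cumulative volume >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PRESSOR_DRUGS = frozenset({
    "dobutamine", "dopamine", "epinephrine",
    "norepinephrine", "phenylephrine", "vasopressin",
})

CATEGORIES = ("pressor", "fluid", "prbc")

#: maximal gap (hours) between consecutive treatment records inside one segment
GAP_HOURS = 12.0

#: trailing-window fluid rules: criterion id -> (window hours, threshold cc)
FLUID_WINDOW_RULES = {
    "FLUID_1H_700": (1.0, 700.0),
    "FLUID_4H_1500": (4.0, 1500.0),
    "FLUID_8H_2400": (8.0, 2400.0),
    "FLUID_12H_3000": (12.0, 3000.0),
}

TWICE_VOLUME = 500.0
TWICE_WINDOW = 4.0

PRBC_24H_THRESHOLD = 800.0
PRBC_24H_WINDOW = 24.0
PRBC_2H_THRESHOLD = 500.0
PRBC_2H_WINDOW = 2.0
PRBC_FLUID_FOLLOW = 12.0
PRBC_NO_FLUID_FOLLOW = 24.0

CRITERION_IDS = (
    "PRESSOR_ANY",
    *FLUID_WINDOW_RULES,
    "FLUID_TWICE_500_4H",
    "PRBC_24H_800",
    "PRBC_500_2H_THEN_FLUID_12H",
    "PRBC_500_NO_FLUID_24H",
)

# absorbs float round-off when fractional aliquots sum to a threshold
_VOL_EPS = 1e-6


@dataclass(frozen=True)
class TreatmentRecord:
    """One timestamped administration for a stay."""

    stay_id: str
    category: str
    time: float  # hours since ICU admission
    volume: float = 0.0  # cc; ignored for pressors ("any quantity")
    drug: str = ""  # pressors only

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown treatment category {self.category!r}")
        if self.time < 0:
            raise ValueError("treatment time must be >= 0")
        if self.category == "pressor":
            if self.drug not in PRESSOR_DRUGS:
                raise ValueError(f"unknown pressor drug {self.drug!r}")
        elif self.volume < 0:
            raise ValueError("volume must be >= 0 for fluid/prbc records")


@dataclass(frozen=True)
class CriterionHit:
    """A trigger criterion satisfied at ``time`` by the listed records."""

    criterion_id: str
    time: float
    contributing: tuple[int, ...]  # indices into the stay's record list


@dataclass
class InterventionSegment:
    stay_id: str
    start: float  # time of the first criterion hit in the segment
    end: float  # time of the last treatment record in the segment
    criteria: list[CriterionHit] = field(default_factory=list)

    @property
    def criterion_ids(self) -> set[str]:
        return {h.criterion_id for h in self.criteria}


def _check_sorted(records: list[TreatmentRecord]) -> None:
    for a, b in zip(records, records[1:]):
        if b.time < a.time:
            raise ValueError("treatment records must be sorted by time")
    stays = {r.stay_id for r in records}
    if len(stays) > 1:
        raise ValueError(f"records span multiple stays: {sorted(stays)}")


def _window_sum(records, idx, category, window):
    """Indices and cumulative volume of `category` records in (t-W, t]."""
    t = records[idx].time
    members = [
        j for j, r in enumerate(records)
        if r.category == category and t - window < r.time <= t
    ]
    return members, sum(records[j].volume for j in members)


def evaluate_criteria(records: list[TreatmentRecord]) -> list[CriterionHit]:
    """All criterion hits over the time-ordered records of one stay.

    Every time at which a criterion is satisfied yields a hit (not just the
    first), so segment construction can reopen segments after long gaps.
    """
    _check_sorted(records)
    hits: list[CriterionHit] = []

    for i, rec in enumerate(records):
        if rec.category == "pressor":
            hits.append(CriterionHit("PRESSOR_ANY", rec.time, (i,)))

    for crit, (window, threshold) in FLUID_WINDOW_RULES.items():
        for i, rec in enumerate(records):
            if rec.category != "fluid":
                continue
            members, total = _window_sum(records, i, "fluid", window)
            if total >= threshold - _VOL_EPS:
                hits.append(CriterionHit(crit, rec.time, tuple(members)))

    big = [i for i, r in enumerate(records)
           if r.category == "fluid" and r.volume >= TWICE_VOLUME - _VOL_EPS]
    for j in big:
        partners = [i for i in big
                    if i != j and records[i].time <= records[j].time
                    and records[j].time - records[i].time <= TWICE_WINDOW]
        if partners:
            hits.append(CriterionHit("FLUID_TWICE_500_4H", records[j].time,
                                     (min(partners), j)))

    for i, rec in enumerate(records):
        if rec.category != "prbc":
            continue
        members, total = _window_sum(records, i, "prbc", PRBC_24H_WINDOW)
        if total >= PRBC_24H_THRESHOLD - _VOL_EPS:
            hits.append(CriterionHit("PRBC_24H_800", rec.time, tuple(members)))

    fluid_hit_times = sorted({h.time for h in hits
                              if h.criterion_id in FLUID_WINDOW_RULES
                              or h.criterion_id == "FLUID_TWICE_500_4H"})
    for i, rec in enumerate(records):
        if rec.category != "prbc":
            continue
        members, total = _window_sum(records, i, "prbc", PRBC_2H_WINDOW)
        if total < PRBC_2H_THRESHOLD - _VOL_EPS:
            continue
        t = rec.time
        followed_12 = any(t <= tf <= t + PRBC_FLUID_FOLLOW for tf in fluid_hit_times)
        followed_24 = any(t <= tf <= t + PRBC_NO_FLUID_FOLLOW for tf in fluid_hit_times)
        if followed_12:
            hits.append(CriterionHit("PRBC_500_2H_THEN_FLUID_12H", t, tuple(members)))
        if not followed_24:
            # end of the observed record stream counts as "not followed"
            hits.append(CriterionHit("PRBC_500_NO_FLUID_24H", t, tuple(members)))

    # dedupe repeated (criterion, time) pairs, keep first contributing set
    seen: dict[tuple[str, float], CriterionHit] = {}
    for h in sorted(hits, key=lambda h: (h.time, h.criterion_id)):
        seen.setdefault((h.criterion_id, h.time), h)
    return sorted(seen.values(), key=lambda h: (h.time, h.criterion_id))


def build_segments(records: list[TreatmentRecord],
                   hits: list[CriterionHit]) -> list[InterventionSegment]:
    """Group records into gap-delimited clusters and attach criterion hits.

    A cluster whose span contains at least one hit becomes a segment that
    starts at its earliest hit time and ends at the cluster's last record.
    """
    if not records or not hits:
        return []
    _check_sorted(records)
    stay_id = records[0].stay_id

    clusters: list[list[TreatmentRecord]] = [[records[0]]]
    for rec in records[1:]:
        if rec.time - clusters[-1][-1].time > GAP_HOURS:
            clusters.append([rec])
        else:
            clusters[-1].append(rec)

    segments = []
    for cluster in clusters:
        lo, hi = cluster[0].time, cluster[-1].time
        in_cluster = [h for h in hits if lo <= h.time <= hi]
        if in_cluster:
            segments.append(InterventionSegment(
                stay_id=stay_id,
                start=min(h.time for h in in_cluster),
                end=hi,
                criteria=in_cluster,
            ))
    return segments


def label_stay(records: list[TreatmentRecord]) -> tuple[str, list[InterventionSegment]]:
    """Label one stay stable/unstable from its full treatment history."""
    records = sorted(records, key=lambda r: r.time)
    hits = evaluate_criteria(records)
    segments = build_segments(records, hits)
    return ("unstable" if segments else "stable"), segments


# ---------------------------------------------------------------------------
# DataFrame plumbing

def records_from_frame(treatments: pd.DataFrame) -> dict[str, list[TreatmentRecord]]:
    """Parse a treatments table into per-stay, time-sorted record lists."""
    required = {"stay_id", "category", "time", "volume", "drug"}
    missing = required - set(treatments.columns)
    if missing:
        raise ValueError(f"treatments table missing columns: {sorted(missing)}")
    out: dict[str, list[TreatmentRecord]] = {}
    for row in treatments.sort_values(["stay_id", "time"]).itertuples(index=False):
        drug = "" if pd.isna(row.drug) else str(row.drug)
        vol = 0.0 if pd.isna(row.volume) else float(row.volume)
        rec = TreatmentRecord(stay_id=str(row.stay_id), category=str(row.category),
                              time=float(row.time), volume=vol, drug=drug)
        out.setdefault(rec.stay_id, []).append(rec)
    return out


def label_cohort(treatments: pd.DataFrame) -> pd.DataFrame:
    """Segments for every stay with at least one record.

    Returns a frame with columns stay_id, start, end, criteria (semicolon
    joined criterion ids). Stays without segments are simply absent.
    """
    rows = []
    for stay_id, records in records_from_frame(treatments).items():
        _, segments = label_stay(records)
        for seg in segments:
            rows.append({
                "stay_id": stay_id,
                "start": seg.start,
                "end": seg.end,
                "criteria": ";".join(sorted(seg.criterion_ids)),
            })
    return pd.DataFrame(rows, columns=["stay_id", "start", "end", "criteria"])
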