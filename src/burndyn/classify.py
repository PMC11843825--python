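"""Preliminary per-day burn-class estimation from parameter-space regions.

A segment's PS_2 point (deep perfusion — the space that carries most class
information) is tested against the day's class hulls; the PS_1 point serves
as tie-breaker evidence. Membership in exactly one hull yields that class;
membership in several yields the most severe contained class (clinically
conservative: missing a deep burn costs more than over-grading), with
confidence reduced accordingly; membership in none falls back to the hull
with the nearest centroid at confidence 0. Reliability against the healing
time reference is summarised per day by a confusion matrix, accuracy and
per-class recall, with regions built from training wounds only
(leave-one-wound-out) to avoid self-classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .dynamics import ClassRegion, class_regions, overlap
from .reference import CLASS_ORDER, BurnClass
from .secondary import PS1, PS2, ParamPoint

__all__ = [
    "ClassEstimate",
    "classify_point",
    "evaluate_day",
    "classify_cohort",
    "accuracy_by_day",
]


@dataclass(frozen=True)
class ClassEstimate:
    """A class estimate with its ambiguity set and confidence."""

    segment_id: str
    day: int
    estimated: BurnClass
    confidence: float
    ambiguous: tuple

    def __post_init__(self) -> None:
        if self.ambiguous and self.estimated not in self.ambiguous:
            raise ValueError("estimate must belong to the ambiguous set")


def _containing(point: ParamPoint, regions: dict[BurnClass, ClassRegion]):
    p = Point(point.x, point.y)
    return [c for c in CLASS_ORDER if c in regions and regions[c].polygon().covers(p)]


def classify_point(
    ps2_point: ParamPoint,
    regions_ps2: dict[BurnClass, ClassRegion],
    ps1_point: ParamPoint | None = None,
    regions_ps1: dict[BurnClass, ClassRegion] | None = None,
    segment_id: str = "",
    day: int = 0,
) -> ClassEstimate:
    """Estimate the class of one segment-day point.

    PS_2 membership is primary. If the PS_2 point lies in several hulls and
    PS_1 evidence is available, classes also containing the PS_1 point are
    preferred; the most severe candidate wins. Outside all hulls, the
    nearest hull centroid decides at confidence 0.
    """
    if not regions_ps2:
        raise ValueError(f"no regions available for day {day}")
    inside = _containing(ps2_point, regions_ps2)

    if not inside:
        dists = [
            (float(np.hypot(*(np.array(r.polygon().centroid.coords[0]) -
                              ps2_point.as_array()))), c.severity, c)
            for c, r in regions_ps2.items()
        ]
        est = min(dists)[2]
        return ClassEstimate(segment_id, day, est, 0.0, ())

    candidates = inside
    if len(inside) > 1 and ps1_point is not None and regions_ps1:
        also_ps1 = [c for c in inside if c in _containing(ps1_point, regions_ps1)]
        if also_ps1:
            candidates = also_ps1
    est = max(candidates, key=lambda c: c.severity)

    others = [c for c in regions_ps2 if c is not est]
    crowd = sum(overlap(regions_ps2[est], regions_ps2[o]) for o in others)
    confidence = max(0.0, 1.0 - crowd) / len(inside)
    return ClassEstimate(segment_id, day, est, confidence, tuple(inside))


def evaluate_day(
    estimates: pd.DataFrame, reference: pd.DataFrame, day: int
) -> dict:
    """Confusion matrix, accuracy and per-class recall for one day.

    ``estimates`` needs columns segment_id, day, estimated_class;
    ``reference`` needs segment_id and ref_class (day-constant). Rows of the
    confusion matrix are reference classes, columns estimates; row sums
    equal the reference class counts.
    """
    est = estimates[estimates["day"] == day][["segment_id", "estimated_class"]]
    ref = reference[["segment_id", "ref_class"]].drop_duplicates("segment_id")
    merged = est.merge(ref, on="segment_id", how="inner")
    if merged.empty:
        raise ValueError(f"no matched segment ids on day {day}")
    names = [c.value for c in CLASS_ORDER]
    mat = pd.DataFrame(0, index=names, columns=names)
    for _, row in merged.iterrows():
        mat.loc[row["ref_class"], row["estimated_class"]] += 1
    total = mat.to_numpy().sum()
    correct = np.trace(mat.to_numpy())
    recall = {
        name: (float(mat.loc[name, name] / rs) if (rs := mat.loc[name].sum()) else np.nan)
        for name in names
    }
    return {
        "day": day,
        "confusion": mat,
        "accuracy": float(correct / total),
        "recall": recall,
        "n": int(total),
    }


def classify_cohort(
    table: pd.DataFrame,
    days=(0, 1, 2, 3),
    leave_one_wound_out: bool = True,
    mass: float = 0.68,
    grid_n: int = 200,
    label_col: str = "true_class",
) -> pd.DataFrame:
    """Classify every segment-day point of a cohort table.

    ``table`` needs segment_id, wound_id, day, ``label_col`` and the
    composed coordinates. With ``leave_one_wound_out`` the day's class
    regions are rebuilt from all other wounds before classifying a wound's
    segments.
    """
    kw = dict(mass=mass, grid_n=grid_n, label_col=label_col)
    cols = ["segment_id", "day", "estimated_class", "confidence", "ambiguous_set"]
    rows = []
    for day in days:
        sub = table[table["day"] == day]
        if leave_one_wound_out:
            for wid, grp in sub.groupby("wound_id", sort=True):
                train = table[table["wound_id"] != wid]
                r2 = class_regions(train, day, PS2, **kw)
                r1 = class_regions(train, day, PS1, **kw)
                if not r2:  # too few training points that day
                    continue
                rows.extend(_classify_rows(grp, r2, r1, day))
        else:
            r2 = class_regions(table, day, PS2, **kw)
            r1 = class_regions(table, day, PS1, **kw)
            if not r2:
                continue
            rows.extend(_classify_rows(sub, r2, r1, day))
    return pd.DataFrame(rows, columns=cols)


def _classify_rows(grp, regions_ps2, regions_ps1, day):
    out = []
    for _, row in grp.iterrows():
        p2 = ParamPoint(PS2, float(np.clip(row["v2"], 0, 1)), float(np.clip(row["flow2"], 0, 1)))
        p1 = ParamPoint(PS1, float(np.clip(row["v1"], 0, 1)), float(np.clip(row["xrate"], 0, 1)))
        est = classify_point(p2, regions_ps2, p1, regions_ps1,
                             segment_id=str(row["segment_id"]), day=day)
        out.append(
            {
                "segment_id": est.segment_id,
                "day": day,
                "estimated_class": est.estimated.value,
                "confidence": est.confidence,
                "ambiguous_set": "|".join(c.value for c in est.ambiguous),
            }
        )
    return out


def accuracy_by_day(estimates: pd.DataFrame, reference: pd.DataFrame, days=(0, 1, 2, 3)) -> dict:
    """Per-day overall accuracy as a plain dict."""
    return {
        day: evaluate_day(estimates, reference, day)["accuracy"] for day in days
    }
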