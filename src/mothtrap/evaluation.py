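"""Tracking and classification quality metrics.

Tracking is scored against a manually (or synthetically) established
ground truth of unique individuals.  A true positive is an individual
that kept a single track ID over its whole presence; an individual that
was split across several tracks, or a track matching no individual,
counts as false positives.  From these,

    TDR = TP / GT            (tracking detection rate)
    FAR = FP / (TP + FP)     (false alarm rate)

Classification quality uses the usual per-class precision, recall and
F1 computed from TP/FP/FN counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from mothtrap.tracking import Track

__all__ = [
    "TrackingEvaluation",
    "ClassMetrics",
    "tdr",
    "far",
    "class_metrics",
    "evaluate_tracking",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero to ``ndigits`` decimals (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TrackingEvaluation:
    tp: int
    fp: int
    gt: int

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0:
            raise ValueError("counts must be non-negative")
        if self.gt < 1:
            raise ValueError("ground truth must contain at least one individual")

    @property
    def tdr(self) -> float:
        return tdr(self.tp, self.gt)

    @property
    def far(self) -> float:
        return far(self.tp, self.fp)


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]


def tdr(tp: int, gt: int) -> float:
    """Tracking detection rate TP / GT."""
    if gt < 1:
        raise ValueError("GT must be >= 1")
    if not 0 <= tp <= gt:
        raise ValueError("TP must lie in [0, GT]")
    return tp / gt


def far(tp: int, fp: int) -> float:
    """False alarm rate FP / (TP + FP)."""
    if tp + fp < 1:
        raise ValueError("TP + FP must be >= 1")
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    return fp / (tp + fp)


def class_metrics(tp: int, fp: int, fn: int) -> ClassMetrics:
    """Precision, recall and F1 from raw counts.

    A metric with an undefined denominator is reported as None rather
    than coerced to zero.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        raise ValueError("at least one count must be positive")
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    return ClassMetrics(tp, fp, fn, precision, recall, f1)


def _truth_by_individual(truth: pd.DataFrame) -> Dict:
    required = {"individual_id", "frame_index", "cx", "cy"}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"ground truth missing columns: {sorted(missing)}")
    if len(truth) == 0:
        raise ValueError("ground truth is empty")
    return {gid: g.set_index("frame_index") for gid, g in truth.groupby("individual_id")}


def _owner_of(det, truth_rows: pd.DataFrame) -> bool:
    """Does the detection's centroid fall inside the truth bbox (or near the centroid)?"""
    cx, cy = det.centroid
    if {"x_min", "y_min", "width", "height"} <= set(truth_rows.index):
        x0, y0 = truth_rows["x_min"], truth_rows["y_min"]
        return bool(x0 <= cx <= x0 + truth_rows["width"] and
                    y0 <= cy <= y0 + truth_rows["height"])
    dx, dy = cx - truth_rows["cx"], cy - truth_rows["cy"]
    return bool(np.hypot(dx, dy) <= 50.0)


def evaluate_tracking(tracks: Sequence[Track], truth: pd.DataFrame) -> TrackingEvaluation:
    """Score predicted tracks against a per-frame ground-truth table.

    ``truth`` has one row per individual per frame with columns
    individual_id, frame_index, cx, cy and optionally the bbox
    (x_min, y_min, width, height).  Each track is attributed per frame
    to the individual whose bbox contains the track's centroid (nearest
    centroid as a fallback), and owned by the individual winning the
    majority of its frames.  An individual is a TP when exactly one
    track owns it and that track spans the individual's full presence;
    every other track is an FP.
    """
    by_id = _truth_by_individual(truth)
    owners: Dict[int, List[int]] = {}  # individual -> owning track indices
    matched_any: List[bool] = []
    for ti, track in enumerate(tracks):
        votes: Dict = {}
        for det in track.detections:
            for gid, rows in by_id.items():
                if det.frame_index in rows.index and _owner_of(det, rows.loc[det.frame_index]):
                    votes[gid] = votes.get(gid, 0) + 1
                    break
        if votes and max(votes.values()) > len(track.detections) / 2:
            owner = max(votes, key=votes.get)
            owners.setdefault(owner, []).append(ti)
            matched_any.append(True)
        else:
            matched_any.append(False)

    tp = 0
    for gid, rows in by_id.items():
        owning = owners.get(gid, [])
        if len(owning) != 1:
            continue
        track = tracks[owning[0]]
        frames = set(track.frames)
        if set(rows.index).issubset(frames):
            tp += 1
    fp = len(tracks) - tp
    return TrackingEvaluation(tp=tp, fp=fp, gt=len(by_id))
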