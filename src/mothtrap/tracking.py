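"""Frame-to-frame insect tracking by minimum-cost assignment.

Resting moths barely move between captures, so linking detections in two
consecutive frames reduces to an assignment problem: the cost of pairing
a previous detection with a current one combines the centroid distance,
normalised by the image diagonal, and the dissimilarity of bounding-box
areas:

    cost = (dist / max_dist) * Wdist + (1 - min(A1,A2)/max(A1,A2)) * Warea

The cost matrix is padded with dummy rows/columns of prohibitively high
cost so it is always square; a real detection matched to a dummy marks an
insect entering or leaving the view.  The optimal assignment is found
with the Hungarian method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from mothtrap.segmentation import Detection

__all__ = [
    "CostParams",
    "Track",
    "AssignmentResult",
    "Tracker",
    "dist",
    "max_dist",
    "area_cost",
    "pair_cost",
    "build_cost_matrix",
    "solve_assignment",
    "step_tracks",
]


@dataclass(frozen=True)
class CostParams:
    """Weights of the pairing cost and the dummy padding cost.

    Distance dominates by default (insects are near-stationary between
    captures).  ``dummy_cost`` must strictly exceed any achievable real
    cost, whose supremum is ``Wdist + Warea``; the default doubles it.
    """

    w_dist: float = 0.8
    w_area: float = 0.2
    dummy_cost: Optional[float] = None

    def __post_init__(self) -> None:
        if self.w_dist < 0 or self.w_area < 0 or self.w_dist + self.w_area <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        if self.dummy_cost is None:
            object.__setattr__(self, "dummy_cost", 2.0 * (self.w_dist + self.w_area))
        if self.dummy_cost <= self.w_dist + self.w_area:
            raise ValueError("dummy_cost must exceed the maximal real cost Wdist + Warea")


@dataclass
class Track:
    """The linked identity of one insect across consecutive frames."""

    track_id: int
    detections: List[Detection] = field(default_factory=list)
    label_history: List[Tuple[str, float]] = field(default_factory=list)  # (label, confidence)
    final_label: Optional[str] = None
    counted: bool = True

    def add(self, det: Detection) -> None:
        if self.detections and det.frame_index <= self.detections[-1].frame_index:
            raise ValueError("detections must be appended in increasing frame order")
        self.detections.append(det)

    @property
    def last(self) -> Detection:
        return self.detections[-1]

    @property
    def first_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.detections[-1].frame_index

    @property
    def frames(self) -> List[int]:
        return [d.frame_index for d in self.detections]


@dataclass
class AssignmentResult:
    """Outcome of one padded assignment between two frames."""

    matches: List[Tuple[int, int]]  # (prev_index, curr_index)
    entered: List[int]  # current indices matched to a dummy row
    exited: List[int]  # previous indices matched to a dummy column
    total_cost: float


def dist(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Euclidean distance between two centroids, in pixels."""
    return math.hypot(p2[0] - p1[0], p2[1] - p1[1])


def max_dist(i_height: float, i_width: float) -> float:
    """Image diagonal, the normalising constant of the distance cost."""
    if i_height <= 0 or i_width <= 0:
        raise ValueError("image dimensions must be positive")
    return math.hypot(i_height, i_width)


def area_cost(area_a: float, area_b: float) -> float:
    """Bounding-box size similarity min/max, in (0, 1]; 1 means equal areas."""
    if area_a <= 0 or area_b <= 0:
        raise ValueError("areas must be positive")
    return min(area_a, area_b) / max(area_a, area_b)


def pair_cost(
    d_prev: Detection,
    d_curr: Detection,
    params: CostParams,
    i_height: float,
    i_width: float,
) -> float:
    """Weighted pairing cost in [0, Wdist + Warea]; 0 iff same position and size."""
    d = dist(d_prev.centroid, d_curr.centroid)
    a = area_cost(d_prev.bbox_area, d_curr.bbox_area)
    return (d / max_dist(i_height, i_width)) * params.w_dist + (1.0 - a) * params.w_area


def build_cost_matrix(
    prev: Sequence[Detection],
    curr: Sequence[Detection],
    params: CostParams,
    i_height: float,
    i_width: float,
) -> np.ndarray:
    """Square N x N cost matrix, N = max(|prev|, |curr|), dummy-padded.

    Rows index previous detections, columns current ones; rows beyond
    |prev| or columns beyond |curr| are dummies at ``dummy_cost``.
    """
    n = max(len(prev), len(curr))
    cost = np.full((n, n), params.dummy_cost, dtype=float)
    for i, dp in enumerate(prev):
        for j, dc in enumerate(curr):
            cost[i, j] = pair_cost(dp, dc, params, i_height, i_width)
    return cost


def solve_assignment(
    cost: np.ndarray,
    n_prev: Optional[int] = None,
    n_curr: Optional[int] = None,
) -> AssignmentResult:
    """Minimum-cost perfect matching of a square cost matrix (Hungarian).

    ``n_prev``/``n_curr`` mark how many leading rows/columns are real
    detections; matches involving a dummy are reported as exits/entries.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError(f"cost matrix must be square, got shape {cost.shape}")
    if cost.size == 0:
        return AssignmentResult([], [], [], 0.0)
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    n = cost.shape[0]
    n_prev = n if n_prev is None else n_prev
    n_curr = n if n_curr is None else n_curr
    rows, cols = linear_sum_assignment(cost)
    matches, entered, exited = [], [], []
    for r, c in zip(rows, cols):
        if r < n_prev and c < n_curr:
            matches.append((int(r), int(c)))
        elif r >= n_prev and c < n_curr:
            entered.append(int(c))
        elif r < n_prev and c >= n_curr:
            exited.append(int(r))
    return AssignmentResult(matches, entered, exited, float(cost[rows, cols].sum()))


def step_tracks(
    active: List[Track],
    curr: Sequence[Detection],
    params: CostParams,
    i_height: float,
    i_width: float,
    next_id: int = 0,
) -> Tuple[List[Track], List[Track], int]:
    """Advance tracking by one frame.

    Matched current detections inherit the matched track's ID; unmatched
    current detections open new tracks; tracks matched to a dummy are
    closed immediately (no coasting).  Returns (active, closed, next_id).
    """
    curr = list(curr)
    if not active and not curr:
        return [], [], next_id
    prev_dets = [t.last for t in active]
    cost = build_cost_matrix(prev_dets, curr, params, i_height, i_width)
    result = solve_assignment(cost, n_prev=len(prev_dets), n_curr=len(curr))

    still_active: List[Track] = []
    closed: List[Track] = []
    for i, j in result.matches:
        active[i].add(curr[j])
        still_active.append(active[i])
    for i in result.exited:
        closed.append(active[i])
    for j in result.entered:
        t = Track(track_id=next_id)
        next_id += 1
        t.add(curr[j])
        still_active.append(t)
    still_active.sort(key=lambda t: t.track_id)
    return still_active, closed, next_id


class Tracker:
    """Stateful wrapper running the per-frame assignment over a sequence.

    Track IDs are unique within a run and never reused; a track closed by
    a missed frame is never revived (a returning insect becomes a new
    individual, as in the field protocol).
    """

    def __init__(self, i_height: float, i_width: float, params: CostParams | None = None):
        self.params = params or CostParams()
        self.i_height = i_height
        self.i_width = i_width
        self.active: List[Track] = []
        self.closed: List[Track] = []
        self._next_id = 0

    def update(self, detections: Sequence[Detection]) -> List[Track]:
        """Feed one frame's detections; returns the currently active tracks."""
        self.active, newly_closed, self._next_id = step_tracks(
            self.active, detections, self.params, self.i_height, self.i_width, self._next_id
        )
        self.closed.extend(newly_closed)
        return self.active

    def finish(self) -> List[Track]:
        """Close all remaining tracks and return every track of the run."""
        self.closed.extend(self.active)
        self.active = []
        all_tracks = sorted(self.closed, key=lambda t: t.track_id)
        return all_tracks
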