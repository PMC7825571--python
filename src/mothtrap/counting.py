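"""Reduce tracks to per-survey statistics.

A track's species is the most frequent per-frame prediction (majority
vote), demoted to "unknown" when the background class wins the vote or
when the mean confidence falls below a threshold.  Tracks are counted
only if they persist for a minimum run of consecutive frames, which
filters transient blobs such as insects flying close to the lens.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from mothtrap.classification import BACKGROUND, SPECIES
from mothtrap.tracking import Track

__all__ = ["UNKNOWN", "SurveySummary", "track_label", "filter_tracks", "summarize"]

UNKNOWN = "unknown"


@dataclass
class SurveySummary:
    """Counts of one survey (one night's image sequence)."""

    species_counts: Dict[str, int] = field(default_factory=dict)
    unknown_count: int = 0
    total_individuals: int = 0
    n_frames: int = 0
    start_time: Optional[float] = None
    end_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.total_individuals != sum(self.species_counts.values()) + self.unknown_count:
            raise ValueError("total_individuals must equal species counts + unknowns")


def track_label(track: Track, unknown_threshold: float = 0.5) -> str:
    """Majority vote over the track's per-frame predictions.

    Ties break toward the label seen in the earliest frame.  The result
    is "unknown" when the background class wins or the mean confidence
    of the winning label is below ``unknown_threshold``.
    """
    if not track.label_history:
        raise ValueError("track has no label history")
    votes = Counter(lab for lab, _ in track.label_history)
    best = max(votes.most_common(), key=lambda kv: (kv[1], -_first_index(track, kv[0])))
    label = best[0]
    if label == BACKGROUND or label == UNKNOWN:
        return UNKNOWN
    confs = [c for lab, c in track.label_history if lab == label]
    if sum(confs) / len(confs) < unknown_threshold:
        return UNKNOWN
    return label


def _first_index(track: Track, label: str) -> int:
    return next(i for i, (lab, _) in enumerate(track.label_history) if lab == label)


def longest_consecutive_run(frames: Sequence[int]) -> int:
    """Length of the longest run of consecutive frame indices."""
    if not frames:
        return 0
    best = run = 1
    for a, b in zip(frames, frames[1:]):
        run = run + 1 if b == a + 1 else 1
        best = max(best, run)
    return best


def filter_tracks(tracks: Sequence[Track], min_consecutive: int = 3,
                  accepted_frames: Optional[Sequence[int]] = None) -> List[Track]:
    """Mark and return tracks observed in >= ``min_consecutive`` consecutive frames.

    Rejected tracks get ``counted=False`` (noise such as near-lens
    transients rarely persists); accepted ones are returned.  When the
    motion gate skipped frames, pass the processed frame indices as
    ``accepted_frames`` so "consecutive" means adjacent accepted frames
    rather than adjacent raw indices.
    """
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    position = (None if accepted_frames is None
                else {f: i for i, f in enumerate(accepted_frames)})
    kept = []
    for t in tracks:
        frames = t.frames if position is None else [position[f] for f in t.frames]
        t.counted = longest_consecutive_run(frames) >= min_consecutive
        if t.counted:
            kept.append(t)
    return kept


def summarize(tracks: Sequence[Track], n_frames: int = 0,
              start_time: Optional[float] = None,
              end_time: Optional[float] = None) -> SurveySummary:
    """Per-species counts of the counted tracks.

    Expects tracks whose ``final_label`` is set (via :func:`track_label`)
    and that have been passed through :func:`filter_tracks`; uncounted
    tracks are ignored.
    """
    counts: Dict[str, int] = {name: 0 for name in SPECIES}
    unknown = 0
    total = 0
    for t in tracks:
        if not t.counted:
            continue
        total += 1
        label = t.final_label if t.final_label is not None else UNKNOWN
        if label in counts:
            counts[label] += 1
        else:
            unknown += 1
    return SurveySummary(
        species_counts=counts,
        unknown_count=unknown,
        total_individuals=total,
        n_frames=n_frames,
        start_time=start_time,
        end_time=end_time,
    )
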