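"""The full survey run: segment, track, classify, count, write artifacts.

``run_survey`` executes the per-frame loop over a capture directory — an
optional motion gate, background-subtraction segmentation, Hungarian
track assignment, per-detection CNN classification — then reduces the
finished tracks to a survey summary with the majority-vote labeling and
consecutive-frame noise filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from mothtrap import io as mio
from mothtrap.classification import load_model, predict, preprocess_crop
from mothtrap.counting import SurveySummary, filter_tracks, summarize, track_label
from mothtrap.segmentation import SegmentationConfig, segment_frame, motion_gate
from mothtrap.tracking import CostParams, Tracker

__all__ = ["RunConfig", "run_survey"]

logger = logging.getLogger("mothtrap")


@dataclass
class RunConfig:
    """Everything one survey run needs."""

    frames_dir: Path
    background_path: Path
    output_dir: Path
    model_path: Optional[Path] = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    cost: CostParams = field(default_factory=CostParams)
    min_consecutive: int = 3
    unknown_threshold: float = 0.5
    pad_fraction: float = 0.1
    use_motion_gate: bool = False
    annotate: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, data: Dict) -> "RunConfig":
        seg = SegmentationConfig(**data.get("segmentation", {}))
        cost = CostParams(**data.get("tracking", {}))
        keys = {"frames_dir", "background_path", "output_dir", "model_path",
                "min_consecutive", "unknown_threshold", "pad_fraction",
                "use_motion_gate", "annotate", "seed"}
        kwargs = {k: v for k, v in data.items() if k in keys}
        for k in ("frames_dir", "background_path", "output_dir", "model_path"):
            if kwargs.get(k) is not None:
                kwargs[k] = Path(kwargs[k])
        return cls(segmentation=seg, cost=cost, **kwargs)


def run_survey(config: RunConfig) -> SurveySummary:
    """Run the whole pipeline over one capture directory.

    Writes detections.csv, tracks.csv, summary.csv and summary.json to
    the output directory (and annotated frames when requested) and
    returns the survey summary.  Without a model file every track is
    labeled "unknown" but still detected, tracked and counted.
    """
    frames = mio.list_frames(config.frames_dir)
    if len(frames) < 2:
        raise ValueError(f"need at least 2 frames, found {len(frames)} in {config.frames_dir}")
    if not Path(config.background_path).is_file():
        raise FileNotFoundError(f"background image not found: {config.background_path}")
    model = None
    if config.model_path is not None:
        if not Path(config.model_path).is_file():
            raise FileNotFoundError(f"model weights not found: {config.model_path}")
        model, _ = load_model(config.model_path)

    background = mio.read_image(config.background_path)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tracker = Tracker(background.shape[0], background.shape[1], config.cost)
    all_detections = []
    images_for_annotation = []
    previous = None
    accepted_frames = []
    for frame_index, path in enumerate(frames):
        try:
            image = mio.read_image(path)
        except Exception as exc:  # unreadable frame: log and move on
            logger.warning("skipping unreadable frame %s: %s", path.name, exc)
            continue
        if config.use_motion_gate and previous is not None:
            if not motion_gate(image, previous,
                               config.segmentation.motion_gate_pixels,
                               config.segmentation.motion_gate_delta):
                previous = image
                continue
        previous = image
        accepted_frames.append(frame_index)
        detections = segment_frame(image, background, config.segmentation,
                                   frame_index=frame_index)
        all_detections.extend(detections)
        logger.info("frame %d (%s): %d detections", frame_index, path.name, len(detections))
        active = tracker.update(detections)
        if model is not None:
            for track in active:
                if track.last.frame_index == frame_index:
                    crop = preprocess_crop(image, track.last, config.pad_fraction)
                    track.label_history.append(predict(model, crop))
        if config.annotate:
            images_for_annotation.append((frame_index, path.name, image, list(active)))

    tracks = tracker.finish()
    for t in tracks:
        t.final_label = (track_label(t, config.unknown_threshold)
                         if t.label_history else None)
    filter_tracks(tracks, config.min_consecutive, accepted_frames)
    for t in tracks:
        logger.info("track %d: frames %d-%d, %d detections, label=%s, counted=%s",
                    t.track_id, t.first_frame, t.last_frame, len(t.detections),
                    t.final_label, t.counted)
    summary = summarize(tracks, n_frames=len(accepted_frames))

    mio.write_detections_csv(all_detections, out_dir / "detections.csv")
    mio.write_tracks_csv(tracks, out_dir / "tracks.csv",
                         history_path=out_dir / "tracks.jsonl")
    mio.write_summary(summary, out_dir / "summary.csv", out_dir / "summary.json")
    if config.annotate:
        ann_dir = out_dir / "annotated"
        ann_dir.mkdir(exist_ok=True)
        for frame_index, name, image, active in images_for_annotation:
            mio.write_image(ann_dir / name, mio.annotate_frame(image, active, frame_index))
    return summary
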