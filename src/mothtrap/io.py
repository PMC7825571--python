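"""File formats of the pipeline: frames, detection/track/truth CSV, config.

Frames are plain JPG/PNG files read in natural-sort order of their
filenames (the capture software numbers them); every tabular artifact
is a CSV that round-trips through pandas, and configuration is YAML
(JSON is a subset and therefore also accepted).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from mothtrap.counting import SurveySummary
from mothtrap.segmentation import Detection
from mothtrap.tracking import Track

__all__ = [
    "natural_key",
    "list_frames",
    "read_image",
    "write_image",
    "detections_to_frame",
    "write_detections_csv",
    "read_detections_csv",
    "write_tracks_csv",
    "write_summary",
    "read_truth_csv",
    "write_truth_csv",
    "load_config",
    "annotate_frame",
]

_FRAME_EXTENSIONS = {".jpg", ".jpeg", ".png"}

DETECTION_COLUMNS = ["frame_index", "x_min", "y_min", "width", "height", "cx", "cy", "area"]


def natural_key(name: str) -> Tuple:
    """Sort key treating digit runs numerically (frame2 < frame10)."""
    return tuple(int(tok) if tok.isdigit() else tok.lower()
                 for tok in re.split(r"(\d+)", name))


def list_frames(directory) -> List[Path]:
    """Image files of a capture directory in natural filename order."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"frames directory not found: {directory}")
    frames = [p for p in directory.iterdir()
              if p.suffix.lower() in _FRAME_EXTENSIONS and p.is_file()]
    frames.sort(key=lambda p: natural_key(p.name))
    return frames


def read_image(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def detections_to_frame(detections: Sequence[Detection]) -> pd.DataFrame:
    rows = [
        {
            "frame_index": d.frame_index,
            "x_min": d.bbox[0], "y_min": d.bbox[1],
            "width": d.bbox[2], "height": d.bbox[3],
            "cx": d.centroid[0], "cy": d.centroid[1],
            "area": d.area,
        }
        for d in detections
    ]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def write_detections_csv(detections: Sequence[Detection], path) -> None:
    detections_to_frame(detections).to_csv(path, index=False)


def read_detections_csv(path) -> List[Detection]:
    df = pd.read_csv(path)
    return [
        Detection(
            frame_index=int(r.frame_index),
            bbox=(int(r.x_min), int(r.y_min), int(r.width), int(r.height)),
            centroid=(float(r.cx), float(r.cy)),
            area=float(r.area),
        )
        for r in df.itertuples()
    ]


def write_tracks_csv(tracks: Sequence[Track], path,
                     history_path=None) -> None:
    """One row per track; optionally full per-frame history as JSON lines."""
    rows = [
        {
            "track_id": t.track_id,
            "first_frame": t.first_frame,
            "last_frame": t.last_frame,
            "n_detections": len(t.detections),
            "final_label": t.final_label if t.final_label is not None else "",
            "counted": t.counted,
        }
        for t in tracks
    ]
    pd.DataFrame(rows, columns=["track_id", "first_frame", "last_frame",
                                "n_detections", "final_label", "counted"]).to_csv(
        path, index=False)
    if history_path is not None:
        with open(history_path, "w") as fh:
            for t in tracks:
                record = {
                    "track_id": t.track_id,
                    "detections": [
                        {"frame_index": d.frame_index, "bbox": list(d.bbox),
                         "centroid": list(d.centroid), "area": d.area}
                        for d in t.detections
                    ],
                    "label_history": [[lab, conf] for lab, conf in t.label_history],
                }
                fh.write(json.dumps(record) + "\n")


def write_summary(summary: SurveySummary, csv_path=None, json_path=None) -> None:
    """Summary as one-row-per-class CSV and/or a JSON document."""
    if csv_path is not None:
        rows = [{"class": name, "count": n} for name, n in summary.species_counts.items()]
        rows.append({"class": "unknown", "count": summary.unknown_count})
        rows.append({"class": "total", "count": summary.total_individuals})
        pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        doc = {
            "species_counts": summary.species_counts,
            "unknown_count": summary.unknown_count,
            "total_individuals": summary.total_individuals,
            "n_frames": summary.n_frames,
            "start_time": summary.start_time,
            "end_time": summary.end_time,
        }
        with open(json_path, "w") as fh:
            json.dump(doc, fh, indent=2)


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"individual_id", "frame_index", "cx", "cy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth CSV missing columns: {sorted(missing)}")
    return df


def load_config(path) -> Dict:
    """Read a YAML (or JSON) configuration file into a dict."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def annotate_frame(frame: np.ndarray, tracks: Sequence[Track],
                   frame_index: int, thickness: int = 4) -> np.ndarray:
    """Copy of the frame with track bounding boxes burned in."""
    out = np.asarray(frame, dtype=np.uint8).copy()
    color = np.array([255, 0, 0], dtype=np.uint8)
    h, w = out.shape[:2]
    for t in tracks:
        for d in t.detections:
            if d.frame_index != frame_index:
                continue
            x, y, bw, bh = d.bbox
            x0, y0 = max(0, x), max(0, y)
            x1, y1 = min(w, x + bw), min(h, y + bh)
            tt = thickness
            out[y0:min(y0 + tt, y1), x0:x1] = color
            out[max(y1 - tt, y0):y1, x0:x1] = color
            out[y0:y1, x0:min(x0 + tt, x1)] = color
            out[y0:y1, max(x1 - tt, x0):x1] = color
    return out
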