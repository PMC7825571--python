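"""Blob detection and segmentation of insects against a fixed background.

A frame is reduced to a set of :class:`Detection` objects in four steps:
grayscale background subtraction, Otsu binarisation, morphological
open/close cleaning, and connected-component extraction with an area
filter.  An optional motion gate reproduces the trap's capture trigger,
which only stores a frame when enough pixels changed since the previous
one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, footprint_rectangle, opening

__all__ = [
    "Detection",
    "SegmentationConfig",
    "motion_gate",
    "foreground",
    "binarize_otsu",
    "morph_clean",
    "extract_detections",
    "segment_frame",
]

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Detection:
    """One segmented insect in one frame.

    Coordinates are 0-based with the origin at the top-left corner;
    bounding boxes are half-open ``[x_min, x_min + width)``.  ``area`` is
    the blob's pixel count, while the centroid is the bounding-box
    center (the position the tracker matches on).
    """

    frame_index: int
    bbox: tuple[int, int, int, int]  # (x_min, y_min, width, height)
    centroid: tuple[float, float]  # (cx, cy)
    area: float

    def __post_init__(self) -> None:
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError(f"degenerate bbox {self.bbox}")
        if self.area <= 0:
            raise ValueError(f"area must be positive, got {self.area}")
        cx, cy = self.centroid
        if not (x <= cx <= x + w and y <= cy <= y + h):
            raise ValueError(f"centroid {self.centroid} outside bbox {self.bbox}")

    @property
    def bbox_area(self) -> float:
        """Bounding-box area in pixels (enters the tracker's area cost)."""
        return float(self.bbox[2] * self.bbox[3])


@dataclass
class SegmentationConfig:
    """Tunable thresholds of the segmentation stage.

    ``motion_gate_pixels`` defaults to 1500 changed pixels, the trigger
    level of the trap's motion-capture software; ``motion_gate_delta`` is
    the per-pixel grayscale difference that counts as "changed".
    """

    min_blob_area: int = 2500
    open_kernel: int = 5
    close_kernel: int = 7
    motion_gate_pixels: int = 1500
    motion_gate_delta: float = 25.0

    def __post_init__(self) -> None:
        for name in ("min_blob_area", "open_kernel", "close_kernel", "motion_gate_pixels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _as_gray(image: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) or grayscale raster to float grayscale."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] >= 3:
        return arr[..., :3] @ _LUMA
    raise ValueError(f"unsupported raster shape {arr.shape}")


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[:2] != b.shape[:2]:
        raise ValueError(f"frame dimensions differ: {a.shape[:2]} vs {b.shape[:2]}")


def motion_gate(
    current: np.ndarray,
    previous: np.ndarray,
    threshold: int = 1500,
    delta: float = 25.0,
) -> bool:
    """Return True when strictly more than ``threshold`` pixels changed.

    A pixel counts as changed when the absolute grayscale difference
    between the two frames exceeds ``delta``.  Emulates the capture
    trigger that filtered out small insects such as mosquitoes.
    """
    _check_same_shape(np.asarray(current), np.asarray(previous))
    diff = np.abs(_as_gray(current) - _as_gray(previous))
    return int(np.count_nonzero(diff > delta)) > threshold


def foreground(image: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Grayscale foreground: per-pixel absolute difference from the background.

    The absolute value makes the operation symmetric, so insects both
    darker and lighter than the white sheet produce positive response.
    """
    _check_same_shape(np.asarray(image), np.asarray(background))
    return np.abs(_as_gray(image) - _as_gray(background))


def binarize_otsu(gray: np.ndarray) -> np.ndarray:
    """Binarise with the Otsu threshold (maximal between-class variance).

    Foreground is the *above*-threshold side: in a background-subtracted
    image insects are the high-difference pixels.  A constant raster has
    no two classes to separate and yields an all-background output.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty raster")
    if np.ptp(gray) == 0:
        return np.zeros(gray.shape, dtype=bool)
    # keep the input dtype: for 8-bit rasters the histogram is exact
    t = threshold_otsu(gray)
    return gray > t


def morph_clean(binary: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Morphological open (drop small noise) then close (fill gaps).

    Square structuring elements of side ``open_kernel`` / ``close_kernel``;
    a kernel size of 0 or 1 disables that operation.
    """
    config = config or SegmentationConfig()
    out = np.asarray(binary, dtype=bool)
    if config.open_kernel > 1:
        out = opening(out, footprint_rectangle((config.open_kernel,) * 2))
    if config.close_kernel > 1:
        out = closing(out, footprint_rectangle((config.close_kernel,) * 2))
    return out


def extract_detections(
    binary: np.ndarray,
    frame_index: int = 0,
    config: SegmentationConfig | None = None,
) -> List[Detection]:
    """Connected components above ``min_blob_area`` as detections.

    The centroid reported is the bounding-box center.  Detections are
    ordered by (y_min, x_min) for determinism.
    """
    config = config or SegmentationConfig()
    labeled = label(np.asarray(binary, dtype=bool), connectivity=2)
    out: List[Detection] = []
    for region in regionprops(labeled):
        if region.area < config.min_blob_area:
            continue
        y0, x0, y1, x1 = region.bbox
        w, h = x1 - x0, y1 - y0
        out.append(
            Detection(
                frame_index=frame_index,
                bbox=(x0, y0, w, h),
                centroid=(x0 + w / 2.0, y0 + h / 2.0),
                area=float(region.area),
            )
        )
    out.sort(key=lambda d: (d.bbox[1], d.bbox[0]))
    return out


def segment_frame(
    image: np.ndarray,
    background: np.ndarray,
    config: SegmentationConfig | None = None,
    frame_index: int = 0,
) -> List[Detection]:
    """Full segmentation stage: foreground → Otsu → morphology → components."""
    config = config or SegmentationConfig()
    fg = foreground(image, background)
    binary = morph_clean(binarize_otsu(fg), config)
    return extract_detections(binary, frame_index=frame_index, config=config)
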