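"""Lumen localization: the ROI contract between detection and segmentation.

The real system localizes the carotid with an object detector that paints a
blue bounding box on the frame; the segmentation stage then *recovers* that
box from the overlay by color thresholding (blue > 150, red < 100,
green < 100), hole filling, and keeping the largest connected component.
This module reproduces that dataflow with a pluggable detector interface:

* :class:`OracleDetector` derives a perfect detection from a ground-truth
  mask (same padded-box rule used to build training annotations), emulating
  a detector operating at recall 1.0;
* :class:`LabelFileDetector` imports external detections from YOLO-format
  label files;
* :func:`paint_box` / :func:`recover_blue_box` round-trip a box through the
  blue overlay representation.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
from scipy import ndimage
from skimage import measure

from .annotations import PixelBox, mask_to_padded_box, normalized_to_pixel, read_labels
from .errors import DetectionMissingError, EmptyMaskError

__all__ = [
    "Detector",
    "OracleDetector",
    "LabelFileDetector",
    "oracle_detector",
    "paint_box",
    "recover_blue_box",
    "BLUE_MIN",
    "RED_MAX",
    "GREEN_MAX",
]

# Color thresholds defining a "blue box" pixel in an RGB overlay.
BLUE_MIN = 150
RED_MAX = 100
GREEN_MAX = 100


class Detector(Protocol):
    """Callable contract: image -> in-bounds PixelBox."""

    def __call__(self, image: np.ndarray) -> PixelBox: ...


def oracle_detector(mask: np.ndarray, pad_frac: float = 0.1) -> PixelBox:
    """Perfect localization from a ground-truth mask (padded bounding box)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot localize from an empty mask")
    return mask_to_padded_box(mask, pad_frac=pad_frac)


class OracleDetector:
    """Detector backed by a known ground-truth mask."""

    def __init__(self, mask: np.ndarray, pad_frac: float = 0.1):
        self.mask = np.asarray(mask, dtype=bool)
        self.pad_frac = pad_frac

    def __call__(self, image: np.ndarray) -> PixelBox:
        if image.shape[:2] != self.mask.shape:
            raise ValueError("image and oracle mask shapes differ")
        return oracle_detector(self.mask, self.pad_frac)


class LabelFileDetector:
    """Detector that reads a precomputed detection from a YOLO label file.

    If the file holds several boxes the largest (by normalized area) is used.
    """

    def __init__(self, path):
        self.path = path

    def __call__(self, image: np.ndarray) -> PixelBox:
        boxes = read_labels(self.path)
        if not boxes:
            raise DetectionMissingError(f"no boxes in {self.path}")
        best = max(boxes, key=lambda b: b.w * b.h)
        h, w = image.shape[:2]
        return normalized_to_pixel(best, w, h)


def paint_box(
    image: np.ndarray, box: PixelBox, thickness: int = 3
) -> np.ndarray:
    """Render a grayscale image as RGB with a pure-blue box outline.

    The outline is drawn just inside the box rectangle, ``thickness`` pixels
    wide; every non-outline pixel replicates the original gray value.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("paint_box expects a single-channel image")
    h, w = image.shape
    if box.left < 0 or box.top < 0 or box.right > w or box.bottom > h:
        raise ValueError("box extends outside the image")
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    overlay = np.repeat(image[:, :, None], 3, axis=2).astype(np.uint8)
    outline = box.to_mask((h, w))
    t = min(thickness, box.width // 2, box.height // 2)
    if t >= 1:
        inner = PixelBox(
            box.left + t, box.top + t, box.width - 2 * t, box.height - 2 * t
        ) if (box.width > 2 * t and box.height > 2 * t) else None
        if inner is not None:
            outline[inner.slices()] = False
    overlay[outline] = (0, 0, 255)
    return overlay


def recover_blue_box(overlay: np.ndarray) -> PixelBox:
    """Recover the painted detection box from an RGB overlay.

    Thresholds the channels (B > 150, R < 100, G < 100), fills holes, keeps
    the largest 8-connected component (ties broken topmost-then-leftmost by
    bounding box), and returns that component's bounding rectangle.  The
    result depends only on the painted overlay, never on the underlying
    grayscale content, because gray-replicated pixels have R = G = B and
    cannot pass the thresholds.
    """
    overlay = np.asarray(overlay)
    if overlay.ndim != 3 or overlay.shape[2] != 3:
        raise ValueError("overlay must be an RGB raster")
    r = overlay[:, :, 0].astype(np.int32)
    g = overlay[:, :, 1].astype(np.int32)
    b = overlay[:, :, 2].astype(np.int32)
    blue = (b > BLUE_MIN) & (r < RED_MAX) & (g < GREEN_MAX)
    if not blue.any():
        raise DetectionMissingError("no pixel passes the blue-box thresholds")
    solid = ndimage.binary_fill_holes(blue)
    labels = measure.label(solid, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best_size = counts.max()
    candidates = np.flatnonzero(counts == best_size)
    best_box: PixelBox | None = None
    for lab in candidates:
        rows = np.flatnonzero((labels == lab).any(axis=1))
        cols = np.flatnonzero((labels == lab).any(axis=0))
        box = PixelBox(
            int(cols[0]), int(rows[0]), int(cols[-1]) - int(cols[0]) + 1,
            int(rows[-1]) - int(rows[0]) + 1,
        )
        if best_box is None or (box.top, box.left) < (best_box.top, best_box.left):
            best_box = box
    assert best_box is not None
    return best_box
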