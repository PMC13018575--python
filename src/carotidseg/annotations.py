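"""Bounding-box annotations: masks to padded boxes, YOLO label files, splits.

Coordinate convention used everywhere in this package: 0-based pixel indices,
x rightward (columns), y downward (rows).  A :class:`PixelBox` is half-open:
it covers columns ``left .. left+width-1`` and rows ``top .. top+height-1``,
i.e. the continuous rectangle ``[left, left+width) x [top, top+height)``.
Normalized (YOLO-style) boxes store the box center and size as fractions of
the image width/height.

The mask-to-annotation chain mirrors the standard recipe for deriving
detector training labels from expert lumen masks: take the tight bounding
extremes of the foreground, pad by 10% of the box extent on each side (so the
full lumen contour sits strictly inside the box), clip to the image, then
normalize center/size by the image dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMaskError, InvalidPartitionError, LabelParseError

__all__ = [
    "PixelBox",
    "NormalizedBox",
    "DatasetSplit",
    "mask_to_padded_box",
    "pixel_to_normalized",
    "normalized_to_pixel",
    "read_labels",
    "write_labels",
    "partition_dataset",
]


def _round_half_up(v: float) -> int:
    """Round a non-negative value to the nearest integer, ties away from zero."""
    return int(math.floor(v + 0.5))


@dataclass(frozen=True)
class PixelBox:
    """Axis-aligned rectangle in pixel coordinates, half-open on the right/bottom."""

    left: int
    top: int
    width: int
    height: int

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError(f"degenerate box: width={self.width}, height={self.height}")

    @property
    def right(self) -> int:
        return self.left + self.width

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) center of the continuous rectangle."""
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    @property
    def area(self) -> int:
        return self.width * self.height

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices selecting the box in a numpy image."""
        return slice(self.top, self.bottom), slice(self.left, self.right)

    def clipped(self, image_width: int, image_height: int) -> "PixelBox":
        """Intersect with the image rectangle [0, W) x [0, H)."""
        left = max(0, self.left)
        top = max(0, self.top)
        right = min(image_width, self.right)
        bottom = min(image_height, self.bottom)
        if right <= left or bottom <= top:
            raise ValueError("box does not intersect the image")
        return PixelBox(left, top, right - left, bottom - top)

    def contains_box(self, other: "PixelBox") -> bool:
        return (
            self.left <= other.left
            and self.top <= other.top
            and self.right >= other.right
            and self.bottom >= other.bottom
        )

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rectangle-support boolean mask of the given (H, W) shape."""
        m = np.zeros(shape, dtype=bool)
        m[self.slices()] = True
        return m


@dataclass(frozen=True)
class NormalizedBox:
    """YOLO-style box: class id plus center/size as fractions of the image."""

    class_id: int
    xc: float
    yc: float
    w: float
    h: float

    def __post_init__(self):
        for name in ("xc", "yc", "w", "h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("normalized box must have positive extent")


def mask_to_padded_box(mask: np.ndarray, pad_frac: float = 0.1) -> PixelBox:
    """Tight bounding box of a binary mask, padded by ``pad_frac`` per side.

    The padding is ``round(pad_frac * extent)`` pixels on each side in each
    axis, then the box is clipped to the image bounds.  Padding never shrinks
    the tight box.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    height, width = mask.shape
    xmin, xmax = int(cols[0]), int(cols[-1]) + 1
    ymin, ymax = int(rows[0]), int(rows[-1]) + 1
    pad_x = _round_half_up(pad_frac * (xmax - xmin))
    pad_y = _round_half_up(pad_frac * (ymax - ymin))
    left = max(0, xmin - pad_x)
    top = max(0, ymin - pad_y)
    right = min(width, xmax + pad_x)
    bottom = min(height, ymax + pad_y)
    return PixelBox(left, top, right - left, bottom - top)


def pixel_to_normalized(
    box: PixelBox, image_width: int, image_height: int, class_id: int = 0
) -> NormalizedBox:
    """Convert a pixel box to normalized center/size fractions."""
    if image_width <= 0 or image_height <= 0:
        raise ValueError(f"invalid image dimensions {image_width}x{image_height}")
    if box.left < 0 or box.top < 0 or box.right > image_width or box.bottom > image_height:
        raise ValueError("box extends outside the image")
    return NormalizedBox(
        class_id=class_id,
        xc=(box.left + box.right) / (2.0 * image_width),
        yc=(box.top + box.bottom) / (2.0 * image_height),
        w=box.width / image_width,
        h=box.height / image_height,
    )


def normalized_to_pixel(
    nbox: NormalizedBox, image_width: int, image_height: int
) -> PixelBox:
    """Invert :func:`pixel_to_normalized` up to edge rounding."""
    if image_width <= 0 or image_height <= 0:
        raise ValueError(f"invalid image dimensions {image_width}x{image_height}")
    left = _round_half_up((nbox.xc - nbox.w / 2.0) * image_width)
    right = _round_half_up((nbox.xc + nbox.w / 2.0) * image_width)
    top = _round_half_up((nbox.yc - nbox.h / 2.0) * image_height)
    bottom = _round_half_up((nbox.yc + nbox.h / 2.0) * image_height)
    right = max(right, left + 1)
    bottom = max(bottom, top + 1)
    return PixelBox(left, top, right - left, bottom - top).clipped(
        image_width, image_height
    )


def write_labels(boxes: list[NormalizedBox], path) -> None:
    """Write one YOLO-format line per box: ``class xc yc w h``, 6 decimals."""
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{b.class_id} {b.xc:.6f} {b.yc:.6f} {b.w:.6f} {b.h:.6f}\n")


def read_labels(path) -> list[NormalizedBox]:
    """Read a YOLO-format label file; raises :class:`LabelParseError` with the
    offending line number on malformed or out-of-range input."""
    boxes: list[NormalizedBox] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise LabelParseError(
                    f"expected 5 whitespace-separated fields, got {len(parts)}", lineno
                )
            try:
                class_id = int(parts[0])
                vals = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise LabelParseError(str(exc), lineno) from exc
            try:
                boxes.append(NormalizedBox(class_id, *vals))
            except ValueError as exc:
                raise LabelParseError(str(exc), lineno) from exc
    return boxes


@dataclass(frozen=True)
class DatasetSplit:
    """A holdout/development partition with k cross-validation folds.

    ``development`` and ``holdout`` are sorted index arrays partitioning
    ``range(n)``; ``folds`` partitions ``development`` into k near-equal
    sorted index arrays.
    """

    n: int
    development: np.ndarray
    holdout: np.ndarray
    folds: tuple[np.ndarray, ...] = field(default=())

    def __post_init__(self):
        all_idx = np.concatenate([self.development, self.holdout])
        if not np.array_equal(np.sort(all_idx), np.arange(self.n)):
            raise ValueError("development and holdout must partition range(n)")
        if self.folds:
            fold_all = np.concatenate(self.folds)
            if not np.array_equal(np.sort(fold_all), self.development):
                raise ValueError("folds must partition the development set")
            sizes = [len(f) for f in self.folds]
            if max(sizes) - min(sizes) > 1:
                raise ValueError("fold sizes must differ by at most 1")

    def to_frame(self, names: list[str] | None = None):
        """Manifest as a DataFrame with columns (item, role, fold)."""
        import pandas as pd

        if names is None:
            names = [str(i) for i in range(self.n)]
        fold_of = {int(i): f for f, idx in enumerate(self.folds) for i in idx}
        rows = []
        for i in range(self.n):
            if i in fold_of:
                rows.append((names[i], "development", fold_of[i]))
            else:
                rows.append((names[i], "holdout", -1))
        return pd.DataFrame(rows, columns=["item", "role", "fold"])


def partition_dataset(
    n: int, holdout_frac: float = 0.1, k: int = 5, seed: int = 0
) -> DatasetSplit:
    """Split ``n`` items into a holdout set and k cross-validation folds.

    The holdout count is ``round(holdout_frac * n)`` with ties rounded away
    from zero (1100 -> 110 held out, 84 -> 8); the remaining development pool
    is divided into k folds whose sizes differ by at most one.  Deterministic
    for a fixed seed.
    """
    if n < k + 1:
        raise InvalidPartitionError(f"need at least k+1={k + 1} items, got {n}")
    n_hold = _round_half_up(holdout_frac * n)
    n_dev = n - n_hold
    if n_dev < k:
        raise InvalidPartitionError(
            f"development pool of {n_dev} cannot form {k} folds"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    holdout = np.sort(perm[:n_hold])
    dev_shuffled = perm[n_hold:]
    folds = tuple(np.sort(f) for f in np.array_split(dev_shuffled, k))
    return DatasetSplit(
        n=n, development=np.sort(dev_shuffled), holdout=holdout, folds=folds
    )
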