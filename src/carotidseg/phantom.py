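"""Synthetic B-mode-like vascular phantoms with exact ground truth.

A phantom emulates the gross appearance of a carotid ultrasound frame: a
dark, near-homogeneous lumen (blood reflects almost no ultrasound) embedded
in a brighter speckled tissue background, with a bright vessel-wall rim
around the lumen.  Transverse sections show an elliptical lumen; longitudinal
sections show a horizontal dark band.  An optional second dark region (the
"decoy") stands in for the jugular vein, which sits next to the carotid and
shares the lumen's low echogenicity - the classic confound for region-based
segmentation.

Speckle is modeled as fully developed multiplicative noise: the clean
piecewise-constant intensity map is multiplied by unit-mean gamma noise with
shape ``speckle_looks`` (larger = smoother), then clipped to [0, 255].  The
ground-truth mask is the exact rasterization of the analytic lumen geometry
(a pixel belongs to the lumen iff its index coordinate satisfies the region
test), so every downstream stage can be scored against a known answer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from typing import Union

import numpy as np

from .errors import InvalidSpecError

__all__ = [
    "Ellipse",
    "Band",
    "Decoy",
    "PhantomSpec",
    "make_phantom",
    "region_masks",
    "default_transverse_spec",
    "default_longitudinal_spec",
]


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (cx, cy) and semi-axes (a, b) in pixels."""

    cx: float
    cy: float
    a: float
    b: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return ((x - self.cx) / self.a) ** 2 + ((y - self.cy) / self.b) ** 2 <= 1.0

    def grown(self, margin: float) -> "Ellipse":
        return Ellipse(self.cx, self.cy, self.a + margin, self.b + margin)

    def bounds(self) -> tuple[float, float, float, float]:
        return (self.cx - self.a, self.cy - self.b, self.cx + self.a, self.cy + self.b)


@dataclass(frozen=True)
class Band:
    """Horizontal band of rows [top, bottom), spanning the full image width."""

    top: int
    bottom: int

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (y >= self.top) & (y < self.bottom)

    def grown(self, margin: float) -> "Band":
        m = int(round(margin))
        return Band(self.top - m, self.bottom + m)

    def bounds(self) -> tuple[float, float, float, float]:
        return (-math.inf, self.top, math.inf, self.bottom)


Geometry = Union[Ellipse, Band]


@dataclass(frozen=True)
class Decoy:
    """A second dark region emulating the jugular vein."""

    geometry: Geometry
    mean: float = 25.0


@dataclass(frozen=True)
class PhantomSpec:
    width: int
    height: int
    section: str  # "transverse" | "longitudinal"
    lumen_geometry: Geometry
    lumen_mean: float = 25.0
    tissue_mean: float = 120.0
    wall_intensity: float = 190.0
    wall_thickness: float = 4.0
    speckle_looks: float = 4.0
    decoy: Decoy | None = None
    seed: int = 0

    def __post_init__(self):
        if self.section not in ("transverse", "longitudinal"):
            raise InvalidSpecError(f"unknown section {self.section!r}")
        if self.speckle_looks <= 0:
            raise InvalidSpecError("speckle_looks must be positive")
        _check_in_bounds(self.lumen_geometry.grown(self.wall_thickness), self)
        if self.decoy is not None:
            _check_in_bounds(self.decoy.geometry.grown(self.wall_thickness), self)

    def to_json(self) -> str:
        d = asdict(self)
        d["lumen_geometry_kind"] = type(self.lumen_geometry).__name__
        return json.dumps(d, indent=2, default=float)


def _check_in_bounds(geom: Geometry, spec: PhantomSpec) -> None:
    x0, y0, x1, y1 = geom.bounds()
    if y0 < 0 or y1 > spec.height:
        raise InvalidSpecError("geometry (with wall rim) extends outside image rows")
    if isinstance(geom, Ellipse) and (x0 < 0 or x1 > spec.width):
        raise InvalidSpecError("geometry (with wall rim) extends outside image columns")


def _grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0 : spec.height, 0 : spec.width]
    return x, y


def region_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Exact rasterized region masks: lumen, wall, decoy, decoy_wall, tissue."""
    x, y = _grid(spec)
    lumen = spec.lumen_geometry.contains(x, y)
    wall = spec.lumen_geometry.grown(spec.wall_thickness).contains(x, y) & ~lumen
    if spec.decoy is not None:
        decoy = spec.decoy.geometry.contains(x, y)
        decoy_wall = (
            spec.decoy.geometry.grown(spec.wall_thickness).contains(x, y) & ~decoy
        )
        if (lumen & decoy).any() or (wall & decoy).any() or (lumen & decoy_wall).any():
            raise InvalidSpecError("lumen and decoy regions overlap")
    else:
        decoy = np.zeros_like(lumen)
        decoy_wall = np.zeros_like(lumen)
    tissue = ~(lumen | wall | decoy | decoy_wall)
    return {
        "lumen": lumen,
        "wall": wall,
        "decoy": decoy,
        "decoy_wall": decoy_wall,
        "tissue": tissue,
    }


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom.

    Returns ``(image, lumen_mask)``: an 8-bit grayscale image and the exact
    boolean ground-truth lumen mask.  Identical specs (including seed) yield
    bit-identical output.
    """
    masks = region_masks(spec)
    clean = np.full((spec.height, spec.width), spec.tissue_mean, dtype=np.float64)
    clean[masks["wall"]] = spec.wall_intensity
    clean[masks["lumen"]] = spec.lumen_mean
    if spec.decoy is not None:
        clean[masks["decoy_wall"]] = spec.wall_intensity
        clean[masks["decoy"]] = spec.decoy.mean

    if math.isfinite(spec.speckle_looks):
        rng = np.random.default_rng(spec.seed)
        looks = float(spec.speckle_looks)
        speckle = rng.gamma(shape=looks, scale=1.0 / looks, size=clean.shape)
        img = clean * speckle
    else:
        img = clean
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, masks["lumen"]


def default_transverse_spec(seed: int = 0, decoy: bool = False) -> PhantomSpec:
    """Study-condition transverse phantom: 176x176, elliptical lumen, optional
    jugular-like decoy ellipse beside it."""
    d = Decoy(Ellipse(cx=46.0, cy=58.0, a=15.0, b=12.0)) if decoy else None
    return PhantomSpec(
        width=176,
        height=176,
        section="transverse",
        lumen_geometry=Ellipse(cx=102.0, cy=92.0, a=30.0, b=25.0),
        decoy=d,
        seed=seed,
    )


def default_longitudinal_spec(seed: int = 0, decoy: bool = True) -> PhantomSpec:
    """Study-condition longitudinal phantom: 224x160, carotid band rows
    [84, 128), with a thinner jugular-like decoy band above it by default."""
    d = Decoy(Band(top=48, bottom=68)) if decoy else None
    return PhantomSpec(
        width=224,
        height=160,
        section="longitudinal",
        lumen_geometry=Band(top=84, bottom=128),
        decoy=d,
        seed=seed,
    )
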