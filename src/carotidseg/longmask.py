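"""Automated longitudinal initialization-mask generator.

The longitudinal detection box typically contains more than the carotid
lumen - surrounding tissue and often the jugular vein, which is just as dark
as the carotid (both are blood).  Initializing Chan-Vese from the raw box
therefore risks capturing the wrong vessel.  This generator turns the box
into a reliable seed mask in four steps:

1. reduce the box to 60% of its size about its own center (pushes the
   search away from box-edge structures such as the jugular);
2. slide a 30 x 30 px window in steps of 5 px over the reduced region,
   computing each window's mean intensity mu and standard deviation sigma;
   windows with mu < 60 and sigma < 15 are candidates (dark *and*
   homogeneous - blood, not speckled tissue);
3. select the candidate minimizing the score mu + sigma (ties: topmost then
   leftmost);
4. expand the winner: quadruple its width, keep its height and vertical
   position, re-center it horizontally on the detection box, clip to the
   image, and re-validate mu/sigma on the expanded window - reverting to
   the unexpanded winner if the check fails.

If no window passes the thresholds the generator falls back to the globally
minimal-score window and flags the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import PixelBox
from .errors import InvalidRegionError

__all__ = [
    "MaskGenConfig",
    "WindowStats",
    "MaskGenResult",
    "reduce_center_box",
    "scan_windows",
    "select_best",
    "expand_and_validate",
    "generate_longitudinal_mask",
]


@dataclass(frozen=True)
class MaskGenConfig:
    reduce_factor: float = 0.6
    win: int = 30
    step: int = 5
    mu_threshold: float = 60.0
    sigma_threshold: float = 15.0
    expand_factor: int = 4  # applied to width only

    def __post_init__(self):
        if not (0.0 < self.reduce_factor <= 1.0):
            raise ValueError("reduce_factor must lie in (0, 1]")
        if self.win < 1 or self.step < 1:
            raise ValueError("win and step must be >= 1")
        if self.mu_threshold <= 0 or self.sigma_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.expand_factor < 1:
            raise ValueError("expand_factor must be >= 1")


@dataclass(frozen=True)
class WindowStats:
    """A scanning window with its intensity moments; score = mu + sigma."""

    window: PixelBox
    mu: float
    sigma: float
    is_candidate: bool = False

    @property
    def score(self) -> float:
        return self.mu + self.sigma


def _window_moments(img: np.ndarray, box: PixelBox) -> tuple[float, float]:
    patch = img[box.slices()].astype(np.float64)
    return float(patch.mean()), float(patch.std())


def reduce_center_box(
    box: PixelBox,
    factor: float = 0.6,
    image_shape: tuple[int, int] | None = None,
    min_size: int = 1,
) -> PixelBox:
    """Scale a box about its center by ``factor`` (rounded, clipped)."""
    if not (0.0 < factor <= 1.0):
        raise ValueError("factor must lie in (0, 1]")
    cx, cy = box.center
    new_w = max(1, int(round(box.width * factor)))
    new_h = max(1, int(round(box.height * factor)))
    left = int(round(cx - new_w / 2.0))
    top = int(round(cy - new_h / 2.0))
    out = PixelBox(left, top, new_w, new_h)
    if image_shape is not None:
        out = out.clipped(image_shape[1], image_shape[0])
    if out.width < min_size or out.height < min_size:
        raise InvalidRegionError(
            f"reduced region {out.width}x{out.height} smaller than {min_size}"
        )
    return out


def scan_windows(
    img: np.ndarray, region: PixelBox, cfg: MaskGenConfig | None = None
) -> list[WindowStats]:
    """All win x win windows at step offsets inside the region.

    Offsets run in steps of ``cfg.step`` from the region's top-left; a final
    offset flush with the far edge is appended when the stride does not land
    there exactly, so the region is always fully covered.
    """
    if cfg is None:
        cfg = MaskGenConfig()
    img = np.asarray(img)
    if region.width < cfg.win or region.height < cfg.win:
        raise InvalidRegionError(
            f"region {region.width}x{region.height} smaller than the "
            f"{cfg.win}px scanning window"
        )

    def offsets(start: int, extent: int) -> list[int]:
        last = start + extent - cfg.win
        offs = list(range(start, last + 1, cfg.step))
        if offs[-1] != last:
            offs.append(last)
        return offs

    out: list[WindowStats] = []
    for top in offsets(region.top, region.height):
        for left in offsets(region.left, region.width):
            win = PixelBox(left, top, cfg.win, cfg.win)
            mu, sigma = _window_moments(img, win)
            out.append(
                WindowStats(
                    window=win,
                    mu=mu,
                    sigma=sigma,
                    is_candidate=bool(
                        mu < cfg.mu_threshold and sigma < cfg.sigma_threshold
                    ),
                )
            )
    return out


def select_best(candidates: list[WindowStats]) -> WindowStats:
    """Minimal-score window; ties broken topmost then leftmost."""
    if not candidates:
        raise InvalidRegionError("no candidate windows to select from")
    return min(
        candidates, key=lambda ws: (ws.score, ws.window.top, ws.window.left)
    )


def expand_and_validate(
    img: np.ndarray,
    best: WindowStats,
    roi_box: PixelBox,
    cfg: MaskGenConfig | None = None,
) -> tuple[PixelBox, bool]:
    """Widen the best window and validate the result.

    The candidate keeps the best window's height and vertical position, has
    ``expand_factor`` times its width, is horizontally re-centered on the
    detection box, and is clipped to the image.  If the candidate still
    satisfies the mu/sigma thresholds it is returned with ``True``;
    otherwise the original best window is returned with ``False``.
    """
    if cfg is None:
        cfg = MaskGenConfig()
    img = np.asarray(img)
    h, w = img.shape[:2]
    new_w = cfg.expand_factor * best.window.width
    roi_cx = roi_box.center[0]
    left = int(round(roi_cx - new_w / 2.0))
    cand = PixelBox(left, best.window.top, new_w, best.window.height).clipped(w, h)
    mu, sigma = _window_moments(img, cand)
    if mu < cfg.mu_threshold and sigma < cfg.sigma_threshold:
        return cand, True
    return best.window, False


@dataclass
class MaskGenResult:
    mask: np.ndarray
    window: PixelBox
    best: WindowStats
    expanded: bool
    fallback: bool
    n_candidates: int

    def diagnostics(self) -> dict:
        return {
            "window": [self.window.left, self.window.top,
                       self.window.width, self.window.height],
            "score": self.best.score,
            "mu": self.best.mu,
            "sigma": self.best.sigma,
            "expanded": self.expanded,
            "fallback": self.fallback,
            "n_candidates": self.n_candidates,
        }


def generate_longitudinal_mask(
    img: np.ndarray, roi_box: PixelBox, cfg: MaskGenConfig | None = None
) -> MaskGenResult:
    """Full chain: reduce -> scan -> select -> expand/validate -> rectangle mask.

    When the scan produces no candidate the globally minimal-score window is
    used instead and the result is flagged as a fallback.
    """
    if cfg is None:
        cfg = MaskGenConfig()
    img = np.asarray(img)
    h, w = img.shape[:2]
    region = reduce_center_box(
        roi_box, cfg.reduce_factor, image_shape=(h, w), min_size=cfg.win
    )
    stats = scan_windows(img, region, cfg)
    candidates = [s for s in stats if s.is_candidate]
    fallback = not candidates
    best = select_best(candidates if candidates else stats)
    window, expanded = expand_and_validate(img, best, roi_box, cfg)
    return MaskGenResult(
        mask=window.to_mask((h, w)),
        window=window,
        best=best,
        expanded=expanded,
        fallback=fallback,
        n_candidates=len(candidates),
    )
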