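"""Parametric active contour (snake) for the transverse lumen.

A closed contour C(s), discretized as n points with unit parameter spacing,
evolves to minimize

    E = sum_i [ (alpha/2) |C_s|^2 + (beta/2) |C_ss|^2 - gamma |grad I(C_i)|^2 ]

i.e. tension + rigidity internal energy plus an edge-attraction external
energy: the negated, smoothed, squared gradient magnitude of the image
(normalized to [0, 1] so that gamma has a scale-free meaning).  The internal
terms are advanced semi-implicitly through the standard cyclic pentadiagonal
system (stable at practical step sizes); the external force is an explicit
step along the negative gradient of the edge energy, interpolated bilinearly
at the subpixel contour points.  A backtracking safeguard halves the step
whenever a move would raise the discrete energy, so the energy trace is
non-increasing across accepted iterations; if no reduction is possible the
evolution stops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .annotations import PixelBox

__all__ = [
    "SnakeParams",
    "EdgeMap",
    "SnakeResult",
    "box_to_initial_contour",
    "edge_map",
    "snake_energy",
    "evolve_snake",
    "contour_to_mask",
]


@dataclass(frozen=True)
class SnakeParams:
    """Snake weights and optimizer settings.

    alpha: tension (first-derivative) weight; beta: rigidity
    (second-derivative) weight; gamma: edge-attraction weight on the
    normalized edge map; tol: mean point displacement (px) below which the
    contour is considered converged.
    """

    alpha: float = 1.5
    beta: float = 0.3
    gamma: float = 2.0
    n_points: int = 120
    step: float = 0.5
    max_iters: int = 500
    tol: float = 0.05
    edge_sigma: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("snake weights must be non-negative")
        if self.n_points < 8:
            raise ValueError("need at least 8 contour points")
        if self.step <= 0 or self.tol <= 0:
            raise ValueError("step and tol must be positive")


@dataclass(frozen=True)
class EdgeMap:
    """External energy raster and its force field.

    ``energy`` is -|grad(G_sigma * I)|^2 normalized to [-1, 0]; ``fx, fy``
    are the components of the negative energy gradient (the force pulling
    contour points toward strong edges).
    """

    energy: np.ndarray
    fx: np.ndarray
    fy: np.ndarray


def edge_map(img: np.ndarray, sigma: float = 2.0) -> EdgeMap:
    """Edge-attraction energy: smoothed squared gradient magnitude, negated."""
    f = np.asarray(img, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("edge_map expects a grayscale image")
    gx = ndimage.gaussian_filter(f, sigma, order=(0, 1), mode="reflect")
    gy = ndimage.gaussian_filter(f, sigma, order=(1, 0), mode="reflect")
    mag2 = gx * gx + gy * gy
    peak = mag2.max()
    if peak > 0:
        mag2 = mag2 / peak
    energy = -mag2
    fy, fx = np.gradient(energy)
    return EdgeMap(energy=energy, fx=-fx, fy=-fy)


def box_to_initial_contour(box: PixelBox, n_points: int = 120) -> np.ndarray:
    """Sample n points uniformly by arc length along the box perimeter,
    clockwise from the top-left corner.  Returns an (n, 2) array of (x, y)."""
    if n_points < 8:
        raise ValueError("need at least 8 contour points")
    l, t = float(box.left), float(box.top)
    r, b = float(box.left + box.width), float(box.top + box.height)
    w, h = r - l, b - t
    per = 2.0 * (w + h)
    s = np.arange(n_points, dtype=np.float64) * per / n_points
    pts = np.empty((n_points, 2), dtype=np.float64)
    for i, si in enumerate(s):
        if si < w:  # top edge, left -> right
            pts[i] = (l + si, t)
        elif si < w + h:  # right edge, top -> bottom
            pts[i] = (r, t + (si - w))
        elif si < 2 * w + h:  # bottom edge, right -> left
            pts[i] = (r - (si - w - h), b)
        else:  # left edge, bottom -> top
            pts[i] = (l, b - (si - 2 * w - h))
    return pts


def _internal_matrix(n: int, alpha: float, beta: float) -> np.ndarray:
    """Cyclic pentadiagonal stiffness matrix of the internal energy."""
    A = np.zeros((n, n))
    idx = np.arange(n)
    A[idx, idx] = 2.0 * alpha + 6.0 * beta
    A[idx, (idx + 1) % n] = -alpha - 4.0 * beta
    A[idx, (idx - 1) % n] = -alpha - 4.0 * beta
    A[idx, (idx + 2) % n] = beta
    A[idx, (idx - 2) % n] = beta
    return A


def snake_energy(pts: np.ndarray, emap: EdgeMap, params: SnakeParams) -> float:
    """Discrete snake energy at the given contour points."""
    d1 = np.roll(pts, -1, axis=0) - pts
    d2 = np.roll(pts, -1, axis=0) - 2.0 * pts + np.roll(pts, 1, axis=0)
    internal = 0.5 * params.alpha * (d1**2).sum() + 0.5 * params.beta * (d2**2).sum()
    ext = _interp(emap.energy, pts).sum()
    return float(internal + params.gamma * ext)


def _interp(raster: np.ndarray, pts: np.ndarray) -> np.ndarray:
    # map_coordinates expects (row, col) = (y, x)
    return ndimage.map_coordinates(
        raster, [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
    )


@dataclass
class SnakeResult:
    contour: np.ndarray
    energies: list[float]
    n_iters: int
    converged: bool
    clamped: bool = False


def evolve_snake(
    img: np.ndarray,
    contour: np.ndarray,
    params: SnakeParams | None = None,
    emap: EdgeMap | None = None,
) -> SnakeResult:
    """Evolve a closed contour on an image (expected: the enhanced image).

    Returns the final contour together with the per-iteration discrete
    energy trace.  Points that would leave the image are clamped to its
    bounds and the result flagged.
    """
    if params is None:
        params = SnakeParams()
    img = np.asarray(img)
    if emap is None:
        emap = edge_map(img, params.edge_sigma)
    h, w = emap.energy.shape
    pts = np.array(contour, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
        raise ValueError("contour must be an (n>=8, 2) array of (x, y) points")
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > h - 1):
        raise ValueError("initial contour must lie inside the image")
    n = pts.shape[0]
    A = _internal_matrix(n, params.alpha, params.beta)
    solvers: dict[float, np.ndarray] = {}

    def solver(tau: float) -> np.ndarray:
        if tau not in solvers:
            solvers[tau] = np.linalg.inv(np.eye(n) + tau * A)
        return solvers[tau]

    clamped = False
    energies = [snake_energy(pts, emap, params)]
    converged = False
    it = 0
    for it in range(1, params.max_iters + 1):
        fx = params.gamma * _interp(emap.fx, pts)
        fy = params.gamma * _interp(emap.fy, pts)
        force = np.column_stack([fx, fy])
        tau = params.step
        accepted = False
        for _ in range(8):
            cand = solver(tau) @ (pts + tau * force)
            lo_ok = cand[:, 0].min() >= 0 and cand[:, 1].min() >= 0
            hi_ok = cand[:, 0].max() <= w - 1 and cand[:, 1].max() <= h - 1
            if not (lo_ok and hi_ok):
                cand[:, 0] = np.clip(cand[:, 0], 0, w - 1)
                cand[:, 1] = np.clip(cand[:, 1], 0, h - 1)
                clamped = True
            e = snake_energy(cand, emap, params)
            if e <= energies[-1] + 1e-9:
                accepted = True
                break
            tau /= 2.0
        if not accepted:
            converged = True
            break
        disp = float(np.mean(np.hypot(*(cand - pts).T)))
        pts = cand
        energies.append(e)
        if disp < params.tol:
            converged = True
            break
    return SnakeResult(
        contour=pts, energies=energies, n_iters=it, converged=converged,
        clamped=clamped,
    )


def contour_to_mask(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed contour: a pixel is foreground iff its center is
    inside the polygon by the even-odd (crossing-number) rule.

    Self-intersecting contours are filled by the same rule (and are the
    reason the rule is even-odd); degenerate zero-area contours yield an
    empty mask with a warning.
    """
    pts = np.asarray(contour, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("contour must be an (n>=3, 2) array")
    h, w = shape
    x1 = pts[:, 0]
    y1 = pts[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    area2 = float(np.abs(np.sum(x1 * y2 - x2 * y1)))
    if area2 < 1e-9:
        warnings.warn("degenerate (zero-area) contour; returning empty mask")
        return np.zeros(shape, dtype=bool)
    yg = np.arange(h, dtype=np.float64)[:, None, None]
    xg = np.arange(w, dtype=np.float64)[None, :, None]
    y1b = y1[None, None, :]
    y2b = y2[None, None, :]
    x1b = x1[None, None, :]
    x2b = x2[None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        crosses = (y1b > yg) != (y2b > yg)
        xint = x1b + (yg - y1b) * (x2b - x1b) / (y2b - y1b)
        hits = crosses & (xg < xint)
    return (hits.sum(axis=2) % 2).astype(bool)
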