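"""Chan-Vese active contour without edges, via level-set evolution.

The segmentation minimizes the two-phase piecewise-constant energy

    F(c1, c2, C) = mu * Length(C) + nu * Area(inside C)
                   + lambda1 * int_inside  (U0 - c1)^2
                   + lambda2 * int_outside (U0 - c2)^2

over contours C (the zero level of a level-set function V, positive inside)
and region means c1 (inside) / c2 (outside).  At fixed V the optimal c1, c2
are the Heaviside-weighted region means; at fixed c1, c2 the level set is
advanced along the Euler-Lagrange flow

    dV/dt = delta_eps(V) [ mu * div(grad V / |grad V|) - nu
                           - lambda1 (U0 - c1)^2 + lambda2 (U0 - c2)^2 ]

with the smoothed Heaviside S_eps(t) = 1/2 (1 + (2/pi) arctan(t/eps)) and
its derivative delta_eps.  Intensities are normalized to [0, 1] internally,
so mu, nu, lambda1, lambda2 are all on order-1 scales.  V is periodically
reinitialized to a signed distance function, and a backtracking step control
halves dt whenever a step would raise the energy, keeping the recorded
energy trace non-increasing.  Non-finite values abort with
:class:`~carotidseg.errors.NumericalInstabilityError` - the "failed" outcome
of an unstable configuration rather than a silent wrong answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, NumericalInstabilityError

__all__ = [
    "ChanVeseParams",
    "ChanVeseResult",
    "init_levelset",
    "heaviside",
    "delta",
    "region_means",
    "chanvese_energy",
    "evolve",
    "segment",
]


@dataclass(frozen=True)
class ChanVeseParams:
    """Chan-Vese weights and solver settings (intensities on the [0, 1] scale).

    mu: contour-length weight; nu: area weight; lambda1/lambda2: inside /
    outside fidelity weights; eps: Heaviside smoothing width (level-set
    units, i.e. pixels after reinitialization); dt: time step; tol: fraction
    of sign-changed pixels below which evolution is considered converged;
    reinit_every: iterations between signed-distance reinitializations.
    """

    mu: float = 0.2
    nu: float = 0.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    eps: float = 1.0
    dt: float = 200.0
    max_iters: int = 800
    tol: float = 2e-5
    reinit_every: int = 10

    def __post_init__(self):
        if self.mu < 0 or self.nu < 0:
            raise ValueError("mu and nu must be non-negative")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda1 and lambda2 must be positive")
        if self.eps <= 0 or self.dt <= 0 or self.tol <= 0:
            raise ValueError("eps, dt and tol must be positive")


def _sdf(mask: np.ndarray) -> np.ndarray:
    """Signed distance to the mask boundary, positive inside."""
    mask = np.asarray(mask, dtype=bool)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def init_levelset(mask: np.ndarray) -> np.ndarray:
    """Signed-distance level set from a binary initialization mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise EmptyMaskError("cannot initialize a level set from an empty mask")
    return _sdf(mask)


def heaviside(v: np.ndarray, eps: float) -> np.ndarray:
    """Smoothed Heaviside; ``eps=0`` gives the sharp indicator V > 0."""
    if eps == 0:
        return (np.asarray(v) > 0).astype(np.float64)
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(v) / eps))


def delta(v: np.ndarray, eps: float) -> np.ndarray:
    """Derivative of the smoothed Heaviside."""
    return (eps / np.pi) / (eps**2 + np.asarray(v, dtype=np.float64) ** 2)


def region_means(
    img: np.ndarray, v: np.ndarray, eps: float = 1.0
) -> tuple[float, float]:
    """Heaviside-weighted interior (c1) and exterior (c2) mean intensities.

    If one side has (numerically) no mass, its mean defaults to the global
    mean of the image.
    """
    f = np.asarray(img, dtype=np.float64)
    h = heaviside(v, eps)
    win = float(h.sum())
    wout = float((1.0 - h).sum())
    gmean = float(f.mean())
    c1 = float((f * h).sum() / win) if win > 1e-12 else gmean
    c2 = float((f * (1.0 - h)).sum() / wout) if wout > 1e-12 else gmean
    return c1, c2


def _curvature(v: np.ndarray) -> np.ndarray:
    """div(grad V / |grad V|) by central differences with a safe norm."""
    vy, vx = np.gradient(v)
    norm = np.sqrt(vx**2 + vy**2) + 1e-8
    nyy, _ = np.gradient(vy / norm)
    _, nxx = np.gradient(vx / norm)
    return nxx + nyy


def chanvese_energy(
    img: np.ndarray, v: np.ndarray, params: ChanVeseParams,
    eps: float | None = None,
) -> float:
    """Discrete energy at V with c1/c2 set to their optima.

    ``eps`` overrides the Heaviside smoothing width; ``eps=0`` gives the
    energy of the segmentation itself (the sharp indicator V > 0), which is
    what the evolution monitors: it depends only on the sign of V and is
    therefore invariant under signed-distance reinitialization.
    """
    f = np.asarray(img, dtype=np.float64)
    if eps is None:
        eps = params.eps
    c1, c2 = region_means(f, v, eps)
    h = heaviside(v, eps)
    hy, hx = np.gradient(h)
    length = float(np.sqrt(hx**2 + hy**2).sum())
    fid1 = float(((f - c1) ** 2 * h).sum())
    fid2 = float(((f - c2) ** 2 * (1.0 - h)).sum())
    return params.mu * length + params.nu * float(h.sum()) \
        + params.lambda1 * fid1 + params.lambda2 * fid2


@dataclass
class ChanVeseResult:
    levelset: np.ndarray
    energies: list[float]
    n_iters: int
    converged: bool
    c1: float
    c2: float
    flags: tuple[str, ...] = ()

    @property
    def mask(self) -> np.ndarray:
        return self.levelset > 0


def _normalize(img: np.ndarray) -> np.ndarray:
    f = np.asarray(img, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("expected a grayscale image")
    return f / 255.0


def evolve(
    img: np.ndarray, v: np.ndarray, params: ChanVeseParams | None = None
) -> ChanVeseResult:
    """Run the level-set evolution from an initial V (8-bit image input).

    The recorded energy trace is non-increasing: a step that would raise the
    energy is retried with a halved dt, and the evolution stops if no
    reduction is possible.  Divergence to non-finite values raises
    :class:`NumericalInstabilityError`.
    """
    if params is None:
        params = ChanVeseParams()
    u = _normalize(img)
    v = np.array(v, dtype=np.float64)
    if v.shape != u.shape:
        raise ValueError("level set and image shapes differ")
    if not np.isfinite(v).all():
        raise NumericalInstabilityError("initial level set is non-finite")
    flags: list[str] = []
    energies = [chanvese_energy(u, v, params, eps=0.0)]
    converged = False
    still = 0
    it = 0
    for it in range(1, params.max_iters + 1):
        c1, c2 = region_means(u, v, 0.0)
        force = delta(v, params.eps) * (
            params.mu * _curvature(v)
            - params.nu
            - params.lambda1 * (u - c1) ** 2
            + params.lambda2 * (u - c2) ** 2
        )
        dt = params.dt
        accepted = False
        bound = energies[-1] + 1e-9 + 1e-9 * abs(energies[-1])
        for _ in range(8):
            cand = v + dt * force
            # Divergence: non-finite values, or magnitudes so far beyond any
            # image-scale signed distance that the evolution is meaningless.
            if not np.isfinite(cand).all() or np.abs(cand).max() > 1e30:
                raise NumericalInstabilityError(
                    "level set diverged (non-finite or unbounded values)"
                )
            e = chanvese_energy(u, cand, params, eps=0.0)
            if e <= bound:
                accepted = True
                break
            dt /= 2.0
        if not accepted:
            converged = True
            flags.append("stalled")
            break
        frac_flipped = float(((cand > 0) != (v > 0)).mean())
        if it % params.reinit_every == 0:
            # Signed-distance reset; preserves signs, hence also the
            # (sharp) energy just recorded.
            cand = _sdf(cand > 0)
        v = cand
        energies.append(e)
        if frac_flipped < params.tol:
            still += 1
            if still >= params.reinit_every + 3:
                converged = True
                break
        else:
            still = 0
    c1, c2 = region_means(u, v, params.eps)
    return ChanVeseResult(
        levelset=v, energies=energies, n_iters=it, converged=converged,
        c1=c1, c2=c2, flags=tuple(flags),
    )


def segment(
    img: np.ndarray, init_mask: np.ndarray, params: ChanVeseParams | None = None
) -> ChanVeseResult:
    """Full stage: signed-distance init from a mask, evolve, threshold at 0."""
    v0 = init_levelset(init_mask)
    return evolve(img, v0, params)
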