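"""Affine motion estimation by maximizing the Bhattacharyya matching energy.

The inter-frame motion is a 6-parameter affine warp acting on (x, y, 1):

    x' = (1+p1)*x + p3*y + p5
    y' = p2*x + (1+p4)*y + p6

The level set from the previous frame is warped (inverse mapping, the frame
stays fixed) and the pose is adjusted by preconditioned finite-difference
gradient ascent with a backtracking line search on the Taylor-expanded
matching energy; the returned energy trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .levelset import DEFAULT_EPS, LevelSet, heaviside
from .target import RegionModels, pixel_weights, region_distributions

__all__ = ["AffinePose", "RegistrationConfig", "apply_affine", "warp_level_set",
           "registration_energy", "estimate_pose"]


@dataclass(frozen=True)
class AffinePose:
    """Pose increment; the zero pose is the identity map."""

    params: tuple[float, float, float, float, float, float] = (0.0,) * 6

    @classmethod
    def from_array(cls, p) -> "AffinePose":
        p = np.asarray(p, dtype=float)
        if p.shape != (6,):
            raise ValueError("pose needs exactly 6 parameters")
        return cls(params=tuple(float(v) for v in p))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "AffinePose":
        return cls(params=(0.0, 0.0, 0.0, 0.0, float(tx), float(ty)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.params, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        p1, p2, p3, p4, p5, p6 = self.params
        return np.array([[1.0 + p1, p3, p5], [p2, 1.0 + p4, p6]])

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    def det(self) -> float:
        return float(np.linalg.det(self.linear))

    def is_invertible(self) -> bool:
        return abs(self.det()) >= 1e-6


def apply_affine(pose: AffinePose, points) -> np.ndarray:
    """Map (x, y) points through the pose; returns an (n, 2) array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    A = pose.matrix
    return pts @ A[:, :2].T + A[:, 2]


def warp_level_set(ls: LevelSet, pose: AffinePose, frame_shape=None) -> LevelSet:
    """phi'(x) = phi(h^{-1}(x)) by bilinear inverse mapping.

    Samples falling outside the grid are filled with -th (background).
    """
    if not pose.is_invertible():
        raise ValueError("affine pose is not invertible")
    shape = frame_shape if frame_shape is not None else ls.phi.shape
    M, N = shape
    yy, xx = np.mgrid[0:M, 0:N].astype(float)
    A = pose.linear
    b = pose.matrix[:, 2]
    Ainv = np.linalg.inv(A)
    # source = A^{-1} (dest - b), with points as (x, y)
    sx = Ainv[0, 0] * (xx - b[0]) + Ainv[0, 1] * (yy - b[1])
    sy = Ainv[1, 0] * (xx - b[0]) + Ainv[1, 1] * (yy - b[1])
    phi = ndimage.map_coordinates(
        ls.phi, [sy, sx], order=1, mode="constant", cval=-ls.th
    )
    return LevelSet(phi=phi, th=ls.th)


@dataclass
class RegistrationConfig:
    gamma: float = 0.5
    eps: float = DEFAULT_EPS
    tol: float = 1e-3
    max_iters: int = 50
    # finite-difference probe sizes: translation in px, linear part unitless
    fd_steps: tuple[float, ...] = (0.01, 0.01, 0.01, 0.01, 0.25, 0.25)
    step0: float = 2.0  # px of motion at which each line search starts
    translation_only: bool = False


def registration_energy(
    phi_warped: np.ndarray,
    th: float,
    hf: np.ndarray,
    hb: np.ndarray,
    gamma: float,
    eps: float,
) -> float:
    """Heaviside-weighted matching energy of the warped level set.

    The normalization masses Ff, Fb are those of the warped candidate
    (the Heaviside mass and the band mass), which keeps the objective a
    per-pixel average and free of the grow-to-cover-everything degeneracy
    a pose-frozen normalization would create.
    """
    H = heaviside(phi_warped, eps)
    band = ((phi_warped < 0) & (phi_warped > -th)).astype(float)
    Ff = max(float(np.sum(H)), 1e-12)
    Fb = max(float(np.sum((1.0 - H) * band)), 1e-12)
    fg_term = float(np.sum(H * hf)) / (2.0 * Ff)
    bg_term = float(np.sum((1.0 - H) * band * hb)) / (2.0 * Fb)
    return fg_term + gamma * bg_term


def estimate_pose(
    frame: np.ndarray,
    ls: LevelSet,
    models: RegionModels,
    cfg: RegistrationConfig | None = None,
) -> tuple[AffinePose, list[float]]:
    """Estimate the affine pose aligning ``ls`` with the target in ``frame``.

    Returns the converged pose and the trace of accepted energies
    (non-decreasing by construction).
    """
    cfg = cfg or RegistrationConfig()
    dist0 = region_distributions(frame, ls, models.r, cfg.eps)
    hf, hb = pixel_weights(frame, ls, models, dist0)

    def energy(p: np.ndarray) -> float:
        warped = warp_level_set(ls, AffinePose.from_array(p))
        if not np.any(warped.phi >= 0):
            raise ValueError("degenerate region after warp: empty foreground")
        return registration_energy(warped.phi, ls.th, hf, hb, cfg.gamma, cfg.eps)

    # Work in preconditioned coordinates q = p / steps so every parameter is
    # probed by +/-1 and the ascent direction is well scaled.  The ascent
    # runs in two phases: translation only (the widest basin), then the full
    # six-parameter warp.
    steps = np.asarray(cfg.fd_steps, dtype=float)

    def energy_q(q: np.ndarray) -> float:
        return energy(q * steps)

    q = np.zeros(6)
    trace = [energy_q(q)]
    # px-equivalent size of a unit move in q, per parameter (linear part acts
    # over roughly the target extent)
    extent = 0.5 * float(np.sqrt(np.count_nonzero(ls.phi >= 0)))
    px_unit = steps * np.array([extent] * 4 + [1.0, 1.0])

    translation = np.array([False] * 4 + [True] * 2)
    phases = [translation] if cfg.translation_only else [translation, np.ones(6, bool)]

    def px_move(d: np.ndarray, alpha: float) -> float:
        return alpha * float(np.max(np.abs(d) * px_unit))

    for active in phases:
        for _ in range(cfg.max_iters):
            grad = np.zeros(6)
            for k in np.flatnonzero(active):
                dq = np.zeros(6)
                dq[k] = 1.0
                try:
                    grad[k] = (energy_q(q + dq) - energy_q(q - dq)) / 2.0
                except ValueError:
                    grad[k] = 0.0
            gnorm = float(np.linalg.norm(grad))
            if gnorm < 1e-14:
                break
            d = grad / gnorm
            # backtracking line search; alpha in q units
            alpha = cfg.step0 / max(float(np.max(np.abs(d) * px_unit)), 1e-12)
            accepted = False
            while px_move(d, alpha) > cfg.tol / 8.0:
                try:
                    e_new = energy_q(q + alpha * d)
                except ValueError:
                    e_new = -np.inf
                if e_new > trace[-1] + 1e-12:
                    q = q + alpha * d
                    trace.append(e_new)
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break
            if px_move(d, alpha) < cfg.tol:
                break
    return AffinePose.from_array(q * steps), trace
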