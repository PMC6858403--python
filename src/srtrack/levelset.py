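"""Signed-distance level-set representation of the tracked region.

The target is the set {phi >= 0}; the contour is the zero crossing; the
background of interest is the narrow band {-th < phi < 0}.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "LevelSet",
    "init_level_set",
    "reinitialize",
    "heaviside",
    "dirac",
    "curvature",
]

DEFAULT_EPS = 1.5  # Heaviside regularization width, px
DEFAULT_TH = 10.0  # background band width, px


@dataclass
class LevelSet:
    phi: np.ndarray
    th: float = DEFAULT_TH

    @property
    def foreground(self) -> np.ndarray:
        return self.phi >= 0

    @property
    def band(self) -> np.ndarray:
        return (self.phi < 0) & (self.phi > -self.th)

    def with_phi(self, phi: np.ndarray) -> "LevelSet":
        return replace(self, phi=phi)


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    # Half-pixel shift centres the zero level on the mask boundary.
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return np.where(mask, inside - 0.5, -(outside - 0.5))


def init_level_set(mask: np.ndarray, th: float = DEFAULT_TH) -> LevelSet:
    """Signed Euclidean distance function, positive inside ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if mask.all():
        raise ValueError("mask covers the whole frame")
    if th <= 0:
        raise ValueError("band threshold must be positive")
    return LevelSet(phi=_signed_distance(mask), th=th)


def reinitialize(ls: LevelSet) -> LevelSet:
    """Rebuild phi as the signed distance from its current zero level."""
    return ls.with_phi(_signed_distance(ls.phi >= 0))


def heaviside(phi: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Regularized step: 0.5 * (1 + (2/pi) * arctan(phi/eps))."""
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / eps))


def dirac(phi: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Derivative of :func:`heaviside`: (1/pi) * eps / (eps^2 + phi^2)."""
    return (eps / np.pi) / (eps**2 + phi**2)


def curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad(phi)/|grad(phi)|) with central differences, reflected edges."""
    p = np.pad(phi, 1, mode="edge")
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    norm = np.sqrt(gx**2 + gy**2)
    norm = np.maximum(norm, 1e-8)
    nx, ny = gx / norm, gy / norm
    px = np.pad(nx, 1, mode="edge")
    py = np.pad(ny, 1, mode="edge")
    div = (px[1:-1, 2:] - px[1:-1, :-2]) / 2.0 + (py[2:, 1:-1] - py[:-2, 1:-1]) / 2.0
    return div
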