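"""Ground-truthed synthetic sequences for benchmarking the tracker.

A piecewise-intensity target (disk, square, or an elongated tool-like
polygon) moves along an affine path over a smooth textured background.
Zero-mean Gaussian noise, a smooth illumination drift and a partial
occluder can be layered on top.  Per-frame masks are the exact rasterized
target before any degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

__all__ = ["SequenceSpec", "make_sequence"]

_MARGIN = 5  # target must stay this many px inside the frame


@dataclass
class SequenceSpec:
    shape: tuple[int, int] = (64, 64)
    target: str = "square"  # disk | square | tool_polygon
    target_size: float = 10.0  # radius / half-side / half-length
    center: tuple[float, float] = (24.0, 24.0)  # (x, y) at t=0
    fg_level: float = 0.75
    bg_level: float = 0.3
    velocity: tuple[float, float] = (2.0, 0.0)  # px/frame (vx, vy)
    scale_rate: float = 0.0  # per-frame isotropic scale increment
    rotation_rate: float = 0.0  # radians/frame, tool_polygon only
    noise_sigma: float = 0.05
    texture_amp: float = 0.03
    illum_amp: float = 0.0
    occluder: dict | None = None  # {"frames": (t0,t1), "rect": (x,y,w,h), "level": v}
    n_frames: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.target not in ("disk", "square", "tool_polygon"):
            raise ValueError(f"unknown target shape {self.target!r}")


def _target_mask(spec: SequenceSpec, t: int) -> np.ndarray:
    M, N = spec.shape
    cx = spec.center[0] + spec.velocity[0] * t
    cy = spec.center[1] + spec.velocity[1] * t
    size = spec.target_size * (1.0 + spec.scale_rate * t)
    if not (
        _MARGIN + size <= cx <= N - 1 - _MARGIN - size
        and _MARGIN + size <= cy <= M - 1 - _MARGIN - size
    ):
        raise ValueError(f"target leaves the frame at t={t}")
    yy, xx = np.mgrid[0:M, 0:N].astype(float)
    if spec.target == "disk":
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= size**2
    if spec.target == "square":
        return (np.abs(xx - cx) <= size) & (np.abs(yy - cy) <= size)
    # tool_polygon: rotated elongated rectangle with a wedge tip
    ang = spec.rotation_rate * t
    L, Wd = size, max(size / 3.0, 2.0)
    pts = np.array(
        [
            [-L, -Wd], [L * 0.6, -Wd], [L, 0.0], [L * 0.6, Wd], [-L, Wd],
        ]
    )
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    pts = pts @ R.T + np.array([cx, cy])
    mask = np.zeros((M, N), dtype=bool)
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=(M, N))
    mask[rr, cc] = True
    return mask


def make_sequence(spec: SequenceSpec) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Render (frames, ground-truth masks); deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    M, N = spec.shape
    texture = ndimage.gaussian_filter(rng.normal(size=(M, N)), sigma=4.0)
    if texture.std() > 0:
        texture = spec.texture_amp * texture / texture.std()

    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for t in range(spec.n_frames):
        mask = _target_mask(spec, t)
        clean = np.where(mask, spec.fg_level, spec.bg_level + texture)
        if spec.illum_amp:
            clean = clean + spec.illum_amp * np.sin(2.0 * np.pi * t / spec.n_frames)
        if spec.occluder is not None:
            t0, t1 = spec.occluder["frames"]
            if t0 <= t <= t1:
                x, y, w, h = spec.occluder["rect"]
                clean[y : y + h, x : x + w] = spec.occluder["level"]
        frame = clean + spec.noise_sigma * rng.normal(size=(M, N))
        frames.append(np.clip(frame, 0.0, 1.0))
        masks.append(mask)
    return frames, masks
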