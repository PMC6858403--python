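"""Two-dimensional maximal-overlap (undecimated) discrete wavelet transform.

The transform keeps every coefficient grid at the input size, uses circular
boundary handling, and is exactly shift-equivariant.  Per level the
orthonormal analysis filters are rescaled by 1/sqrt(2) and upsampled by
2**(level-1), following the standard pyramid algorithm for the maximal
overlap transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveletPyramid",
    "modwt_forward",
    "modwt_inverse",
    "max_levels",
    "wavelet_filters",
]

_SQRT2 = np.sqrt(2.0)

# Orthonormal scaling (low-pass) filters; each sums to sqrt(2).
_SCALING_FILTERS: dict[str, np.ndarray] = {
    "haar": np.array([1.0, 1.0]) / _SQRT2,
    # Daubechies extremal-phase, 8 taps.
    "db4": np.array(
        [
            0.230377813308855230,
            0.714846570552541500,
            0.630880767929590400,
            -0.027983769416983850,
            -0.187034811718881140,
            0.030841381835986965,
            0.032883011666982945,
            -0.010597401784997278,
        ]
    ),
}


def wavelet_filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return the orthonormal (scaling, wavelet) filter pair for ``name``.

    The wavelet filter is the quadrature mirror of the scaling filter:
    ``h[l] = (-1)**l * g[L-1-l]``.
    """
    try:
        g = _SCALING_FILTERS[name]
    except KeyError:
        raise ValueError(
            f"unknown wavelet {name!r}; supported: {sorted(_SCALING_FILTERS)}"
        ) from None
    L = len(g)
    h = np.array([(-1.0) ** l * g[L - 1 - l] for l in range(L)])
    return g, h


def max_levels(shape: tuple[int, int], wavelet: str) -> int:
    """Deepest level whose upsampled filter still fits in the grid."""
    g, _ = wavelet_filters(wavelet)
    L = len(g)
    n = min(shape)
    j = 0
    while (L - 1) * 2**j < n:
        j += 1
    return j


@dataclass
class WaveletPyramid:
    """Undecimated wavelet pyramid of a single 2-D frame.

    ``approx`` holds the deepest-level smooth coefficients; ``details[l-1]``
    holds the level-``l`` detail grids keyed ``"H"``, ``"V"``, ``"D"``
    (high-pass along columns, along rows, and along both).
    """

    approx: np.ndarray
    details: list[dict[str, np.ndarray]]
    wavelet_name: str
    levels: int = field(default=0)

    def __post_init__(self) -> None:
        if self.levels == 0:
            self.levels = len(self.details)
        shape = self.approx.shape
        for lev in self.details:
            for s in ("H", "V", "D"):
                if lev[s].shape != shape:
                    raise ValueError("pyramid grids have mismatched shapes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.approx.shape

    def coefficient_grids(self):
        """Yield (label, grid) pairs over every coefficient grid."""
        yield "approx", self.approx
        for l, lev in enumerate(self.details, start=1):
            for s in ("H", "V", "D"):
                yield f"{s}{l}", lev[s]


def _analyze(x: np.ndarray, filt: np.ndarray, step: int, axis: int) -> np.ndarray:
    """Circular filtering  y[t] = sum_l f[l] x[(t - l*step) mod N]."""
    out = np.zeros_like(x)
    for l, fl in enumerate(filt):
        out += fl * np.roll(x, l * step, axis=axis)
    return out


def _synthesize(x: np.ndarray, filt: np.ndarray, step: int, axis: int) -> np.ndarray:
    """Adjoint pass  y[t] = sum_l f[l] x[(t + l*step) mod N]."""
    out = np.zeros_like(x)
    for l, fl in enumerate(filt):
        out += fl * np.roll(x, -l * step, axis=axis)
    return out


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D grid")
    if min(frame.shape) < 8:
        raise ValueError("frame must be at least 8x8")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    return frame


def modwt_forward(frame: np.ndarray, wavelet_name: str = "haar", levels: int = 2) -> WaveletPyramid:
    """Decompose ``frame`` into an undecimated pyramid of ``levels`` levels."""
    frame = _check_frame(frame)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if levels > max_levels(frame.shape, wavelet_name):
        raise ValueError(
            f"{levels} levels exceed what a {frame.shape} grid supports "
            f"for wavelet {wavelet_name!r}"
        )
    g, h = wavelet_filters(wavelet_name)
    gt, ht = g / _SQRT2, h / _SQRT2

    approx = frame
    details: list[dict[str, np.ndarray]] = []
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        lo0 = _analyze(approx, gt, step, axis=0)
        hi0 = _analyze(approx, ht, step, axis=0)
        details.append(
            {
                "H": _analyze(lo0, ht, step, axis=1),
                "V": _analyze(hi0, gt, step, axis=1),
                "D": _analyze(hi0, ht, step, axis=1),
            }
        )
        approx = _analyze(lo0, gt, step, axis=1)
    return WaveletPyramid(approx=approx, details=details, wavelet_name=wavelet_name)


def modwt_inverse(pyramid: WaveletPyramid) -> np.ndarray:
    """Reconstruct the frame; exact inverse of :func:`modwt_forward`."""
    g, h = wavelet_filters(pyramid.wavelet_name)
    gt, ht = g / _SQRT2, h / _SQRT2

    approx = pyramid.approx
    for j in range(pyramid.levels, 0, -1):
        step = 2 ** (j - 1)
        lev = pyramid.details[j - 1]
        lo0 = _synthesize(approx, gt, step, axis=1) + _synthesize(lev["H"], ht, step, axis=1)
        hi0 = _synthesize(lev["V"], gt, step, axis=1) + _synthesize(lev["D"], ht, step, axis=1)
        approx = _synthesize(lo0, gt, step, axis=0) + _synthesize(hi0, ht, step, axis=0)
    return approx
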