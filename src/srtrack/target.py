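"""Histogram region models and the Bhattacharyya matching energy.

The target is described by an r-bin intensity histogram of the foreground
(phi >= 0) and of the background band (-th < phi < 0), built on the first
frame.  Candidate regions on later frames are scored by the weighted
Bhattacharyya coefficient

    En1 = sum_bins( sqrt(fg * fd) + gamma * sqrt(bg * bd) ),

which is maximal (1 + gamma) when the candidate matches the models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .levelset import DEFAULT_EPS, LevelSet, heaviside

__all__ = [
    "RegionModels",
    "RegionDistributions",
    "bin_map",
    "build_models",
    "region_distributions",
    "bhattacharyya_energy",
    "pixel_weights",
]

DEFAULT_BINS = 32


@dataclass
class RegionModels:
    """First-frame foreground/background histograms, each summing to 1."""

    fd: np.ndarray
    bd: np.ndarray
    r: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.fd, self.bd):
            if abs(float(v.sum()) - 1.0) > 1e-9 or (v < 0).any():
                raise ValueError("model histograms must be non-negative and sum to 1")


@dataclass
class RegionDistributions:
    """Heaviside-weighted candidate histograms and their total masses."""

    fg: np.ndarray
    bg: np.ndarray
    Ff: float
    Fb: float


def bin_map(frame: np.ndarray, r: int) -> np.ndarray:
    """Map each pixel intensity in [0, 1] to a bin index in {0..r-1}."""
    if r < 2:
        raise ValueError("need at least 2 bins")
    return np.clip((np.asarray(frame, dtype=float) * r).astype(np.intp), 0, r - 1)


def _normalized_hist(bins: np.ndarray, weights: np.ndarray, r: int) -> tuple[np.ndarray, float]:
    h = np.bincount(bins.ravel(), weights=weights.ravel(), minlength=r).astype(float)
    total = float(h.sum())
    return h, total


def build_models(frame: np.ndarray, ls: LevelSet, r: int = DEFAULT_BINS) -> RegionModels:
    """Crisp foreground/band histograms of the first frame."""
    if r < 2:
        raise ValueError("need at least 2 bins")
    fg_mask = ls.foreground
    band_mask = ls.band
    if not fg_mask.any() or not band_mask.any():
        raise ValueError("foreground and background band must be non-empty")
    bins = bin_map(frame, r)
    fd, nf = _normalized_hist(bins, fg_mask.astype(float), r)
    bd, nb = _normalized_hist(bins, band_mask.astype(float), r)
    return RegionModels(fd=fd / nf, bd=bd / nb, r=r,
                        bin_edges=np.linspace(0.0, 1.0, r + 1))


def region_distributions(
    frame: np.ndarray, ls: LevelSet, r: int = DEFAULT_BINS, eps: float = DEFAULT_EPS
) -> RegionDistributions:
    """Soft candidate histograms: fg weighted by H_eps(phi), bg by
    (1 - H_eps(phi)) restricted to the band phi > -th."""
    bins = bin_map(frame, r)
    H = heaviside(ls.phi, eps)
    wf = H
    wb = (1.0 - H) * (ls.phi > -ls.th)
    fg, Ff = _normalized_hist(bins, wf, r)
    bg, Fb = _normalized_hist(bins, wb, r)
    if Ff < 1e-12 or Fb < 1e-12:
        raise ValueError("degenerate region: vanishing foreground or band mass")
    return RegionDistributions(fg=fg / Ff, bg=bg / Fb, Ff=Ff, Fb=Fb)


def bhattacharyya_energy(
    dist: RegionDistributions, models: RegionModels, gamma: float = 0.5
) -> float:
    if len(dist.fg) != len(models.fd) or len(dist.bg) != len(models.bd):
        raise ValueError("distribution/model length mismatch")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    fg_term = float(np.sum(np.sqrt(dist.fg * models.fd)))
    bg_term = float(np.sum(np.sqrt(dist.bg * models.bd)))
    return fg_term + gamma * bg_term


def _ratio_weights(model: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    # sqrt(model/candidate) per bin; bins with zero candidate mass carry no
    # gradient information and get weight 0 (0/0 -> 0 and c/0 -> 0).
    out = np.zeros_like(model)
    ok = candidate > 0
    out[ok] = np.sqrt(model[ok] / candidate[ok])
    out[model == 0] = 0.0
    return out


def pixel_weights(
    frame: np.ndarray,
    ls_phi0: LevelSet,
    models: RegionModels,
    dist0: RegionDistributions,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Taylor-expansion weights h_f, h_b.

    h_f(x) = sqrt(fd[b(x)] / fg0[b(x)]), h_b(x) = sqrt(bd[b(x)] / bg0[b(x)]),
    where b(x) is the pixel's bin and fg0/bg0 the candidate distributions at
    the initial pose.
    """
    bins = bin_map(frame, models.r)
    hf_bins = _ratio_weights(models.fd, dist0.fg)
    hb_bins = _ratio_weights(models.bd, dist0.bg)
    return hf_bins[bins], hb_bins[bins]
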