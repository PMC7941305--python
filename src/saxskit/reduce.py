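"""Radial averaging of detector images into 1D curves, and basic 1D curve algebra.

Each unmasked pixel contributes to exactly one ring (no pixel splitting, so
ring estimates stay statistically independent).  Within a ring, outliers are
rejected by variance-stabilizing the Poisson counts with the Anscombe
transform, y = 2 sqrt(x + 3/8), and discarding points whose median-based
robust z score exceeds 4.  Errors follow Poisson counting statistics.

If the image carries a per-pixel normalisation grid (expected counts per unit
intensity, as attached by the image simulator), the ring estimate is the ratio
``sum(counts) / sum(norm)`` over kept pixels, which returns the curve in the
source intensity units; otherwise plain count units are reported.
"""

from __future__ import annotations

import numpy as np

from .detector_sim import DetectorImage, s_map
from .sasio import ScatteringCurve

__all__ = [
    "anscombe_robust_z",
    "radial_average",
    "average_curves",
    "subtract_curves",
    "GRID_RTOL",
]

#: relative tolerance when matching s-grids of 1D curves
GRID_RTOL = 1e-6

_ROBUST_Z_SCALE = 0.6745   # Phi^-1(3/4): MAD -> sigma for a normal
_ROBUST_Z_CUTOFF = 4.0


def anscombe_robust_z(counts, cutoff: float = _ROBUST_Z_CUTOFF,
                      two_sided: bool = True) -> np.ndarray:
    """Keep-flags for a ring of Poisson counts.

    Anscombe-transform the counts, compute the median-based robust z score
    ``z = 0.6745 (y - median) / MAD`` and keep ``|z| <= cutoff`` (or
    ``z <= cutoff`` when ``two_sided=False``).  A degenerate ring with
    MAD = 0 keeps everything.
    """
    x = np.asarray(counts, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ring")
    y = 2.0 * np.sqrt(x + 0.375)
    med = np.median(y)
    mad = np.median(np.abs(y - med))
    if mad == 0:
        return np.ones(x.size, dtype=bool)
    z = _ROBUST_Z_SCALE * (y - med) / mad
    return (np.abs(z) <= cutoff) if two_sided else (z <= cutoff)


def radial_average(image: DetectorImage, nbins: int, reject: bool = True,
                   two_sided: bool = True) -> ScatteringCurve:
    """Azimuthal/radial average of a detector image into a 1D curve.

    Equal-width bins in s between the smallest and largest s of unmasked
    pixels; the bin's s coordinate is the plain (intensity-independent) mean s
    of kept pixels; empty rings are omitted.  I = sum(counts)/sum(norm) with
    sigma = sqrt(sum counts)/sum(norm) (norm == 1 per pixel when the image
    carries none; a zero-count ring gets the one-count error bound).
    """
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    mask = image.mask
    if not mask.any():
        raise ValueError("all pixels are masked")
    smap = s_map(image.geometry)
    s_valid = smap[mask]
    counts = image.counts[mask].astype(float)
    norm = (image.norm[mask] if image.norm is not None
            else np.ones(counts.size))
    lo, hi = float(s_valid.min()), float(s_valid.max())
    edges = np.linspace(lo, hi, nbins + 1)
    idx = np.clip(np.searchsorted(edges, s_valid, side="right") - 1, 0, nbins - 1)

    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    bounds = np.searchsorted(idx_sorted, np.arange(nbins + 1))

    s_out, i_out, sig_out = [], [], []
    for b in range(nbins):
        sel = order[bounds[b]:bounds[b + 1]]
        if sel.size == 0:
            continue
        x = counts[sel]
        k = norm[sel]
        ss = s_valid[sel]
        if reject and x.size >= 3:
            keep = anscombe_robust_z(x, two_sided=two_sided)
            x, k, ss = x[keep], k[keep], ss[keep]
            if x.size == 0:
                continue
        tot = x.sum()
        denom = k.sum()
        s_out.append(ss.mean())
        i_out.append(tot / denom)
        sig_out.append(np.sqrt(max(tot, 1.0)) / denom)
    if len(s_out) < 2:
        raise ValueError("fewer than 2 non-empty rings")
    scale = "absolute" if image.norm is not None else "relative"
    return ScatteringCurve(s=np.array(s_out), I=np.array(i_out),
                           sigma=np.array(sig_out), scale=scale,
                           label="radial_average")


def _check_grids(curves) -> np.ndarray:
    ref = curves[0].s
    for c in curves[1:]:
        if c.n != curves[0].n or not np.allclose(c.s, ref, rtol=GRID_RTOL,
                                                 atol=0.0):
            raise ValueError("s-grids differ beyond tolerance")
    return ref


def average_curves(curves) -> ScatteringCurve:
    """Pointwise mean of replicate curves on a common grid.

    sigma_out = sqrt(sum sigma_i^2) / N, assuming independent errors; absent
    if any input lacks error estimates.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    s = _check_grids(curves)
    n = len(curves)
    I = np.mean([c.I for c in curves], axis=0)
    sigma = None
    if all(c.sigma is not None for c in curves):
        sigma = np.sqrt(np.sum([c.sigma ** 2 for c in curves], axis=0)) / n
    return ScatteringCurve(s=s, I=I, sigma=sigma, scale=curves[0].scale,
                           label="average")


def subtract_curves(sample: ScatteringCurve,
                    background: ScatteringCurve) -> ScatteringCurve:
    """sample - background with errors added in quadrature."""
    s = _check_grids([sample, background])
    sigma = None
    if sample.sigma is not None and background.sigma is not None:
        sigma = np.hypot(sample.sigma, background.sigma)
    return ScatteringCurve(s=s, I=sample.I - background.I, sigma=sigma,
                           scale=sample.scale, label="subtracted")
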