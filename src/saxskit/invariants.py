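"""Model-free structural parameters from a 1D curve: Guinier fit, Porod
invariant and volume, volume of correlation, and concentration-independent
molecular-weight estimates.

All quantities here are strictly invariant under rescaling of the intensities
(I0 and the integrals scale together), which is what makes them usable when the
sample concentration is unknown (e.g. SEC-SAXS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sasio import ScatteringCurve
from .realspace import fit_tail

__all__ = [
    "GuinierResult",
    "InvariantsReport",
    "guinier_fit",
    "porod",
    "volume_of_correlation",
    "mw_from_vp",
    "mw_from_vc",
    "mw_estimates",
    "invariants_report",
]

#: atomic mass unit in grams (1 Da)
DALTON_G = 1.66053907e-24

# Volume-of-correlation -> MW power law for proteins and RNA
# (Rambo & Tainer, Nature 496, 477 (2013): QR = Vc^2 / Rg,
#  MW_protein = QR / 0.1231, MW_RNA = (QR / 0.00934)^0.808).
_VC_MW_LAWS = {
    "protein": (0.1231, 1.0),
    "rna": (0.00934, 0.808),
}


@dataclass(frozen=True)
class GuinierResult:
    rg: float
    i0: float
    rg_se: float
    i0_se: float
    s_lo: float
    s_hi: float
    npoints: int


@dataclass(frozen=True)
class InvariantsReport:
    """Collected model-free parameters; unavailable entries are None."""

    guinier: GuinierResult | None
    qp: float | None
    vp: float | None
    vc: float | None
    mw_vp: float | None
    mw_vc: float | None

    def __str__(self) -> str:
        lines = []
        g = self.guinier
        if g is not None:
            lines.append(f"Rg        = {g.rg:.2f} +/- {g.rg_se:.2f} A  "
                         f"(Guinier, {g.npoints} pts, s in "
                         f"[{g.s_lo:.4f}, {g.s_hi:.4f}])")
            lines.append(f"I0        = {g.i0:.4g} +/- {g.i0_se:.2g}")
        if self.vp is not None:
            lines.append(f"Vp        = {self.vp:.0f} A^3   (Qp = {self.qp:.4g})")
        if self.vc is not None:
            lines.append(f"Vc        = {self.vc:.1f} A^2")
        if self.mw_vp is not None:
            lines.append(f"MW (Vp)   = {self.mw_vp:.0f} Da")
        if self.mw_vc is not None:
            lines.append(f"MW (Vc)   = {self.mw_vc:.0f} Da")
        return "\n".join(lines)


def guinier_fit(curve: ScatteringCurve, srg_limit: float = 1.3,
                min_points: int = 5, max_iter: int = 50) -> GuinierResult:
    """Weighted linear fit of ln I vs s^2 over the Guinier region.

    The window [s_min, s_hi] is found self-consistently: starting from the
    lowest ``min_points`` positive-intensity points, the fit is repeated with
    the window s * Rg <= srg_limit until it stabilizes.  Standard errors come
    from the weighted regression (delta method for Rg).
    """
    s, I = curve.s, curve.I
    pos = I > 0
    if np.count_nonzero(pos[:min_points]) < min_points:
        raise ValueError("intensities must be positive at low s")
    x = s ** 2
    y = np.where(pos, np.log(np.where(pos, I, 1.0)), -np.inf)
    # weights: relative errors of I -> absolute errors of ln I, w = (I/sigma)^2;
    # with sigma absent, w = I^2 (the linearization of unweighted LS on I)
    if curve.sigma is not None and np.all(curve.sigma[pos] > 0):
        wt = np.where(pos, (np.where(pos, I, 1.0)
                            / np.where(curve.sigma > 0, curve.sigma, 1.0)) ** 2, 0.0)
    else:
        wt = np.where(pos, I, 0.0) ** 2

    # initial window: down to roughly half the forward intensity (sRg ~ 0.9
    # for globular shapes) -- wider and far more noise-robust than the first
    # handful of points, then refined self-consistently below
    i0_guess = np.median(I[pos][:min_points])
    below = np.flatnonzero(pos & (I < 0.5 * i0_guess))
    hi0 = int(below[0]) if below.size else curve.n
    kth = np.searchsorted(np.cumsum(pos), min_points) + 1
    sel = pos & (np.arange(curve.n) < max(hi0, kth))

    def fit(sel):
        X, Y, W = x[sel], y[sel], wt[sel]
        Sw = W.sum()
        xm = (W * X).sum() / Sw
        ym = (W * Y).sum() / Sw
        sxx = (W * (X - xm) ** 2).sum()
        slope = (W * (X - xm) * (Y - ym)).sum() / sxx
        intercept = ym - slope * xm
        resid = Y - (intercept + slope * X)
        npts = int(np.count_nonzero(sel))
        # scale the nominal covariance by reduced chi2 (>=1 guard not applied)
        dof = max(npts - 2, 1)
        s2 = (W * resid ** 2).sum() / dof
        slope_se = np.sqrt(s2 / sxx)
        intercept_se = np.sqrt(s2 * (1.0 / Sw + xm ** 2 / sxx))
        return slope, intercept, slope_se, intercept_se, npts

    prev_hi = -1
    for _ in range(max_iter):
        slope, intercept, slope_se, intercept_se, npts = fit(sel)
        if slope >= 0:
            raise ValueError("non-negative Guinier slope: no decaying "
                             "low-angle region")
        rg = float(np.sqrt(-3.0 * slope))
        hi = np.searchsorted(s, srg_limit / rg, side="right")
        hi = max(hi, min_points)
        new_sel = pos & (np.arange(curve.n) < hi)
        if np.count_nonzero(new_sel) < min_points:
            raise ValueError("no valid Guinier window with >= "
                             f"{min_points} points")
        if hi == prev_hi:
            break
        prev_hi = hi
        sel = new_sel
    i0 = float(np.exp(intercept))
    return GuinierResult(
        rg=rg, i0=i0,
        rg_se=float(3.0 * slope_se / (2.0 * rg)),
        i0_se=float(i0 * intercept_se),
        s_lo=float(s[sel][0]), s_hi=float(s[sel][-1]), npoints=npts)


def _tail_amplitude(curve: ScatteringCurve, exponent: int,
                    tail_fraction: float) -> float | None:
    """Power-law tail amplitude, or None (with a warning) if not tail-like."""
    try:
        A = fit_tail(curve, exponent, tail_fraction)
    except ValueError:
        warnings.warn("high-angle tail is not Porod-like; "
                      "continuation skipped")
        return None
    # sanity: the fitted tail should match the data level at s_max
    if not np.isfinite(A):
        return None
    return A


def porod(curve: ScatteringCurve, i0: float,
          tail_fraction: float = 0.1) -> tuple[float, float]:
    """Porod invariant Q_p = int s^2 I ds (with s^-4 tail continuation) and
    the Porod volume V_p = 2 pi^2 I0 / Q_p (A^3)."""
    if i0 <= 0:
        raise ValueError("I0 must be positive")
    s, I = curve.s, curve.I
    qp = float(np.trapezoid(s ** 2 * I, s))
    A = _tail_amplitude(curve, 4, tail_fraction)
    if A is not None:
        qp += A / s[-1]          # int_{smax}^inf A s^-2 ds
    return qp, 2.0 * np.pi ** 2 * i0 / qp


def volume_of_correlation(curve: ScatteringCurve, i0: float,
                          tail_fraction: float = 0.1) -> float:
    """V_c = I0 / int s I ds (A^2), with s^-4 tail continuation."""
    if i0 <= 0:
        raise ValueError("I0 must be positive")
    s, I = curve.s, curve.I
    denom = float(np.trapezoid(s * I, s))
    A = _tail_amplitude(curve, 4, tail_fraction)
    if A is not None:
        denom += A / (2.0 * s[-1] ** 2)   # int_{smax}^inf A s^-3 ds
    return i0 / denom


def mw_from_vp(vp: float, psv: float = 0.74) -> float:
    """MW (Da) from the Porod volume: mass = V_p / v-bar, in daltons.

    ``psv`` is the partial specific volume in cm^3/g (0.74 for an average
    protein); 1 A^3 = 1e-24 cm^3.
    """
    if vp <= 0 or psv <= 0:
        raise ValueError("vp and psv must be positive")
    return vp * 1.0e-24 / psv / DALTON_G


def mw_from_vc(vc: float, rg: float, kind: str = "protein") -> float:
    """MW (Da) from the volume of correlation via QR = V_c^2 / R_g and the
    empirical power law for the chosen molecule kind ('protein' or 'rna')."""
    if vc <= 0 or rg <= 0:
        raise ValueError("vc and rg must be positive")
    try:
        coef, power = _VC_MW_LAWS[kind]
    except KeyError:
        raise ValueError(f"unknown molecule kind {kind!r}") from None
    qr = vc ** 2 / rg
    return (qr / coef) ** power


def mw_estimates(vp: float | None, vc: float | None, rg: float | None,
                 psv: float = 0.74,
                 kind: str = "protein") -> tuple[float | None, float | None]:
    """(MW_vp, MW_vc); absent inputs give absent outputs."""
    mw_vp = mw_from_vp(vp, psv) if vp is not None else None
    mw_vc = mw_from_vc(vc, rg, kind) if (vc is not None and rg is not None) \
        else None
    return mw_vp, mw_vc


def invariants_report(curve: ScatteringCurve, rg: float | None = None,
                      i0: float | None = None, srg_limit: float = 1.3,
                      psv: float = 0.74,
                      kind: str = "protein") -> InvariantsReport:
    """One-stop report: Guinier fit (unless Rg/I0 supplied), Porod volume,
    volume of correlation and the MW estimates derived from them."""
    g = None
    if rg is None or i0 is None:
        g = guinier_fit(curve, srg_limit=srg_limit)
        rg = g.rg if rg is None else rg
        i0 = g.i0 if i0 is None else i0
    qp = vp = vc = None
    try:
        qp, vp = porod(curve, i0)
        vc = volume_of_correlation(curve, i0)
    except ValueError as exc:
        warnings.warn(f"invariant integrals unavailable: {exc}")
    mw_vp, mw_vc = mw_estimates(vp, vc, rg, psv=psv, kind=kind)
    return InvariantsReport(guinier=g, qp=qp, vp=vp, vc=vc,
                            mw_vp=mw_vp, mw_vc=mw_vc)
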