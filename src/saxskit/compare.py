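"""Pairwise goodness-of-fit statistics for scattering curves, and parametric resampling.

Three complementary tests for the hypothesis "these two curves are identical up
to noise":

* reduced chi-square of the standardized residuals (requires well-estimated
  errors); p is the upper tail of chi^2 with nu = n degrees of freedom (pure
  two-curve comparison, nothing fitted);
* the correlation-map (CorMap) test: the longest run of consecutive same-sign
  differences, with an *exact* longest-run null distribution — independent of
  error estimates;
* the Anderson-Darling test of the standardized residuals against the fully
  specified standard normal (case 0), with the asymptotic p-value evaluation of
  Marsaglia & Marsaglia.

For well-calibrated data ~99% of standardized residuals fall within +/-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .sasio import ScatteringCurve
from .reduce import GRID_RTOL

__all__ = [
    "ComparisonResult",
    "residuals",
    "reduced_chi2",
    "cormap",
    "cormap_pvalue",
    "longest_run",
    "anderson_darling",
    "ad_statistic",
    "ad_pvalue",
    "datcmp",
    "resample_curve",
]


@dataclass(frozen=True)
class ComparisonResult:
    """The three test statistics and their p-values for one pair of curves."""

    n: int
    chi2_red: float
    chi2_p: float
    cormap_C: int
    cormap_p: float
    ad_A2: float
    ad_p: float

    def __str__(self) -> str:  # Table-1 style layout
        return (f"n={self.n}  CorMap C={self.cormap_C} (p={self.cormap_p:.4f})  "
                f"chi2_red={self.chi2_red:.3f} (p={self.chi2_p:.4f})  "
                f"AD A2={self.ad_A2:.3f} (p={self.ad_p:.4f})")


def _common(a: ScatteringCurve, b: ScatteringCurve):
    if a.n != b.n or not np.allclose(a.s, b.s, rtol=GRID_RTOL, atol=0.0):
        raise ValueError("curves are not on a common s-grid")


def _propagated_sigma(a: ScatteringCurve, b: ScatteringCurve) -> np.ndarray:
    if a.sigma is None and b.sigma is None:
        raise ValueError("at least one curve must carry error estimates")
    sa = a.sigma if a.sigma is not None else 0.0
    sb = b.sigma if b.sigma is not None else 0.0
    sig = np.hypot(sa, sb)
    if np.any(sig == 0):
        raise ValueError("zero propagated error at some points")
    return sig


def residuals(a: ScatteringCurve, b: ScatteringCurve) -> np.ndarray:
    """Standardized residuals (I_a - I_b) / sqrt(sigma_a^2 + sigma_b^2)."""
    _common(a, b)
    return (a.I - b.I) / _propagated_sigma(a, b)


def fraction_within(r: np.ndarray, bound: float = 3.0) -> float:
    """Fraction of standardized residuals with |r| <= bound."""
    r = np.asarray(r, dtype=float)
    return float(np.mean(np.abs(r) <= bound))


# ---------------------------------------------------------------------------
# reduced chi-square
# ---------------------------------------------------------------------------

def reduced_chi2(a: ScatteringCurve, b: ScatteringCurve) -> tuple[float, float]:
    """Reduced chi^2 = mean squared standardized residual, and its upper-tail p
    at nu = n degrees of freedom."""
    r = residuals(a, b)
    n = r.size
    stat = float(np.mean(r ** 2))
    return stat, float(stats.chi2.sf(stat * n, df=n))


# ---------------------------------------------------------------------------
# CorMap: exact longest-run test
# ---------------------------------------------------------------------------

def longest_run(diff: np.ndarray) -> int:
    """Length of the longest run of consecutive same-sign values.

    sign(0) counts as positive (ties are measure-zero on real data).
    """
    sgn = np.where(np.asarray(diff) >= 0, 1, -1)
    best = run = 1
    for i in range(1, sgn.size):
        run = run + 1 if sgn[i] == sgn[i - 1] else 1
        if run > best:
            best = run
    return best


@lru_cache(maxsize=None)
def _q_no_head_run(m: int, x: int) -> float:
    """P(longest run of heads <= x in m fair coin flips), by recursion."""
    if x >= m:
        return 1.0
    if x < 0:
        return 0.0
    Q = np.ones(m + 1)
    w = 0.5 ** np.arange(1, x + 2)
    for k in range(x + 1, m + 1):
        Q[k] = float(np.dot(Q[k - 1 - np.arange(x + 1)], w))
    return float(Q[m])


def cormap_pvalue(n: int, C: int) -> float:
    """Exact P(longest run of identical outcomes >= C in n fair Bernoulli trials).

    Uses the classical identity that a run of C identical outcomes among n
    trials corresponds to a run of C-1 "same as previous" successes among the
    n-1 consecutive pairs.
    """
    if n < 1 or C < 1:
        raise ValueError("n and C must be >= 1")
    if C > n:
        return 0.0
    if C <= 1:
        return 1.0
    return 1.0 - _q_no_head_run(n - 1, C - 2)


def cormap(a: ScatteringCurve, b: ScatteringCurve) -> tuple[int, float]:
    """Longest same-sign run of I_a - I_b and its exact p-value."""
    _common(a, b)
    C = longest_run(a.I - b.I)
    return C, cormap_pvalue(a.n, C)


# ---------------------------------------------------------------------------
# Anderson-Darling, case 0 (fully specified standard normal)
# ---------------------------------------------------------------------------

def ad_statistic(r: np.ndarray) -> float:
    """A^2 of a sample against the standard normal with known mean 0, sd 1."""
    u = np.sort(np.asarray(r, dtype=float))
    n = u.size
    if n < 1:
        raise ValueError("empty sample")
    logcdf = stats.norm.logcdf(u)
    logsf = stats.norm.logsf(u)
    i = np.arange(1, n + 1)
    return float(-n - np.sum((2 * i - 1) * (logcdf + logsf[::-1])) / n)


def ad_pvalue(a2: float) -> float:
    """Upper-tail p of the asymptotic A^2 distribution (Marsaglia & Marsaglia).

    For A^2 > 12 the asymptotic series underflows; 0.0 is returned (floor).
    """
    z = float(a2)
    if z <= 0:
        return 1.0
    if z > 12.0:
        return 0.0
    if z < 2.0:
        cdf = (z ** -0.5 * np.exp(-1.2337141 / z)
               * (2.00012 + (0.247105 - (0.0649821 - (0.0347962
                  - (0.011672 - 0.00168691 * z) * z) * z) * z) * z))
    else:
        cdf = np.exp(-np.exp(1.0776 - (2.30695 - (0.43424 - (0.082433
                     - (0.008056 - 0.0003146 * z) * z) * z) * z) * z))
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def anderson_darling(a: ScatteringCurve, b: ScatteringCurve,
                     small_n_warning: int = 8) -> tuple[float, float]:
    """A^2 of the standardized residuals vs the standard normal, with its
    asymptotic p-value."""
    import warnings

    r = residuals(a, b)
    if r.size < small_n_warning:
        warnings.warn(f"n={r.size} < {small_n_warning}: asymptotic "
                      "Anderson-Darling p-value is unreliable")
    a2 = ad_statistic(r)
    return a2, ad_pvalue(a2)


def datcmp(a: ScatteringCurve, b: ScatteringCurve) -> ComparisonResult:
    """All three pairwise statistics in one report."""
    chi2_red, chi2_p = reduced_chi2(a, b)
    C, cp = cormap(a, b)
    a2, ap = anderson_darling(a, b)
    return ComparisonResult(n=a.n, chi2_red=chi2_red, chi2_p=chi2_p,
                            cormap_C=C, cormap_p=cp, ad_A2=a2, ad_p=ap)


# ---------------------------------------------------------------------------
# parametric resampling
# ---------------------------------------------------------------------------

def resample_curve(curve: ScatteringCurve, n: int, scale: float = 1.0,
                   seed: int = 0) -> list[ScatteringCurve]:
    """n parametric replicates: I*_i ~ Normal(I_i, (scale * sigma_i)^2).

    The error column is carried over unchanged; ``scale`` inflates the sampling
    width to admit extra uncertainty beyond the recorded errors.
    """
    if curve.sigma is None:
        raise ValueError("resampling requires error estimates")
    if n < 1:
        raise ValueError("n must be >= 1")
    if scale < 0:
        raise ValueError("scale must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        I = curve.I + scale * curve.sigma * rng.standard_normal(curve.n)
        out.append(ScatteringCurve(s=curve.s, I=I, sigma=curve.sigma,
                                   scale=curve.scale,
                                   label=f"{curve.label}#resample{k}"))
    return out
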