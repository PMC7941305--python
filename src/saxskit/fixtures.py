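"""Closed-form synthetic scattering models: oracles and demo inputs.

Every generator here has an analytic or brute-force definition independent of
the numerical machinery it is used to test:

* solid sphere of radius R:  I(s)/I0 = [3 (sin x - x cos x)/x^3]^2, x = sR,
  with first zero at x ~ 4.493 (root of tan x = x), Rg = sqrt(3/5) R,
  p(r) proportional to r^2 (1 - 3u/4 + u^3/16), u = r/R, on [0, 2R];
* thin spherical shell:      I(s)/I0 = [sin(sR)/(sR)]^2;
* two-point dumbbell:        I(s)/I0 = (1 + sin(sd)/(sd)) / 2;
* uniform point clouds in a ball (mean squared radius 3R^2/5) for the Debye
  calculator, and Gaussian noise with recorded sigma for reduced 1D data.
"""

from __future__ import annotations

import numpy as np

from .realspace import PofR
from .sasio import AtomSet, ScatteringCurve

__all__ = [
    "sphere_curve",
    "shell_curve",
    "dumbbell_curve",
    "sphere_pofr",
    "sphere_points",
    "noisy_curve",
    "SPHERE_FIRST_ZERO_X",
]

#: first zero of the sphere form factor, the smallest positive root of tan x = x
SPHERE_FIRST_ZERO_X = 4.493409457909064


def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """3 (sin x - x cos x) / x^3, with the x -> 0 limit of 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    amp = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3
    return np.where(small, 1.0 - x ** 2 / 10.0, amp)


def sphere_curve(R: float, s_grid, i0: float = 1.0) -> ScatteringCurve:
    """Scattering of a homogeneous sphere of radius R (Angstrom); sigma absent."""
    if R <= 0:
        raise ValueError("R must be positive")
    s = np.asarray(s_grid, dtype=float)
    I = i0 * _sphere_amplitude(s * R) ** 2
    return ScatteringCurve(s=s, I=I, scale="relative", label=f"sphere(R={R})")


def shell_curve(R: float, s_grid, i0: float = 1.0) -> ScatteringCurve:
    """Infinitely thin spherical shell of radius R."""
    if R <= 0:
        raise ValueError("R must be positive")
    s = np.asarray(s_grid, dtype=float)
    I = i0 * np.sinc(s * R / np.pi) ** 2
    return ScatteringCurve(s=s, I=I, scale="relative", label=f"shell(R={R})")


def dumbbell_curve(d: float, s_grid, i0: float = 1.0) -> ScatteringCurve:
    """Two identical point scatterers at distance d."""
    if d <= 0:
        raise ValueError("d must be positive")
    s = np.asarray(s_grid, dtype=float)
    I = i0 * 0.5 * (1.0 + np.sinc(s * d / np.pi))
    return ScatteringCurve(s=s, I=I, scale="relative", label=f"dumbbell(d={d})")


def sphere_pofr(R: float, npoints: int = 201, i0: float = 1.0) -> PofR:
    """Closed-form distance distribution of a solid sphere, normalized so that
    4 pi int p dr = i0."""
    if R <= 0:
        raise ValueError("R must be positive")
    r = np.linspace(0.0, 2.0 * R, npoints)
    u = r / R
    gamma = 1.0 - 0.75 * u + u ** 3 / 16.0
    p = r ** 2 * gamma
    p[-1] = 0.0
    norm = np.trapezoid(p, r)
    p *= i0 / (4.0 * np.pi * norm)
    return PofR(r=r, p=p, dmax=2.0 * R)


def sphere_points(R: float, n: int, seed: int = 0) -> AtomSet:
    """n points uniform in the ball of radius R, labelled as carbons.

    Radial inverse-CDF sampling (r = R u^{1/3}) with isotropic directions;
    mean squared radius is 3 R^2 / 5.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if R <= 0:
        raise ValueError("R must be positive")
    rng = np.random.default_rng(seed)
    r = R * rng.random(n) ** (1.0 / 3.0)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    coords = v * r[:, None]
    return AtomSet(elements=("C",) * n, coords=coords,
                   occupancy=np.ones(n), label=f"ball(R={R}, n={n})")


def noisy_curve(curve: ScatteringCurve, noise: float = 0.02,
                floor: float = 0.01, seed: int = 0) -> ScatteringCurve:
    """Add Gaussian noise with a recorded sigma model.

    sigma_i = noise * (|I_i| + floor * max|I|): proportional noise with a
    small floor so sigma stays positive through intensity zeros.  ``noise=0``
    is the identity (with the sigma column still attached).
    """
    if noise < 0 or floor < 0:
        raise ValueError("noise and floor must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = noise * (np.abs(curve.I) + floor * np.max(np.abs(curve.I)))
    I = curve.I + sigma * rng.standard_normal(curve.n) if noise > 0 \
        else curve.I.copy()
    return ScatteringCurve(s=curve.s, I=I, sigma=sigma, scale=curve.scale,
                           label=f"{curve.label}+noise")
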