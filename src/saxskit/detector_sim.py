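"""Statistical simulation of 2D photon-counting detector images, and image algebra.

The forward model is purely statistical: given an absolute-scale 1D curve, the
expected count in pixel (i, j) is

    mu_ij = I_abs(s_ij) * c * Phi * t * T * eta * dOmega_ij

(concentration, flux, exposure time, transmission, detector efficiency, pixel
solid angle; implicit 1 cm beam path), and observed counts are independent
Poisson draws.  Systematic instrument effects — polarization, point-spread,
dead time, self-absorption — are deliberately not modelled; the goal is that
radially averaged simulated images carry the same *statistics* as measured data.

Flat-detector optics: a pixel at radial distance r from the beam center sees
scattering angle 2*theta = arctan(r/D) and solid angle
``(pixel_size^2 / D^2) cos^3(psi)`` with psi the off-normal angle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sasio import ScatteringCurve

__all__ = [
    "DetectorGeometry",
    "DetectorImage",
    "ExposureModel",
    "ExpectedImage",
    "pixel_to_s",
    "s_map",
    "solid_angle_map",
    "expected_image",
    "sample_image",
    "image_op",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Physical mapping pixel -> scattering vector.

    shape (rows, cols); pixel_size and sample-detector distance in mm;
    wavelength in Angstrom; beam_center (row, col) in fractional pixels and may
    lie outside the image.
    """

    shape: tuple[int, int]
    pixel_size: float
    distance: float
    wavelength: float
    beam_center: tuple[float, float]

    def __post_init__(self):
        if min(self.shape) < 1:
            raise ValueError("shape must be positive")
        if self.pixel_size <= 0 or self.distance <= 0 or self.wavelength <= 0:
            raise ValueError("pixel_size, distance and wavelength must be positive")


@dataclass(frozen=True)
class ExposureModel:
    """Photon budget of one exposure.

    flux photons/s, exposure s, concentration mg/ml, transmission and detector
    efficiency in [0, 1].
    """

    flux: float
    exposure: float
    concentration: float
    transmission: float = 1.0
    efficiency: float = 1.0

    def __post_init__(self):
        for name in ("flux", "exposure", "concentration", "transmission",
                     "efficiency"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.transmission > 1 or self.efficiency > 1:
            raise ValueError("transmission and efficiency must be <= 1")

    @property
    def photon_factor(self) -> float:
        """c * Phi * t * T * eta — expected counts per (cm^-1 sr)."""
        return (self.concentration * self.flux * self.exposure
                * self.transmission * self.efficiency)


@dataclass(frozen=True)
class DetectorImage:
    """Integer photon counts plus geometry, validity mask and optional
    per-pixel normalisation (expected counts per unit absolute intensity)."""

    counts: np.ndarray
    geometry: DetectorGeometry
    mask: np.ndarray
    norm: np.ndarray | None = None
    clipped: bool = False

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be integer")
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != counts.shape:
            raise ValueError("mask shape must equal counts shape")
        if tuple(counts.shape) != tuple(self.geometry.shape):
            raise ValueError("counts shape must equal geometry shape")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "mask", mask)
        if self.norm is not None:
            norm = np.asarray(self.norm, dtype=float)
            if norm.shape != counts.shape:
                raise ValueError("norm shape must equal counts shape")
            object.__setattr__(self, "norm", norm)


@dataclass(frozen=True)
class ExpectedImage:
    """Noise-free per-pixel expectations, ready for Poisson sampling."""

    mu: np.ndarray
    geometry: DetectorGeometry
    mask: np.ndarray
    norm: np.ndarray


def _radius_mm(geometry: DetectorGeometry, i, j) -> np.ndarray:
    di = (np.asarray(i, dtype=float) - geometry.beam_center[0])
    dj = (np.asarray(j, dtype=float) - geometry.beam_center[1])
    return geometry.pixel_size * np.hypot(di, dj)


def pixel_to_s(geometry: DetectorGeometry, i, j) -> np.ndarray:
    """Momentum transfer (1/A) of pixel (row i, col j).

    s = (4 pi / lambda) sin(theta), theta = arctan(r/D)/2.
    """
    r = _radius_mm(geometry, i, j)
    theta = 0.5 * np.arctan2(r, geometry.distance)
    return 4.0 * np.pi / geometry.wavelength * np.sin(theta)


def s_map(geometry: DetectorGeometry) -> np.ndarray:
    """Per-pixel s over the whole detector (pixel centers)."""
    ii, jj = np.meshgrid(np.arange(geometry.shape[0]),
                         np.arange(geometry.shape[1]), indexing="ij")
    return pixel_to_s(geometry, ii, jj)


def solid_angle_map(geometry: DetectorGeometry) -> np.ndarray:
    """Per-pixel solid angle, sr: (pix^2/D^2) cos^3(psi), flat detector."""
    ii, jj = np.meshgrid(np.arange(geometry.shape[0]),
                         np.arange(geometry.shape[1]), indexing="ij")
    r = _radius_mm(geometry, ii, jj)
    cos_psi = geometry.distance / np.hypot(geometry.distance, r)
    return (geometry.pixel_size / geometry.distance) ** 2 * cos_psi ** 3


def expected_image(curve: ScatteringCurve, geometry: DetectorGeometry,
                   exposure: ExposureModel,
                   mask: np.ndarray | None = None) -> ExpectedImage:
    """Expected (noise-free) counts for every pixel from an absolute-scale curve.

    Pixels whose s lies outside the curve's range are masked with a warning.
    The returned object also carries the per-pixel normalisation
    ``photon_factor * dOmega`` used later to undo the photon budget.
    """
    if curve.scale != "absolute":
        raise ValueError("expected_image requires an absolute-scale curve")
    smap = s_map(geometry)
    if mask is None:
        mask = np.ones(geometry.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(geometry.shape):
            raise ValueError("mask shape must equal geometry shape")
        mask = mask.copy()
    out_of_range = (smap < curve.s[0]) | (smap > curve.s[-1])
    n_out = int(np.count_nonzero(out_of_range & mask))
    if n_out:
        warnings.warn(f"{n_out} pixels outside the curve s-range were masked")
        mask &= ~out_of_range
    norm = exposure.photon_factor * solid_angle_map(geometry)
    mu = np.where(mask, np.interp(smap, curve.s, curve.I) * norm, 0.0)
    return ExpectedImage(mu=mu, geometry=geometry, mask=mask, norm=norm)


def sample_image(expected: ExpectedImage, seed: int) -> DetectorImage:
    """One Poisson realization of an ExpectedImage; fully seed-deterministic."""
    if np.any(expected.mu < 0):
        raise ValueError("expected counts must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected.mu).astype(np.int64)
    counts[~expected.mask] = 0
    return DetectorImage(counts=counts, geometry=expected.geometry,
                         mask=expected.mask.copy(), norm=expected.norm)


def _require_binary(img: DetectorImage, what: str) -> None:
    if np.any(img.counts > 1):
        raise ValueError(f"{what} requires binary operands (0/1 counts)")


def image_op(a: DetectorImage, b, op: str) -> DetectorImage:
    """Elementwise image arithmetic and mask logic.

    ``add``/``sub`` on equally shaped count images (sub clamps at 0 and flags
    the result); ``and``/``or``/``xor`` on binary images; ``apply_mask``
    permanently zeroes pixels where the mask operand is 0.
    """
    if op in ("add", "sub", "and", "or", "xor"):
        if not isinstance(b, DetectorImage):
            raise TypeError("second operand must be a DetectorImage")
        if a.counts.shape != b.counts.shape:
            raise ValueError("shape mismatch")
        mask = a.mask & b.mask
        if op == "add":
            counts = a.counts + b.counts
            # summed exposures: normalisations add
            norm = None
            if a.norm is not None and b.norm is not None:
                norm = a.norm + b.norm
            return DetectorImage(counts, a.geometry, mask, norm)
        if op == "sub":
            diff = a.counts - b.counts
            clipped = bool(np.any(diff < 0))
            if clipped:
                warnings.warn("subtraction clamped negative counts to 0")
            return DetectorImage(np.maximum(diff, 0), a.geometry, mask,
                                 None, clipped=clipped)
        _require_binary(a, f"op {op!r}")
        _require_binary(b, f"op {op!r}")
        x, y = a.counts.astype(bool), b.counts.astype(bool)
        out = {"and": x & y, "or": x | y, "xor": x ^ y}[op]
        return DetectorImage(out.astype(np.int64), a.geometry, mask, None)
    if op == "apply_mask":
        m = b.counts.astype(bool) if isinstance(b, DetectorImage) else \
            np.asarray(b, dtype=bool)
        if m.shape != a.counts.shape:
            raise ValueError("shape mismatch")
        counts = np.where(m, a.counts, 0)
        return DetectorImage(counts, a.geometry, a.mask & m, a.norm)
    raise ValueError(f"unknown op {op!r}")
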