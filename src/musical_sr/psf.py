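"""Parametric point-spread-function models.

The imaging model throughout this package is a radially symmetric 2D
intensity PSF, peak-normalized to 1 at radius 0.  Two kinds are supported:

* ``airy`` — the in-focus diffraction pattern of a circular aperture,
  ``[2 J1(v) / v]**2`` with ``v = 2*pi*NA*r / wavelength``;
* ``gaussian`` — ``exp(-r**2 / (2*sigma**2))`` with ``sigma`` chosen so the
  Gaussian FWHM equals the Airy FWHM for the same optics.

Conventions: pixel centers sit at integer coordinates; positions are
continuous, 0-based, in pixel units, and are converted to nanometres only
inside :func:`evaluate_psf` via ``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import j1, jn_zeros

__all__ = [
    "PSFModel",
    "evaluate_psf",
    "sample_psf_vector",
    "psf_fwhm",
    "airy_first_zero",
    "GAUSSIAN_FWHM_FACTOR",
]

#: FWHM of a unit-sigma Gaussian: 2*sqrt(2*ln 2).
GAUSSIAN_FWHM_FACTOR = float(2.0 * np.sqrt(2.0 * np.log(2.0)))

# Half-maximum point of [2 J1(v)/v]^2, solved once at import (the function
# is monotone on [0, first zero of J1)).
_AIRY_V_HALF = brentq(
    lambda v: (2.0 * j1(v) / v) ** 2 - 0.5, 1e-6, float(jn_zeros(1, 1)[0])
)


@dataclass(frozen=True)
class PSFModel:
    """Diffraction-limited PSF parameterization.

    Parameters
    ----------
    model_kind
        ``"airy"`` or ``"gaussian"``.
    numerical_aperture
        Objective NA (dimensionless, > 0).
    emission_wavelength
        Emission wavelength in nm (> 0).
    pixel_size
        Sample-plane size of one camera pixel in nm (> 0).
    """

    model_kind: str = "airy"
    numerical_aperture: float = 1.49
    emission_wavelength: float = 593.0
    pixel_size: float = 65.0

    def __post_init__(self) -> None:
        if self.model_kind not in ("airy", "gaussian"):
            raise ValueError(f"unknown PSF kind: {self.model_kind!r}")
        for name in ("numerical_aperture", "emission_wavelength", "pixel_size"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be positive and finite, got {value}")

    @property
    def airy_fwhm_nm(self) -> float:
        """FWHM of the Airy profile for these optics (closed form in v)."""
        return 2.0 * _AIRY_V_HALF * self.emission_wavelength / (
            2.0 * np.pi * self.numerical_aperture
        )

    @property
    def gaussian_sigma_nm(self) -> float:
        """Sigma of the FWHM-matched Gaussian approximation, in nm."""
        return self.airy_fwhm_nm / GAUSSIAN_FWHM_FACTOR


def evaluate_psf(model: PSFModel, radius):
    """Peak-normalized PSF intensity at radial distance ``radius`` (nm).

    Accepts scalars or arrays; returns values in [0, 1] with the limit 1 at
    radius 0.
    """
    r = np.asarray(radius, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    if model.model_kind == "airy":
        v = 2.0 * np.pi * model.numerical_aperture * r / model.emission_wavelength
        # J1(v)/v -> 1/2 as v -> 0; substitute the limit where v is tiny.
        with np.errstate(invalid="ignore", divide="ignore"):
            amp = np.where(v > 1e-12, 2.0 * j1(v) / np.where(v > 1e-12, v, 1.0), 1.0)
        out = amp**2
    else:
        sigma = model.gaussian_sigma_nm
        out = np.exp(-(r**2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


def sample_psf_vector(model: PSFModel, test_point, window_pixels) -> np.ndarray:
    """Unit-norm steering vector of the PSF centred at a subpixel test point.

    Parameters
    ----------
    test_point
        ``(y, x)`` continuous position in pixel units.
    window_pixels
        Ordered ``(N, 2)`` array-like of integer ``(y, x)`` pixel centers.

    Returns
    -------
    numpy.ndarray
        Length-N vector: the PSF evaluated at each pixel-center distance
        (converted to nm with ``model.pixel_size``), scaled to unit
        Euclidean norm, in ``window_pixels`` order.
    """
    pixels = np.atleast_2d(np.asarray(window_pixels, dtype=float))
    if pixels.size == 0:
        raise ValueError("window_pixels must be non-empty")
    point = np.asarray(test_point, dtype=float)
    if not np.all(np.isfinite(point)):
        raise ValueError("test_point must be finite")
    dist_nm = np.hypot(pixels[:, 0] - point[0], pixels[:, 1] - point[1])
    dist_nm *= model.pixel_size
    raw = evaluate_psf(model, dist_nm)
    norm = np.linalg.norm(raw)
    if norm == 0.0:
        raise ValueError(
            "degenerate steering vector: test point too far from the window"
        )
    return raw / norm


def psf_fwhm(model: PSFModel, tol_nm: float = 0.01) -> float:
    """Full width at half maximum of the radial profile, in nm.

    The half-max crossing is bracketed on [0, first zero] and refined by
    bisection (scipy's Brent method) to ``tol_nm``.
    """
    if model.model_kind == "gaussian":
        return GAUSSIAN_FWHM_FACTOR * model.gaussian_sigma_nm
    upper = airy_first_zero(model)
    xtol = min(tol_nm / 2.0, 1e-9 * upper)
    half = brentq(
        lambda r: evaluate_psf(model, r) - 0.5, 1e-9, upper, xtol=xtol
    )
    return 2.0 * half


def airy_first_zero(model: PSFModel) -> float:
    """Radius (nm) of the first dark ring: j_{1,1}/(2*pi) * lambda/NA."""
    j11 = float(jn_zeros(1, 1)[0])
    return j11 * model.emission_wavelength / (2.0 * np.pi * model.numerical_aperture)
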