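"""Lognormal emission band shape and wavelength/wavenumber conversions.

Tryptophan emission bands are asymmetric; the standard empirical shape for
time-resolved Stokes-shift work is the lognormal ("Maroncelli–Fleming") form
parameterised by peak position ``nu_p`` (cm⁻¹), full width ``width`` (cm⁻¹),
and a dimensionless asymmetry ``gamma``:

    alpha(nu) = 2 * gamma * (nu - nu_p) / width
    g(nu)     = h * exp(-ln2 * (ln(1 + alpha) / gamma)^2)   for 1 + alpha > 0
    g(nu)     = 0                                            otherwise

``gamma -> 0`` recovers a Gaussian of FWHM ``width``.  Negative ``gamma``
skews the band toward low wavenumber (the red tail typical of emission).

Spectra measured per nm must be converted to the energy axis with the
Jacobian |dnu/dlambda|:  I(nu) = I(lambda) * lambda^2 / 1e7.
"""

from __future__ import annotations

import numpy as np
import lmfit

__all__ = [
    "nm_to_wavenumber",
    "wavenumber_to_nm",
    "intensity_nm_to_wavenumber",
    "intensity_wavenumber_to_nm",
    "lognormal",
    "lognormal_peak_series",
    "lognormal_support",
    "fit_lognormal",
]

_LN2 = np.log(2.0)


def nm_to_wavenumber(lam_nm):
    """Vacuum wavenumber (cm⁻¹) from wavelength (nm)."""
    return 1.0e7 / np.asarray(lam_nm, dtype=float)


def wavenumber_to_nm(nu_cm):
    """Wavelength (nm) from vacuum wavenumber (cm⁻¹)."""
    return 1.0e7 / np.asarray(nu_cm, dtype=float)


def intensity_nm_to_wavenumber(lam_nm, intensity_lam):
    """Convert per-nm intensity to per-cm⁻¹ intensity (Jacobian λ²/10⁷)."""
    lam = np.asarray(lam_nm, dtype=float)
    return np.asarray(intensity_lam, dtype=float) * lam**2 / 1.0e7


def intensity_wavenumber_to_nm(lam_nm, intensity_nu):
    """Convert per-cm⁻¹ intensity to per-nm intensity (Jacobian 10⁷/λ²)."""
    lam = np.asarray(lam_nm, dtype=float)
    return np.asarray(intensity_nu, dtype=float) * 1.0e7 / lam**2


def lognormal(nu, height: float, peak: float, width: float, gamma: float):
    """Evaluate the lognormal band at wavenumber(s) ``nu`` (cm⁻¹)."""
    nu = np.asarray(nu, dtype=float)
    if width <= 0:
        raise ValueError("width must be positive")
    if abs(gamma) < 1.0e-8:
        return height * np.exp(-_LN2 * (2.0 * (nu - peak) / width) ** 2)
    alpha = 2.0 * gamma * (nu - peak) / width
    out = np.zeros_like(nu)
    ok = alpha > -1.0
    out[ok] = height * np.exp(-_LN2 * (np.log1p(alpha[ok]) / gamma) ** 2)
    return out


def lognormal_peak_series(nu: float, peaks, width: float, gamma: float):
    """Band intensity at one fixed wavenumber for an array of peak positions.

    Unit height; used to evaluate a relaxing band (time-dependent peak) at a
    detection wavelength.
    """
    peaks = np.asarray(peaks, dtype=float)
    if abs(gamma) < 1.0e-8:
        return np.exp(-_LN2 * (2.0 * (nu - peaks) / width) ** 2)
    alpha = 2.0 * gamma * (nu - peaks) / width
    out = np.zeros_like(peaks)
    ok = alpha > -1.0
    out[ok] = np.exp(-_LN2 * (np.log1p(alpha[ok]) / gamma) ** 2)
    return out


def lognormal_support(peak: float, width: float, gamma: float):
    """(nu_lo, nu_hi) support of the band; one side is infinite for gamma != 0."""
    if abs(gamma) < 1.0e-8:
        return (-np.inf, np.inf)
    edge = peak - width / (2.0 * gamma)
    return (edge, np.inf) if gamma > 0 else (-np.inf, edge)


def _residual(params, nu, intensity, weights):
    model = lognormal(
        nu,
        params["height"].value,
        params["peak"].value,
        params["width"].value,
        params["gamma"].value,
    )
    return (model - intensity) * weights


def fit_lognormal(nu, intensity, weights=None, init=None) -> lmfit.minimizer.MinimizerResult:
    """Least-squares lognormal fit of one emission slice.

    Parameters
    ----------
    nu, intensity
        Sample points (cm⁻¹) and per-cm⁻¹ intensities.
    weights
        Optional per-point weights (default: uniform).
    init
        Optional dict overriding the moment-based initial guess for any of
        ``height``, ``peak``, ``width``, ``gamma``.

    Returns the lmfit result; fitted values are in ``result.params``.
    """
    nu = np.asarray(nu, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if nu.size < 4:
        raise ValueError("need at least 4 points to fit a 4-parameter band")
    order = np.argsort(nu)
    nu, intensity = nu[order], intensity[order]
    w = np.ones_like(nu) if weights is None else np.asarray(weights, float)[order]

    clipped = np.clip(intensity, 0.0, None)
    i_max = int(np.argmax(clipped))
    guess = {
        "height": max(clipped[i_max], 1.0e-300),
        "peak": nu[i_max],
        "width": 5000.0,
        "gamma": -0.2,
    }
    # refine the peak guess by a parabola through the top three points
    if 0 < i_max < nu.size - 1:
        x = nu[i_max - 1 : i_max + 2]
        y = clipped[i_max - 1 : i_max + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        if denom != 0:
            a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
            b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
            if a < 0:
                guess["peak"] = float(np.clip(-b / (2 * a), nu[0] - 2000, nu[-1] + 2000))
    if init:
        guess.update(init)

    params = lmfit.Parameters()
    params.add("height", value=guess["height"], min=0.0)
    params.add("peak", value=guess["peak"], min=nu[0] - 5000.0, max=nu[-1] + 5000.0)
    params.add("width", value=guess["width"], min=200.0, max=30000.0)
    params.add("gamma", value=guess["gamma"], min=-1.0, max=1.0)
    return lmfit.minimize(
        _residual, params, args=(nu, clipped, w), method="least_squares"
    )
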