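"""Exponential decay kinetics with Gaussian instrument-response convolution.

All analytic signal models in this package are sums of exponentials (decays,
rises, and a constant floor) convolved with a Gaussian instrument response
function (IRF).  The convolution has a closed form in terms of the scaled
complementary error function, which stays numerically stable for both the
femtosecond-upconversion regime (IRF ~ 0.15 ps, taus down to ~0.1 ps) and the
TCSPC regime (IRF ~ 600 ps, taus up to tens of ns).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfc, erfcx

__all__ = [
    "fwhm_to_sigma",
    "exp_conv_gauss",
    "step_conv_gauss",
    "multiexp",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation."""
    return float(fwhm) / _FWHM_PER_SIGMA


def exp_conv_gauss(t, tau: float, sigma: float):
    """H(t)·exp(-t/tau) convolved with a unit-area Gaussian of width ``sigma``.

    Uses the stable form ``0.5 * erfcx(z) * exp(-t^2 / 2 sigma^2)`` with
    ``z = (sigma/tau - t/sigma) / sqrt(2)``, which avoids overflow of the
    textbook expression when ``sigma >> tau`` or ``t >> tau``.

    For ``sigma == 0`` the un-broadened causal exponential is returned.
    """
    t = np.asarray(t, dtype=float)
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0.0:
        out = np.zeros_like(t)
        mask = t >= 0
        out[mask] = np.exp(-t[mask] / tau)
        return out
    z = (sigma / tau - t / sigma) / np.sqrt(2.0)
    out = np.empty_like(t)
    pos = z > 0
    # z > 0 (early times): erfcx form avoids overflow of exp(sigma^2/2tau^2)
    out[pos] = 0.5 * erfcx(z[pos]) * np.exp(-0.5 * (t[pos] / sigma) ** 2)
    # z <= 0 (t > sigma^2/tau): erfc is O(1) and the plain exponent is safe
    neg = ~pos
    out[neg] = (
        0.5
        * erfc(z[neg])
        * np.exp(0.5 * (sigma / tau) ** 2 - t[neg] / tau)
    )
    return out


def step_conv_gauss(t, sigma: float):
    """Heaviside step convolved with a unit-area Gaussian (the tau→∞ limit)."""
    t = np.asarray(t, dtype=float)
    if sigma == 0.0:
        return (t >= 0).astype(float)
    return 0.5 * erfc(-t / (sigma * np.sqrt(2.0)))


def multiexp(t, amplitudes, taus):
    """Plain multiexponential  Σ_k a_k exp(-t/tau_k)  evaluated for t >= 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for a, tau in zip(amplitudes, taus):
        out += a * np.exp(-np.clip(t, 0.0, None) / tau)
    return out
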