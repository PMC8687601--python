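"""Reconstruction of time-resolved emission spectra from transient fits.

The per-wavelength multiexponential fits only fix relative kinetics; scaling
each fitted model so that its analytic time integral equals the steady-state
intensity at that wavelength puts all wavelengths on a common intensity
scale.  Evaluating the scaled (IRF-deconvolved) models at a common delay then
yields one emission spectrum per delay — the femtosecond-resolved emission
spectra (FRES).  Each slice is converted to the energy axis
(nu = 10^7/lambda cm⁻¹, with the lambda²/10^7 Jacobian on the intensity) and
fitted with a lognormal band; the fitted peak positions trace the spectral
relaxation nu_p(t) that feeds the solvation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import bands
from .transients import DecayFit

__all__ = ["Spectrum", "FRESlice", "scale_to_steady_state", "build_fres",
           "peak_trajectory", "default_slice_times"]


@dataclass
class Spectrum:
    """A steady-state emission spectrum sampled per nm."""

    wavelength: np.ndarray
    intensity: np.ndarray
    flags: list = field(default_factory=list)
    _peak_nm: float | None = None

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < -1e-12 * np.max(np.abs(self.intensity))):
            raise ValueError("steady-state intensities must be non-negative")

    @property
    def peak_nm(self) -> float:
        """Peak wavelength of the *fitted* band (lognormal in energy space).

        The band is fitted in wavenumber space and mapped back to the
        wavelength axis (Jacobian included) before locating the maximum, so
        the peak is not tied to the sampling grid.
        """
        if self._peak_nm is None:
            nu = bands.nm_to_wavenumber(self.wavelength)
            i_nu = bands.intensity_nm_to_wavenumber(self.wavelength, self.intensity)
            res = bands.fit_lognormal(nu, i_nu)
            p = res.params
            lam_dense = np.linspace(
                float(self.wavelength.min()), float(self.wavelength.max()), 4001
            )
            band_lam = bands.intensity_wavenumber_to_nm(
                lam_dense,
                bands.lognormal(
                    bands.nm_to_wavenumber(lam_dense),
                    p["height"].value, p["peak"].value,
                    p["width"].value, p["gamma"].value,
                ),
            )
            j = int(np.argmax(band_lam))
            # parabolic refinement off the dense grid
            if 0 < j < lam_dense.size - 1:
                y0, y1, y2 = band_lam[j - 1 : j + 2]
                denom = y0 - 2 * y1 + y2
                shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
                self._peak_nm = float(lam_dense[j] + shift * (lam_dense[1] - lam_dense[0]))
            else:
                self._peak_nm = float(lam_dense[j])
        return self._peak_nm

    def at(self, lam) -> np.ndarray:
        """Linear interpolation of the sampled intensities."""
        return np.interp(np.asarray(lam, dtype=float), self.wavelength, self.intensity)


@dataclass
class FRESlice:
    """One reconstructed emission spectrum at delay ``t`` with its band fit."""

    t: float
    nu: np.ndarray  # cm^-1
    intensity: np.ndarray  # per cm^-1
    peak: float  # fitted nu_p, cm^-1
    width: float
    gamma: float
    height: float
    gof: float
    flags: list = field(default_factory=list)


def scale_to_steady_state(fits: list, ss: Spectrum) -> list:
    """Rescale each fit so its analytic time integral matches the steady state.

    Wavelengths where the steady-state intensity vanishes (or the fit
    integral is non-positive) are excluded with a warning.
    """
    lam_lo, lam_hi = float(ss.wavelength.min()), float(ss.wavelength.max())
    out = []
    for fit in fits:
        if not (lam_lo <= fit.wavelength <= lam_hi):
            raise ValueError(
                f"fit wavelength {fit.wavelength} nm outside steady-state support"
            )
        target = float(ss.at(fit.wavelength))
        integral = fit.integral()
        if target <= 0.0 or integral <= 0.0:
            warnings.warn(
                f"excluding {fit.wavelength} nm: zero steady-state intensity "
                "or non-positive fit integral",
                UserWarning,
            )
            continue
        out.append(fit.scaled(target / integral))
    return out


def default_slice_times(window: float = 3000.0, n: int = 60, t_min: float = 0.05):
    """Log-spaced FRES delays across the window, with t = 0 prepended."""
    return np.concatenate([[0.0], np.geomspace(t_min, window, n)])


def build_fres(scaled_fits: list, times=None) -> list:
    """Evaluate scaled fits at each delay and fit a lognormal per slice.

    The fitted models are evaluated IRF-deconvolved, so the t = 0 slice is the
    time-zero emission spectrum.  Slices whose band fit fails to converge are
    flagged; :func:`peak_trajectory` interpolates over them.
    """
    if len(scaled_fits) < 5:
        raise ValueError("need at least 5 wavelengths for a stable band fit")
    if times is None:
        times = default_slice_times()
    lam = np.array([f.wavelength for f in scaled_fits])
    nu = bands.nm_to_wavenumber(lam)
    slices = []
    init = None
    for t in np.asarray(times, dtype=float):
        i_lam = np.array([f.model(np.array([t]), deconvolved=True)[0] for f in scaled_fits])
        i_nu = bands.intensity_nm_to_wavenumber(lam, i_lam)
        flags = []
        if np.any(i_nu < 0):
            flags.append("negative_intensity_clipped")
            i_nu = np.clip(i_nu, 0.0, None)
        try:
            res = bands.fit_lognormal(nu, i_nu, init=init)
            ok = res.success and np.isfinite(res.params["peak"].value)
        except Exception:
            ok = False
        if not ok:
            slices.append(
                FRESlice(t=float(t), nu=nu, intensity=i_nu, peak=np.nan,
                         width=np.nan, gamma=np.nan, height=np.nan,
                         gof=np.nan, flags=flags + ["fit_failed"])
            )
            continue
        p = res.params
        # warm-start the next (neighbouring) slice
        init = {k: p[k].value for k in ("height", "peak", "width", "gamma")}
        slices.append(
            FRESlice(
                t=float(t), nu=nu, intensity=i_nu,
                peak=float(p["peak"].value), width=float(p["width"].value),
                gamma=float(p["gamma"].value), height=float(p["height"].value),
                gof=float(res.redchi), flags=flags,
            )
        )
    return slices


def peak_trajectory(slices: list):
    """(t, nu_p) arrays from slices, interpolating across flagged fits."""
    t = np.array([s.t for s in slices])
    peak = np.array([s.peak for s in slices])
    bad = ~np.isfinite(peak)
    if bad.all():
        raise RuntimeError("every FRES slice fit failed")
    if bad.any():
        peak[bad] = np.interp(t[bad], t[~bad], peak[~bad])
    return t, peak
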