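"""Solvation correlation function, its decomposition, and solvation speeds.

The solvation correlation function normalises the emission-peak relaxation,

    c(t) = (nu_p(t) - nu_inf) / (nu_p(0) - nu_inf),

so c(0) = 1 and c -> 0 at equilibrium.  A multiexponential fit partitions the
total dynamic Stokes shift into components (tau_Si, f_i) where f_i is the
fraction of the shift relaxing on timescale tau_Si.  Each component carries a
solvation energy dE_i = f_i * total_shift (cm⁻¹) and a solvation speed
S_i = dE_i / tau_Si (cm⁻¹/ps), the rate of energy relaxation of that process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = ["SolvationResult", "DegenerateShiftError", "correlation_function",
           "fit_correlation", "solvation_speeds"]


class DegenerateShiftError(ValueError):
    """nu_p(0) equals nu_inf: no dynamic Stokes shift to analyse."""


@dataclass
class SolvationResult:
    """c(t) with its fitted decomposition and derived energies/speeds."""

    t: np.ndarray
    c: np.ndarray
    nu0: float  # cm^-1, time-zero peak
    nu_inf: float  # cm^-1, relaxed peak
    components: list = field(default_factory=list)  # [(tau_ps, fraction)]
    delta_e: list = field(default_factory=list)  # cm^-1 per component
    speeds: list = field(default_factory=list)  # cm^-1 / ps per component
    total_shift: float | None = None  # cm^-1 used for the energy partition
    gof: float | None = None
    flags: list = field(default_factory=list)

    @property
    def taus(self):
        return [tau for tau, _ in self.components]

    @property
    def fractions(self):
        return [f for _, f in self.components]


def correlation_function(t, nu_p, nu_inf=None, plateau_fraction: float = 0.1):
    """Build c(t) from a peak trajectory.

    Parameters
    ----------
    t, nu_p
        Delay times (ps, first point must be <= 0.1 ps so the time-zero peak
        is sampled) and fitted emission peaks (cm⁻¹).
    nu_inf
        Relaxed peak.  ``None`` (default) estimates it as the mean of nu_p
        over the last decade of the window (the plateau); a number uses that
        value directly (e.g. a steady-state-derived peak).
    """
    t = np.asarray(t, dtype=float)
    nu_p = np.asarray(nu_p, dtype=float)
    if t[0] > 0.1:
        raise ValueError("nu_p(t) must sample early times (first point <= 0.1 ps)")
    flags = []
    if nu_inf is None:
        plateau = t >= plateau_fraction * t[-1]
        nu_inf = float(np.mean(nu_p[plateau]))
        flags.append("nu_inf_from_plateau")
    nu0 = float(nu_p[0])
    # sub-0.5 cm^-1 shifts are far below what peak fitting can resolve
    if abs(nu0 - nu_inf) < max(1.0e-9 * abs(nu0), 0.5):
        raise DegenerateShiftError(
            "nu_p(0) equals nu_inf; the transient spectra show no Stokes shift"
        )
    c = (nu_p - nu_inf) / (nu0 - nu_inf)
    return SolvationResult(
        t=t, c=c, nu0=nu0, nu_inf=float(nu_inf),
        total_shift=nu0 - float(nu_inf), flags=flags,
    )


def _multiexp(t, amps, taus):
    out = np.zeros_like(t)
    for a, tau in zip(amps, taus):
        out += a * np.exp(-t / tau)
    return out


def fit_correlation(
    result: SolvationResult,
    n_components: int,
    weights=None,
    tau_bounds=(0.01, 1000.0),
    n_starts: int = 3,
) -> SolvationResult:
    """Fit c(t) with ``n_components`` exponentials (non-negative amplitudes).

    Components are reported sorted by ascending tau with fractions normalised
    to sum to one.  Multi-start initialisation over log-spaced taus; a
    non-converged fit is flagged, never silent.
    """
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be in 1..3")
    t, c = result.t, result.c
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)

    def resid(params):
        amps = [params[f"a{i}"].value for i in range(n_components)]
        taus = [params[f"tau{i}"].value for i in range(n_components)]
        return (_multiexp(t, amps, taus) - c) * w

    best = None
    for shift in np.linspace(-0.5, 0.5, n_starts):
        params = lmfit.Parameters()
        inits = np.geomspace(0.5, 50.0, n_components) * 10.0**shift
        for i in range(n_components):
            params.add(f"a{i}", value=1.0 / n_components, min=0.0, max=2.0)
            params.add(
                f"tau{i}", value=float(inits[i]),
                min=tau_bounds[0], max=tau_bounds[1],
            )
        try:
            res = lmfit.minimize(resid, params, method="least_squares",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("correlation-function fit failed from every start")
    if not best.success:
        result.flags.append("non_convergence")

    pairs = sorted(
        (
            (float(best.params[f"tau{i}"].value), float(best.params[f"a{i}"].value))
            for i in range(n_components)
        ),
        key=lambda p: p[0],
    )
    total_amp = sum(a for _, a in pairs)
    if total_amp <= 0:
        raise RuntimeError("fitted amplitudes vanished")
    result.components = [(tau, a / total_amp) for tau, a in pairs]
    result.gof = float(best.redchi)
    return result


def solvation_speeds(result: SolvationResult, total_shift: float | None = None) -> SolvationResult:
    """Attach energies dE_i = f_i * total and speeds S_i = dE_i / tau_Si.

    ``total_shift`` defaults to the measured nu_p(0) - nu_inf; an override is
    accepted when the energy scale comes from elsewhere (e.g. a literature
    total back-derived from reported speeds).
    """
    if total_shift is None:
        total_shift = result.nu0 - result.nu_inf
    if total_shift <= 0:
        raise ValueError("total_shift must be positive")
    if not result.components:
        raise ValueError("fit the correlation function before computing speeds")
    result.total_shift = float(total_shift)
    result.delta_e = [f * total_shift for _, f in result.components]
    result.speeds = [
        (f * total_shift) / tau for tau, f in result.components
    ]
    return result
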