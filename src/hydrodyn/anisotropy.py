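"""Fluorescence anisotropy: r(t), the four-component model, and cone analysis.

From a polarized transient pair, r(t) = (I_par - g I_perp)/(I_par + 2 g I_perp).
The decay is modelled with four components: a sub-100-fs internal-conversion
drop (tau_IC, the 1Lb -> 1La electronic jump of tryptophan), two
wobbling-in-cone motions (tau_W2, tau_W3), and a constant floor beta_T from
whole-complex tumbling, which is far slower than the fluorescence lifetime
and therefore does not decay within either window.

Because the detected intensities are lifetime-weighted, the anisotropy
measured through a broad IRF is conv(K·r)/conv(K), not conv(r); both
numerator and denominator are sums of exponentials, so the joint
(upconversion + TCSPC) fit model is analytic in the Gaussian IRF widths.

The wobbling amplitudes are translated into cone semiangles with the
sequential (nested) wobbling-in-cone decomposition, and each motion gets an
angular speed omega_i = theta_i / tau_Wi (deg/ps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

from . import cones
from .kinetics import exp_conv_gauss, fwhm_to_sigma
from .transients import Transient

__all__ = ["AnisotropyResult", "compute_r", "fit_anisotropy",
           "cone_semiangle", "angular_speeds"]


@dataclass
class AnisotropyResult:
    """r(t) for one window, later augmented with the fitted decomposition."""

    t: np.ndarray
    r: np.ndarray
    sigma: np.ndarray | None = None
    g_factor: float = 1.0
    window: str = "upconversion"
    irf_fwhm: float = 0.0
    components: dict = field(default_factory=dict)  # name -> (beta, tau or None)
    theta: dict = field(default_factory=dict)  # cone name -> semiangle (deg)
    omega: dict = field(default_factory=dict)  # cone name -> deg/ps
    convention: str = "nested"
    stderr: dict = field(default_factory=dict)
    gof: float | None = None
    flags: list = field(default_factory=list)


def compute_r(parallel: Transient, perpendicular: Transient, g: float = 1.0) -> AnisotropyResult:
    """Anisotropy from a polarized pair, with per-point error propagation.

    Grids are matched by linear resampling of the perpendicular channel if
    needed; points where the total intensity is non-positive are masked out
    with a warning.
    """
    if g <= 0:
        raise ValueError("g factor must be positive")
    t = parallel.t
    i_par = parallel.intensity
    if perpendicular.t.size == t.size and np.allclose(perpendicular.t, t):
        i_perp = perpendicular.intensity
        s_perp = perpendicular.sigma
    else:
        i_perp = np.interp(t, perpendicular.t, perpendicular.intensity)
        s_perp = (
            np.interp(t, perpendicular.t, np.broadcast_to(perpendicular.sigma, perpendicular.t.shape))
            if perpendicular.sigma is not None
            else None
        )
    den = i_par + 2.0 * g * i_perp
    num = i_par - g * i_perp
    keep = den > 0
    if not keep.all():
        warnings.warn(
            f"masking {np.sum(~keep)} points with non-positive total intensity",
            UserWarning,
        )
    r = num[keep] / den[keep]
    sigma_r = None
    if parallel.sigma is not None and s_perp is not None:
        s_par = np.broadcast_to(parallel.sigma, t.shape)[keep]
        s_pp = np.broadcast_to(s_perp, t.shape)[keep]
        d, n = den[keep], num[keep]
        dr_dpar = (d - n) / d**2
        dr_dperp = (-g * d - 2.0 * g * n) / d**2
        sigma_r = np.sqrt((dr_dpar * s_par) ** 2 + (dr_dperp * s_pp) ** 2)
    return AnisotropyResult(
        t=t[keep], r=r, sigma=sigma_r, g_factor=g,
        window=parallel.window, irf_fwhm=parallel.irf_fwhm or 0.0,
    )


def _branch_model(t, sigma_irf, lifetimes, terms):
    """conv(K·r)/conv(K) for anisotropy terms [(beta, tau or None), ...]."""
    den = np.zeros_like(t)
    for w, tau_l in lifetimes:
        den += w * exp_conv_gauss(t, tau_l, sigma_irf)
    num = np.zeros_like(t)
    for beta, tau_r in terms:
        for w, tau_l in lifetimes:
            tau = tau_l if tau_r is None else 1.0 / (1.0 / tau_l + 1.0 / tau_r)
            num += w * beta * exp_conv_gauss(t, tau, sigma_irf)
    return num / np.where(den > 0, den, np.inf)


def fit_anisotropy(
    upconv: AnisotropyResult | None,
    tcspc: AnisotropyResult | None = None,
    *,
    lifetimes,
    n_wobble: int = 2,
    fit_ic: bool = True,
    convention: str = "nested",
    tau_ic_max: float = 0.2,
    tau_w2_bounds=(1.0, 200.0),
    tau_w3_bounds=(200.0, 20000.0),
    n_starts: int = 3,
) -> AnisotropyResult:
    """Joint fit of the anisotropy decay across the available windows.

    Parameters are shared between branches; each branch is convolved with its
    own IRF.  The TCSPC branch pins the tumbling floor beta_T (its long
    window sees the true residual anisotropy); without it the floor is fitted
    from the upconversion tail alone and the result is flagged.  The IC
    component is unresolvable through a ~600 ps IRF, so a TCSPC-only fit
    fixes it at zero amplitude.

    ``lifetimes`` is the [(weight, tau_ps), ...] population decay, normally
    taken from the global transient fit of the same dataset.
    """
    branches = [b for b in (upconv, tcspc) if b is not None]
    if not branches:
        raise ValueError("at least one anisotropy window is required")
    flags = []
    if tcspc is None:
        flags.append("beta_t_unpinned_no_tcspc")
    if upconv is None:
        flags.append("ic_fixed_tcspc_only")
        fit_ic = False

    # crude initial guesses from the data
    r_early = float(branches[0].r[0])
    longest = max(branches, key=lambda b: b.t[-1])
    tail = longest.t >= 0.8 * longest.t[-1]
    beta_t0 = float(np.clip(np.mean(longest.r[tail]), 1e-4, 0.4))
    free_amp = max(r_early - beta_t0, 0.02)

    def make_params(tau2_init, tau3_init):
        p = lmfit.Parameters()
        if fit_ic:
            p.add("beta_ic", value=0.25 * free_amp, min=0.0, max=0.4)
            p.add("tau_ic", value=0.08, min=0.01, max=tau_ic_max)
        else:
            p.add("beta_ic", value=0.0, vary=False)
            p.add("tau_ic", value=0.08, vary=False)
        p.add("beta_2", value=0.5 * free_amp, min=0.0, max=0.4)
        p.add("tau_w2", value=tau2_init, min=tau_w2_bounds[0], max=tau_w2_bounds[1])
        if n_wobble >= 2:
            p.add("beta_3", value=0.25 * free_amp, min=0.0, max=0.4)
            p.add("tau_w3", value=tau3_init, min=tau_w3_bounds[0], max=tau_w3_bounds[1])
        else:
            p.add("beta_3", value=0.0, vary=False)
            p.add("tau_w3", value=tau3_init, vary=False)
        p.add("beta_t", value=beta_t0, min=0.0, max=0.4)
        return p

    def resid(params):
        v = params.valuesdict()
        terms = [
            (v["beta_ic"], v["tau_ic"]),
            (v["beta_2"], v["tau_w2"]),
            (v["beta_3"], v["tau_w3"]),
            (v["beta_t"], None),
        ]
        pieces = []
        for b in branches:
            model = _branch_model(
                b.t, fwhm_to_sigma(b.irf_fwhm) if b.irf_fwhm else 0.0,
                lifetimes, terms,
            )
            w = 1.0 / b.sigma if b.sigma is not None else np.ones_like(b.t)
            pieces.append((model - b.r) * w)
        return np.concatenate(pieces)

    best = None
    for f2, f3 in zip((1.0, 0.4, 2.5), (1.0, 0.4, 2.5)):
        params = make_params(
            float(np.clip(20.0 * f2, *tau_w2_bounds)),
            float(np.clip(1000.0 * f3, *tau_w3_bounds)),
        )
        try:
            res = lmfit.minimize(resid, params, method="least_squares",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("anisotropy fit failed from every initialisation")
    if not best.success:
        flags.append("non_convergence")

    v = best.params.valuesdict()
    components = {
        "ic": (v["beta_ic"], v["tau_ic"]),
        "w2": (v["beta_2"], v["tau_w2"]),
        "w3": (v["beta_3"], v["tau_w3"]),
        "floor": (v["beta_t"], None),
    }
    stderr = {
        name: (best.params[name].stderr if best.params[name].stderr is not None else np.nan)
        for name in best.params
        if best.params[name].vary
    }
    ref = branches[0]
    out = AnisotropyResult(
        t=ref.t, r=ref.r, sigma=ref.sigma, g_factor=ref.g_factor,
        window="+".join(b.window for b in branches),
        irf_fwhm=ref.irf_fwhm, components=components,
        convention=convention, stderr=stderr,
        gof=float(best.redchi), flags=flags,
    )
    betas = [v["beta_2"]] + ([v["beta_3"]] if n_wobble >= 2 else [])
    try:
        thetas = cone_semiangle(betas, v["beta_t"], convention=convention)
    except ValueError as err:
        out.flags.append(f"cone_rejected: {err}")
        return out
    taus = [v["tau_w2"]] + ([v["tau_w3"]] if n_wobble >= 2 else [])
    names = ["w2", "w3"][: len(thetas)]
    out.theta = dict(zip(names, thetas))
    out.omega = dict(zip(names, angular_speeds(thetas, taus)))
    return out


def cone_semiangle(betas, beta_floor, convention: str = "nested"):
    """Cone semiangles (deg) for wobbling amplitudes over a constant floor.

    Raises ``ValueError`` with diagnostics if an order parameter falls
    outside (0, 1].
    """
    s2 = cones.sequential_order_parameters(betas, beta_floor, convention)
    for i, s in enumerate(s2):
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"squared order parameter {s:.4f} of cone {i+2} outside [0, 1]")
    return [float(cones.semiangle_deg(np.sqrt(s))) for s in s2]


def angular_speeds(thetas_deg, taus_ps):
    """omega_i = theta_i / tau_Wi in degrees per picosecond."""
    if any(tau <= 0 for tau in taus_ps):
        raise ValueError("wobbling times must be positive")
    return [float(th) / float(tau) for th, tau in zip(thetas_deg, taus_ps)]
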