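"""Per-wavelength decomposition of fluorescence transients.

Each transient I(lambda, t) is modelled as a Gaussian-IRF-convolved sum of

* up to three *solvation* exponentials (tau <~ 200 ps) whose amplitudes may be
  negative — spectral relaxation produces decays on the blue side of the
  emission band and rises on the red side; and
* one or two *lifetime* exponentials (tau >~ 100 ps, non-negative amplitude)
  describing population decay, shared across all wavelengths of a dataset.

Fitting uses variable projection: the nonlinear search runs over the decay
times only (in log space, trust-region least squares with multi-start), and
the amplitudes are solved exactly by weighted linear least squares at every
step.  This is the standard approach for global (multi-wavelength) analysis
and keeps the shared-lifetime fit fast and well conditioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import exp_conv_gauss, fwhm_to_sigma, multiexp

__all__ = ["Transient", "DecayFit", "fit_single", "fit_global", "FitWarning"]

# empirical timescale separation between solvation and lifetime processes
SOLV_TAU_BOUNDS = (0.05, 200.0)
LIFE_TAU_BOUNDS = (100.0, 20000.0)


class FitWarning(UserWarning):
    pass


@dataclass
class Transient:
    """One wavelength's intensity-versus-time trace."""

    wavelength: float  # nm
    t: np.ndarray  # ps, strictly increasing
    intensity: np.ndarray  # a.u.
    sigma: np.ndarray | float | None = None  # per-point noise, a.u.
    window: str = "upconversion"  # "upconversion" or "tcspc"
    irf_fwhm: float | None = None  # ps, if known from the instrument
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.ndim != 1 or self.t.size != self.intensity.size:
            raise ValueError("t and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def peak(self) -> float:
        return float(np.max(self.intensity))


@dataclass
class DecayFit:
    """Multiexponential decomposition of one transient."""

    wavelength: float
    solvation_terms: list  # [(amplitude, tau_ps)], signed amplitudes
    lifetime_terms: list  # [(amplitude, tau_ps)], amplitudes >= 0
    irf_fwhm: float
    gof: float  # reduced chi-square
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def terms(self) -> list:
        return list(self.solvation_terms) + list(self.lifetime_terms)

    def model(self, t, deconvolved: bool = False) -> np.ndarray:
        """Evaluate the fitted model; ``deconvolved`` drops the IRF broadening."""
        t = np.asarray(t, dtype=float)
        if deconvolved or self.irf_fwhm == 0:
            return multiexp(t, *zip(*self.terms))
        sigma = fwhm_to_sigma(self.irf_fwhm)
        out = np.zeros_like(t)
        for a, tau in self.terms:
            out += a * exp_conv_gauss(t, tau, sigma)
        return out

    def integral(self) -> float:
        """Analytic time integral Σ a_k tau_k (IRF convolution preserves it)."""
        return float(sum(a * tau for a, tau in self.terms))

    def scaled(self, factor: float) -> "DecayFit":
        return DecayFit(
            wavelength=self.wavelength,
            solvation_terms=[(a * factor, tau) for a, tau in self.solvation_terms],
            lifetime_terms=[(a * factor, tau) for a, tau in self.lifetime_terms],
            irf_fwhm=self.irf_fwhm,
            gof=self.gof,
            stderr=dict(self.stderr),
            flags=list(self.flags),
        )


def _design_matrix(t, taus, sigma_irf):
    cols = [exp_conv_gauss(t, tau, sigma_irf) for tau in taus]
    return np.column_stack(cols)


def _weights(transient: Transient) -> np.ndarray:
    if transient.sigma is None:
        return np.ones_like(transient.t)
    sig = np.broadcast_to(np.asarray(transient.sigma, dtype=float), transient.t.shape)
    sig = np.where(sig > 0, sig, np.max(sig) if np.max(sig) > 0 else 1.0)
    return 1.0 / sig


def _solve_amplitudes(y, w, X):
    a, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    return a


def _tau_starts(n_solv: int, n_starts: int):
    """Log-spaced initial solvation-time tuples spanning [0.1, 100] ps."""
    starts = []
    for shift in np.linspace(-0.6, 0.6, n_starts):
        base = np.geomspace(0.3, 30.0, max(n_solv, 1)) * 10.0**shift
        starts.append(tuple(base[:n_solv]))
    return starts


def _redchi(resid, n_params):
    dof = max(resid.size - n_params, 1)
    return float(np.sum(resid**2) / dof)


def _flag_unresolvable(solv_terms, irf_fwhm, flags):
    for _, tau in solv_terms:
        if irf_fwhm > 0 and tau < irf_fwhm / 3.0:
            flags.append("unidentifiable_fast_component")
            break


def fit_single(
    transient: Transient,
    n_solv: int,
    n_life: int,
    init: DecayFit | None = None,
    irf_fwhm: float | None = None,
    n_starts: int = 5,
    solv_bounds=SOLV_TAU_BOUNDS,
    life_bounds=LIFE_TAU_BOUNDS,
) -> DecayFit:
    """Fit one transient with ``n_solv`` solvation and ``n_life`` lifetime terms.

    Solvation amplitudes are free in sign (rises on the red side of the band);
    decay times are optimised in log space within class bounds that encode the
    empirical solvation/lifetime timescale separation.  Multi-start
    initialisation guards against local minima; a non-converged result is
    returned flagged, never silently.
    """
    if not 0 <= n_solv <= 3:
        raise ValueError("n_solv must be in 0..3")
    if not 1 <= n_life <= 2:
        raise ValueError("n_life must be 1 or 2")
    if irf_fwhm is None:
        irf_fwhm = transient.irf_fwhm or 0.0
    sigma_irf = fwhm_to_sigma(irf_fwhm) if irf_fwhm else 0.0
    t, y = transient.t, transient.intensity
    w = _weights(transient)

    lo = np.log10([solv_bounds[0]] * n_solv + [life_bounds[0]] * n_life)
    hi = np.log10([solv_bounds[1]] * n_solv + [life_bounds[1]] * n_life)

    def residual(log_tau):
        X = _design_matrix(t, 10.0**log_tau, sigma_irf)
        a = _solve_amplitudes(y, w, X)
        return (y - X @ a) * w

    if init is not None:
        starts = [tuple(tau for _, tau in init.solvation_terms)]
        life_init = tuple(tau for _, tau in init.lifetime_terms)
    else:
        starts = _tau_starts(n_solv, n_starts)
        life_init = tuple(np.geomspace(250.0, 3000.0, n_life))

    best = None
    for solv_init in starts:
        x0 = np.log10(np.concatenate([solv_init, life_init]))
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(
                residual, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400 * x0.size,
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        if best is None or res.cost < best.cost:
            best = res
    flags = []
    if best is None:
        raise RuntimeError("transient fit failed from every initialisation")
    if best.status <= 0:
        flags.append("non_convergence")

    taus = 10.0 ** best.x
    X = _design_matrix(t, taus, sigma_irf)
    amps = _solve_amplitudes(y, w, X)
    resid = (y - X @ amps) * w
    n_params = 2 * (n_solv + n_life)
    gof = _redchi(resid, n_params)

    # parameter uncertainties from the local quadratic model
    stderr = _stderr(t, y, w, amps, taus, sigma_irf, gof, n_solv)

    solv = sorted(zip(amps[:n_solv], taus[:n_solv]), key=lambda p: p[1])
    life = sorted(zip(amps[n_solv:], taus[n_solv:]), key=lambda p: p[1])
    if any(a < 0 for a, _ in life):
        flags.append("negative_lifetime_amplitude")
    _flag_unresolvable(solv, irf_fwhm, flags)
    return DecayFit(
        wavelength=transient.wavelength,
        solvation_terms=[(float(a), float(tau)) for a, tau in solv],
        lifetime_terms=[(float(a), float(tau)) for a, tau in life],
        irf_fwhm=irf_fwhm,
        gof=gof,
        stderr=stderr,
        flags=flags,
    )


def _stderr(t, y, w, amps, taus, sigma_irf, gof, n_solv):
    """Approximate 1-sigma errors from the Jacobian of the full parameter set."""
    eps = 1e-6
    params = np.concatenate([amps, np.log10(taus)])

    def model(p):
        a, logtau = p[: len(amps)], p[len(amps) :]
        X = _design_matrix(t, 10.0**logtau, sigma_irf)
        return X @ a

    f0 = model(params)
    J = np.empty((t.size, params.size))
    for j in range(params.size):
        dp = params.copy()
        step = eps * max(1.0, abs(params[j]))
        dp[j] += step
        J[:, j] = (model(dp) - f0) / step
    Jw = J * w[:, None]
    try:
        cov = np.linalg.pinv(Jw.T @ Jw) * gof
        err = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        err = np.full(params.size, np.nan)
    names = (
        [f"a_solv{i+1}" for i in range(n_solv)]
        + [f"a_life{i+1}" for i in range(len(amps) - n_solv)]
        + [f"log10_tau_solv{i+1}" for i in range(n_solv)]
        + [f"log10_tau_life{i+1}" for i in range(len(amps) - n_solv)]
    )
    return dict(zip(names, err.tolist()))


def fit_global(
    transients: list,
    n_solv: int,
    n_life: int,
    irf_fwhm: float | None = None,
    allow_mixed_windows: bool = False,
    n_starts: int = 3,
    solv_bounds=SOLV_TAU_BOUNDS,
    life_bounds=LIFE_TAU_BOUNDS,
) -> list:
    """Global fit of several wavelengths with shared lifetime decay times.

    Per-wavelength solvation times and all amplitudes stay free; only the
    lifetime taus are linked, mirroring the single lifetime pair reported per
    dataset.  Initialised from independent per-wavelength fits.
    """
    if len(transients) < 3:
        raise ValueError("global fit needs at least 3 wavelengths")
    windows = {tr.window for tr in transients}
    if len(windows) > 1 and not allow_mixed_windows:
        raise ValueError(
            "mixed instrument windows in one global fit; pass allow_mixed_windows=True"
        )
    if irf_fwhm is None:
        irfs = {tr.irf_fwhm or 0.0 for tr in transients}
        if len(irfs) > 1:
            raise ValueError("transients carry inconsistent IRF widths")
        irf_fwhm = irfs.pop()
    sigma_irf = fwhm_to_sigma(irf_fwhm) if irf_fwhm else 0.0

    singles = [
        fit_single(tr, n_solv, n_life, irf_fwhm=irf_fwhm, n_starts=n_starts)
        for tr in transients
    ]
    life_init = np.median(
        [[tau for _, tau in f.lifetime_terms] for f in singles], axis=0
    )
    solv_init = [[tau for _, tau in f.solvation_terms] for f in singles]

    n_wl = len(transients)
    ts = [tr.t for tr in transients]
    ys = [tr.intensity for tr in transients]
    ws = [_weights(tr) for tr in transients]

    def unpack(x):
        solv = 10.0 ** x[: n_wl * n_solv].reshape(n_wl, n_solv)
        life = 10.0 ** x[n_wl * n_solv :]
        return solv, life

    def residual(x):
        solv, life = unpack(x)
        pieces = []
        for i in range(n_wl):
            X = _design_matrix(ts[i], np.concatenate([solv[i], life]), sigma_irf)
            a = _solve_amplitudes(ys[i], ws[i], X)
            pieces.append((ys[i] - X @ a) * ws[i])
        return np.concatenate(pieces)

    x0 = np.concatenate(
        [np.log10(np.asarray(solv_init).ravel()), np.log10(life_init)]
    )
    lo = np.concatenate(
        [np.full(n_wl * n_solv, np.log10(solv_bounds[0])), np.full(n_life, np.log10(life_bounds[0]))]
    )
    hi = np.concatenate(
        [np.full(n_wl * n_solv, np.log10(solv_bounds[1])), np.full(n_life, np.log10(life_bounds[1]))]
    )
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
    res = least_squares(
        residual, x0, bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=300 * x0.size,
    )
    solv_taus, life_taus = unpack(res.x)

    fits = []
    for i, tr in enumerate(transients):
        taus = np.concatenate([solv_taus[i], life_taus])
        X = _design_matrix(tr.t, taus, sigma_irf)
        amps = _solve_amplitudes(tr.intensity, ws[i], X)
        resid = (tr.intensity - X @ amps) * ws[i]
        gof = _redchi(resid, 2 * n_solv + n_life + n_life / n_wl)
        flags = [] if res.status > 0 else ["non_convergence"]
        solv = sorted(zip(amps[:n_solv], taus[:n_solv]), key=lambda p: p[1])
        life = sorted(zip(amps[n_solv:], taus[n_solv:]), key=lambda p: p[1])
        _flag_unresolvable(solv, irf_fwhm, flags)
        fits.append(
            DecayFit(
                wavelength=tr.wavelength,
                solvation_terms=[(float(a), float(tau)) for a, tau in solv],
                lifetime_terms=[(float(a), float(tau)) for a, tau in life],
                irf_fwhm=irf_fwhm,
                gof=gof,
                flags=flags,
            )
        )
    return fits
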