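"""Ground-truth parameter models for the synthetic-data generator.

Three small validated containers describe everything the generator needs:

* :class:`SpectralModel` — a time-dependent lognormal emission band whose peak
  relaxes (red-shifts) as a sum of solvation exponentials, multiplied by a
  population (lifetime) decay;
* :class:`AnisotropyModel` — a four-component anisotropy decay r(t):
  internal conversion, two wobbling-in-cone motions, and a constant
  tumbling floor;
* :class:`InstrumentModel` — time window, grid, Gaussian IRF width, and the
  noise statistics of either detection scheme (femtosecond upconversion with
  additive Gaussian noise, or TCSPC with Poisson counting noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import cones
from .kinetics import fwhm_to_sigma

__all__ = ["SpectralModel", "AnisotropyModel", "InstrumentModel", "DEFAULT_SEED"]

DEFAULT_SEED = 20210615


@dataclass(frozen=True)
class SpectralModel:
    """Time-dependent emission band: relaxing lognormal times a lifetime decay.

    Parameters
    ----------
    peak_t0, peak_inf
        Emission peak (cm⁻¹) at time zero and after full solvation relaxation;
        ``peak_t0 > peak_inf`` (the band red-shifts, i.e. loses energy).
    components
        Solvation components ``(fraction, tau_ps)``; fractions sum to 1 and
        give each component's share of the total Stokes shift.
    width, asymmetry
        Lognormal band full width (cm⁻¹) and skew (held constant in time).
    lifetimes
        Population decay components ``(weight, tau_ps)``; weights need not be
        normalised.
    """

    peak_t0: float
    peak_inf: float
    components: tuple = ()
    width: float = 5200.0
    asymmetry: float = -0.3
    lifetimes: tuple = ((1.0, 3000.0),)

    def __post_init__(self):
        comps = tuple((float(f), float(tau)) for f, tau in self.components)
        lifes = tuple((float(w), float(tau)) for w, tau in self.lifetimes)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "lifetimes", lifes)
        if self.peak_t0 < self.peak_inf:
            raise ValueError(
                "peak_t0 must be >= peak_inf (emission red-shifts over time)"
            )
        if comps:
            total = sum(f for f, _ in comps)
            if abs(total - 1.0) > 1.0e-9:
                raise ValueError(f"solvation fractions must sum to 1, got {total}")
            if any(not (0.0 < f <= 1.0) for f, _ in comps):
                raise ValueError("solvation fractions must lie in (0, 1]")
            if any(tau <= 0 for _, tau in comps):
                raise ValueError("solvation times must be positive")
        elif self.peak_t0 != self.peak_inf:
            raise ValueError("a peak shift requires at least one component")
        if not lifes or any(tau <= 0 for _, tau in lifes) or any(w < 0 for w, _ in lifes):
            raise ValueError("lifetimes must have non-negative weights and positive taus")
        if self.width <= 0:
            raise ValueError("band width must be positive")

    @property
    def total_shift(self) -> float:
        """Total dynamic Stokes shift (cm⁻¹)."""
        return self.peak_t0 - self.peak_inf

    def peak_at(self, t):
        """Emission peak nu_p(t) in cm⁻¹ for t >= 0 (clamped below zero)."""
        t = np.clip(np.asarray(t, dtype=float), 0.0, None)
        relax = np.zeros_like(t)
        for f, tau in self.components:
            relax += f * np.exp(-t / tau)
        return self.peak_inf + self.total_shift * relax

    def population_at(self, t):
        """Lifetime decay K(t) = Σ w_j exp(-t/tau_j) for t >= 0, else 0."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        mask = t >= 0
        for w, tau in self.lifetimes:
            out[mask] += w * np.exp(-t[mask] / tau)
        return out


@dataclass(frozen=True)
class AnisotropyModel:
    """Multiexponential anisotropy decay with a constant tumbling floor.

    r(t) = beta_ic e^(-t/tau_ic) + beta_2 e^(-t/tau_w2)
         + beta_3 e^(-t/tau_w3) + beta_t

    The amplitudes sum to the initial anisotropy r0 (<= 0.4).  The tumbling
    time of the chaperone complex is far longer than the fluorescence
    lifetime, so beta_t does not decay within either measurement window.
    A wobbling component may be disabled by setting its amplitude to zero.
    """

    r0: float
    beta_ic: float = 0.0
    tau_ic: float = 0.08
    beta_2: float = 0.0
    tau_w2: float = 20.0
    beta_3: float = 0.0
    tau_w3: float = 1000.0
    beta_t: float = 0.0

    def __post_init__(self):
        betas = (self.beta_ic, self.beta_2, self.beta_3, self.beta_t)
        if any(b < 0 for b in betas):
            raise ValueError("anisotropy amplitudes must be non-negative")
        if abs(sum(betas) - self.r0) > 1.0e-9:
            raise ValueError("amplitudes must sum to r0")
        if self.r0 > 0.4 + 1.0e-12:
            raise ValueError("r0 cannot exceed the collinear-dipole limit 0.4")
        for tau in (self.tau_ic, self.tau_w2, self.tau_w3):
            if tau <= 0:
                raise ValueError("anisotropy decay times must be positive")

    @classmethod
    def from_cones(
        cls,
        r0: float,
        beta_ic: float,
        tau_ic: float,
        theta2_deg: float,
        tau_w2: float,
        theta3_deg: float | None = None,
        tau_w3: float = 1000.0,
    ) -> "AnisotropyModel":
        """Build amplitudes from nested wobbling-cone semiangles.

        The post-internal-conversion amplitude r_w = r0 - beta_ic is split so
        that the nested (sequential) cone analysis recovers exactly the given
        semiangles: with S_i the order parameter of cone i,
        beta_2 = r_w (1 - S2²), beta_3 = r_w S2² (1 - S3²), beta_t = r_w S2² S3².
        Omit ``theta3_deg`` for a single-cone model (beta_3 = 0).
        """
        r_w = r0 - beta_ic
        if r_w <= 0:
            raise ValueError("r0 must exceed beta_ic")
        s2sq = float(cones.order_parameter(theta2_deg)) ** 2
        if theta3_deg is None:
            return cls(
                r0=r0, beta_ic=beta_ic, tau_ic=tau_ic,
                beta_2=r_w * (1.0 - s2sq), tau_w2=tau_w2,
                beta_3=0.0, tau_w3=tau_w3, beta_t=r_w * s2sq,
            )
        s3sq = float(cones.order_parameter(theta3_deg)) ** 2
        return cls(
            r0=r0, beta_ic=beta_ic, tau_ic=tau_ic,
            beta_2=r_w * (1.0 - s2sq), tau_w2=tau_w2,
            beta_3=r_w * s2sq * (1.0 - s3sq), tau_w3=tau_w3,
            beta_t=r_w * s2sq * s3sq,
        )

    def r_at(self, t):
        """Evaluate r(t) for t >= 0."""
        t = np.clip(np.asarray(t, dtype=float), 0.0, None)
        return (
            self.beta_ic * np.exp(-t / self.tau_ic)
            + self.beta_2 * np.exp(-t / self.tau_w2)
            + self.beta_3 * np.exp(-t / self.tau_w3)
            + self.beta_t
        )

    def terms(self):
        """Non-zero (beta, tau) pairs; the floor is returned with tau=None."""
        out = []
        if self.beta_ic > 0:
            out.append((self.beta_ic, self.tau_ic))
        if self.beta_2 > 0:
            out.append((self.beta_2, self.tau_w2))
        if self.beta_3 > 0:
            out.append((self.beta_3, self.tau_w3))
        if self.beta_t > 0:
            out.append((self.beta_t, None))
        return out


@dataclass(frozen=True)
class InstrumentModel:
    """Detection window, grid, IRF, and noise statistics of one instrument."""

    irf_fwhm: float
    window: float
    n_points: int = 301
    kind: str = "upconversion"  # "upconversion" (log grid) or "tcspc" (linear)
    noise_kind: str = "gaussian"  # "gaussian" or "poisson"
    noise_scale: float = 0.0  # sigma as fraction of peak, or peak counts
    seed: int = DEFAULT_SEED
    t_min: float = 0.01

    def __post_init__(self):
        if self.irf_fwhm < 0 or self.irf_fwhm >= self.window:
            raise ValueError("need 0 <= irf_fwhm < window")
        if self.n_points < 50:
            raise ValueError("need at least 50 time points")
        if self.kind not in ("upconversion", "tcspc"):
            raise ValueError(f"unknown instrument kind {self.kind!r}")
        if self.noise_kind not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")

    @classmethod
    def upconversion(cls, **kw) -> "InstrumentModel":
        """Femtosecond upconversion default: 0.15 ps IRF, 3 ns log-spaced window."""
        kw.setdefault("irf_fwhm", 0.15)
        kw.setdefault("window", 3000.0)
        kw.setdefault("kind", "upconversion")
        kw.setdefault("noise_kind", "gaussian")
        return cls(**kw)

    @classmethod
    def tcspc(cls, **kw) -> "InstrumentModel":
        """TCSPC default: ~600 ps IRF, 100 ns linear window, Poisson counts."""
        kw.setdefault("irf_fwhm", 600.0)
        kw.setdefault("window", 100000.0)
        kw.setdefault("kind", "tcspc")
        kw.setdefault("noise_kind", "poisson")
        kw.setdefault("n_points", 1001)
        return cls(**kw)

    @property
    def irf_sigma(self) -> float:
        return fwhm_to_sigma(self.irf_fwhm)

    def time_grid(self) -> np.ndarray:
        """Sampling times in ps: log-spaced for upconversion, linear for TCSPC."""
        if self.kind == "upconversion":
            return np.geomspace(self.t_min, self.window, self.n_points)
        return np.linspace(0.0, self.window, self.n_points)

    def with_seed(self, seed: int) -> "InstrumentModel":
        return replace(self, seed=int(seed))
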