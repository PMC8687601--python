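"""Wobbling-in-cone geometry: order parameters and cone semiangles.

For a transition dipole diffusing inside a cone of semiangle theta, the
residual anisotropy fraction defines the cone order parameter

    S_cone = cos(theta) * (1 + cos(theta)) / 2 ,

so S_cone = 1 corresponds to a rigid dipole (theta = 0) and S_cone = 0 to a
free rotor (theta = 90 deg).  Inverting for theta amounts to solving the
quadratic x^2 + x - 2 S = 0 for x = cos(theta) on [0, 1].
"""

from __future__ import annotations

import numpy as np

__all__ = ["order_parameter", "semiangle_deg", "sequential_order_parameters"]


def order_parameter(theta_deg):
    """Cone order parameter S from the semiangle in degrees."""
    c = np.cos(np.deg2rad(np.asarray(theta_deg, dtype=float)))
    return 0.5 * c * (1.0 + c)


def semiangle_deg(s_cone):
    """Cone semiangle (degrees) from the order parameter S on [0, 1]."""
    s = np.asarray(s_cone, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError(f"order parameter must lie in [0, 1], got {s_cone}")
    cos_theta = 0.5 * (-1.0 + np.sqrt(1.0 + 8.0 * s))
    return np.rad2deg(np.arccos(np.clip(cos_theta, -1.0, 1.0)))


def sequential_order_parameters(betas, beta_floor, convention: str = "nested"):
    """Squared order parameters for wobbling amplitudes over a constant floor.

    Parameters
    ----------
    betas
        Anisotropy amplitudes of the wobbling components, fastest first
        (e.g. ``[beta_2, beta_3]``).  The sub-100-fs internal-conversion
        amplitude must NOT be included: it reflects the electronic transition
        moment jump, not dipole wobbling.
    beta_floor
        Constant (tumbling) amplitude beta_T, effectively non-decaying within
        the measurement window.
    convention
        ``"nested"`` (default): each slower motion carries the faster cone
        with it; cone i sees only the amplitude decayed at-or-after its own
        timescale:  S_i^2 = (sum of strictly slower betas + floor) /
        (sum of at-or-slower betas + floor).
        ``"independent"``: each cone is referenced to the full wobbling
        amplitude:  S_i^2 = 1 - beta_i / (sum of all betas + floor).

    Returns
    -------
    list of squared order parameters, one per wobbling component.
    """
    betas = [float(b) for b in betas]
    if any(b < 0 for b in betas) or beta_floor < 0:
        raise ValueError("anisotropy amplitudes must be non-negative")
    total = sum(betas) + beta_floor
    if total <= 0:
        raise ValueError("total wobbling amplitude must be positive")
    s2 = []
    if convention == "nested":
        for i in range(len(betas)):
            slower = sum(betas[i + 1 :]) + beta_floor
            at_or_slower = slower + betas[i]
            s2.append(slower / at_or_slower)
    elif convention == "independent":
        for b in betas:
            s2.append(1.0 - b / total)
    else:
        raise ValueError(f"unknown cone convention {convention!r}")
    return s2
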