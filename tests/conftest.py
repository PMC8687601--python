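"""Shared fixtures: cached end-to-end solvation chains per reference system.

The full transient -> global fit -> FRES -> c(t) chain on noiseless synthetic
data takes a few seconds per system, so it is computed once per session and
shared by every test that inspects an intermediate or final stage.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from hydrodyn import fres, presets, solvation, synthetic
from hydrodyn.models import InstrumentModel
from hydrodyn.transients import fit_global

WAVELENGTHS = tuple(np.linspace(310.0, 370.0, 9))


@lru_cache(maxsize=None)
def _solvation_chain(site: str, state: str, noise: float = 0.0, seed: int = 1):
    model = presets.spectral_model(site, state)
    inst = InstrumentModel.upconversion(noise_scale=noise, seed=seed)
    transients = synthetic.generate_transients(model, inst, list(WAVELENGTHS))
    ss = synthetic.generate_steady_state(model, np.arange(300.0, 400.01, 0.25))
    fits = fit_global(transients, 3, 2)
    scaled = fres.scale_to_steady_state(fits, ss)
    slices = fres.build_fres(scaled)
    t, nu_p = fres.peak_trajectory(slices)
    gof = np.array([s.gof for s in slices])
    weights = 1.0 / np.sqrt(gof + 1.0e-9 * np.nanmax(gof))
    weights /= weights.max()
    solv = solvation.correlation_function(t, nu_p)
    solv = solvation.fit_correlation(solv, 3, weights=weights)
    solv = solvation.solvation_speeds(solv)
    return {
        "model": model,
        "instrument": inst,
        "transients": transients,
        "steady_state": ss,
        "fits": fits,
        "scaled_fits": scaled,
        "slices": slices,
        "t": t,
        "nu_p": nu_p,
        "solv": solv,
    }


@pytest.fixture(scope="session")
def solvation_chain():
    """Factory: solvation_chain(site, state) -> cached chain artifacts."""
    return _solvation_chain


@pytest.fixture(scope="session")
def apo_f44w_chain():
    return _solvation_chain("F44W", "apo")


@pytest.fixture(scope="session")
def football_f281w_chain():
    return _solvation_chain("F281W", "football")
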