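"""Anisotropy decay analysis: r(t), joint fits, cones, angular speeds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrodyn import cones, presets, synthetic
from hydrodyn.anisotropy import angular_speeds, compute_r, cone_semiangle, fit_anisotropy
from hydrodyn.models import AnisotropyModel, InstrumentModel


def _polarized(site, state, instrument):
    return synthetic.generate_polarized(
        presets.anisotropy_model(site, state),
        presets.spectral_model(site, state),
        instrument,
    )


class TestComputeR:
    def test_constant_ratio_three_gives_r_04(self):
        from hydrodyn.transients import Transient

        t = np.linspace(0.0, 10.0, 50)
        par = Transient(wavelength=330, t=t, intensity=np.full(50, 3.0))
        perp = Transient(wavelength=330, t=t, intensity=np.full(50, 1.0))
        r = compute_r(par, perp, g=1.0)
        assert np.allclose(r.r, 0.4)

    def test_roundtrip_without_irf(self):
        m = presets.anisotropy_model("F281W", "apo")
        life = presets.spectral_model("F281W", "apo")
        inst = InstrumentModel.upconversion(irf_fwhm=0.0)
        par, perp = synthetic.generate_polarized(m, life, inst)
        r = compute_r(par, perp)
        assert np.max(np.abs(r.r - m.r_at(r.t))) < 1e-10

    def test_intensity_scaling_invariance(self):
        """r(t), theta and omega are unchanged under a global intensity scale."""
        par, perp = _polarized("F44W", "apo", InstrumentModel.upconversion())
        r1 = compute_r(par, perp)
        par.intensity = par.intensity * 37.5
        perp.intensity = perp.intensity * 37.5
        r2 = compute_r(par, perp)
        assert np.allclose(r1.r, r2.r, rtol=1e-12)

    def test_nonpositive_denominator_masked(self):
        from hydrodyn.transients import Transient

        t = np.linspace(0.0, 5.0, 6)
        par = Transient(wavelength=330, t=t, intensity=np.array([3.0, 3, 0, 3, 3, 3]))
        perp = Transient(wavelength=330, t=t, intensity=np.array([1.0, 1, 0, 1, 1, 1]))
        with pytest.warns(UserWarning, match="masking"):
            r = compute_r(par, perp)
        assert r.t.size == 5

    def test_sigma_propagation(self):
        m = presets.anisotropy_model("F44W", "apo")
        life = presets.spectral_model("F44W", "apo")
        inst = InstrumentModel.tcspc(noise_scale=1.0e4, seed=9)
        par, perp = synthetic.generate_polarized(m, life, inst)
        r = compute_r(par, perp)
        assert r.sigma is not None and np.all(r.sigma > 0)


class TestFitAnisotropy:
    def test_joint_two_window_recovery_apo_f281w(self):
        """tau_W2 = 12 ps and tau_W3 = 2.0 ns recovered within 10%."""
        life = presets.spectral_model("F281W", "apo")
        par_u, perp_u = _polarized("F281W", "apo", InstrumentModel.upconversion(seed=2))
        par_t, perp_t = _polarized(
            "F281W", "apo", InstrumentModel.tcspc(seed=3, noise_scale=0.0)
        )
        res = fit_anisotropy(
            compute_r(par_u, perp_u), compute_r(par_t, perp_t),
            lifetimes=life.lifetimes,
        )
        assert res.components["w2"][1] == pytest.approx(12.0, rel=0.10)
        assert res.components["w3"][1] == pytest.approx(1997.0, rel=0.10)

    @pytest.mark.parametrize("site,state", presets.SYSTEMS)
    def test_end_to_end_wobbling_recovery(self, site, state):
        """(tau_W2, omega_2) within 10% for all four reference systems."""
        life = presets.spectral_model(site, state)
        row = presets.TABLE[(site, state)]
        par_u, perp_u = _polarized(site, state, InstrumentModel.upconversion(seed=4))
        par_t, perp_t = _polarized(
            site, state, InstrumentModel.tcspc(seed=5, noise_scale=0.0)
        )
        res = fit_anisotropy(
            compute_r(par_u, perp_u), compute_r(par_t, perp_t),
            lifetimes=life.lifetimes,
        )
        assert res.components["w2"][1] == pytest.approx(row["tau_w"][0], rel=0.10)
        assert res.omega["w2"] == pytest.approx(row["omega"][0], rel=0.10)

    def test_null_wobbling_amplitudes_near_zero(self):
        m = AnisotropyModel(r0=0.4, beta_ic=0.04, beta_t=0.36)
        life = presets.spectral_model("F44W", "apo")
        par, perp = synthetic.generate_polarized(m, life, InstrumentModel.upconversion())
        res = fit_anisotropy(compute_r(par, perp), None, lifetimes=life.lifetimes)
        assert res.components["w2"][0] < 1e-3
        assert res.components["w3"][0] < 1e-3

    def test_dropping_tcspc_inflates_floor_uncertainty(self):
        """Without the long window, beta_T is at least 2x less certain."""
        site, state = "F44W", "apo"
        life = presets.spectral_model(site, state)
        par_u, perp_u = _polarized(
            site, state, InstrumentModel.upconversion(seed=6, noise_scale=0.005)
        )
        par_t, perp_t = _polarized(
            site, state, InstrumentModel.tcspc(seed=7, noise_scale=1.0e4)
        )
        r_u, r_t = compute_r(par_u, perp_u), compute_r(par_t, perp_t)
        both = fit_anisotropy(r_u, r_t, lifetimes=life.lifetimes)
        alone = fit_anisotropy(r_u, None, lifetimes=life.lifetimes)
        assert "beta_t_unpinned_no_tcspc" in alone.flags
        assert alone.stderr["beta_t"] > 2.0 * both.stderr["beta_t"]

    def test_tcspc_only_fixes_internal_conversion(self):
        site, state = "F44W", "apo"
        life = presets.spectral_model(site, state)
        par_t, perp_t = _polarized(
            site, state, InstrumentModel.tcspc(seed=8, noise_scale=0.0)
        )
        res = fit_anisotropy(None, compute_r(par_t, perp_t), lifetimes=life.lifetimes)
        assert "ic_fixed_tcspc_only" in res.flags
        assert res.components["ic"][0] == 0.0


class TestCones:
    def test_rigid_limit(self):
        assert float(cones.semiangle_deg(1.0)) == pytest.approx(0.0, abs=1e-9)

    def test_free_rotor_limit(self):
        assert float(cones.semiangle_deg(0.0)) == pytest.approx(90.0, abs=1e-9)

    def test_reference_order_parameter(self):
        """S^2 = 0.8711 corresponds to a 17.3 degree cone."""
        theta = float(cones.semiangle_deg(np.sqrt(0.8711)))
        assert theta == pytest.approx(17.3, abs=0.1)

    def test_closed_form_matches_root_finding(self):
        from scipy.optimize import brentq

        for s in (0.05, 0.3, 0.6, 0.9, 0.99):
            oracle = brentq(
                lambda th: 0.5 * np.cos(th) * (1 + np.cos(th)) - s, 0.0, np.pi / 2
            )
            assert float(cones.semiangle_deg(s)) == pytest.approx(
                np.rad2deg(oracle), abs=1e-9
            )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
    def test_semiangle_monotone_in_order_parameter(self, s1, s2):
        lo, hi = sorted((s1, s2))
        if hi - lo > 1e-12:
            assert cones.semiangle_deg(hi) < cones.semiangle_deg(lo)

    def test_out_of_range_order_parameter_rejected(self):
        with pytest.raises(ValueError):
            cone_semiangle([-0.1], 0.3)

    def test_conventions_agree_on_fast_cone_differ_on_slow(self):
        """Both conventions give the same fastest cone (same amplitude ratio)
        but disagree on the slower cone's reference amplitude."""
        nested = cone_semiangle([0.07, 0.056], 0.234, convention="nested")
        indep = cone_semiangle([0.07, 0.056], 0.234, convention="independent")
        assert nested[0] == pytest.approx(indep[0], abs=1e-9)
        assert abs(nested[1] - indep[1]) > 0.5


class TestAngularSpeeds:
    def test_reference_arithmetic(self):
        """19.17 deg over 27 ps is 0.71 deg/ps; 21.4 deg over 904 ps is 0.0237."""
        w2, w3 = angular_speeds([19.17, 21.42], [27.0, 904.0])
        assert w2 == pytest.approx(0.71, abs=0.005)
        assert w3 == pytest.approx(0.0237, abs=0.0002)

    def test_zero_angle_zero_speed(self):
        assert angular_speeds([0.0], [27.0]) == [0.0]

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            angular_speeds([10.0], [0.0])
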