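"""Forward generator: transients, steady state, polarized pairs, noise."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from hydrodyn import presets, synthetic
from hydrodyn.models import AnisotropyModel, InstrumentModel, SpectralModel


@pytest.fixture(scope="module")
def apo_f44w_model():
    return presets.spectral_model("F44W", "apo")


class TestGenerateTransients:
    def test_blue_decays_red_rises(self, apo_f44w_chain):
        """Spectral relaxation shows as blue-side decay and red-side rise."""
        trs = apo_f44w_chain["transients"]
        blue, red = trs[0], trs[-1]
        late = blue.t > 1.0
        assert np.all(np.diff(blue.intensity[late]) <= 1e-12)
        assert np.argmax(red.intensity) > 5  # rises before decaying

    def test_no_relaxation_gives_identical_shapes(self):
        """With a static band every wavelength is the same lifetime decay."""
        m = SpectralModel(peak_t0=29000.0, peak_inf=29000.0,
                          lifetimes=((0.5, 315.0), (0.5, 3600.0)))
        inst = InstrumentModel.upconversion()
        trs = synthetic.generate_transients(m, inst, [320.0, 345.0, 368.0])
        ref = trs[0].intensity / trs[0].peak
        for tr in trs[1:]:
            assert np.allclose(tr.intensity / tr.peak, ref, rtol=1e-9, atol=1e-12)

    def test_rejects_unsorted_and_out_of_range(self, apo_f44w_model):
        inst = InstrumentModel.upconversion()
        with pytest.raises(ValueError, match="sorted"):
            synthetic.generate_transients(apo_f44w_model, inst, [350.0, 310.0])
        with pytest.raises(ValueError, match="300-400"):
            synthetic.generate_transients(apo_f44w_model, inst, [250.0])

    def test_rejects_wavelength_outside_band_support(self):
        # positive skew puts a hard band edge on the low-energy side
        m = SpectralModel(peak_t0=31000.0, peak_inf=30500.0,
                          components=((1.0, 5.0),), width=3000.0, asymmetry=0.5)
        inst = InstrumentModel.upconversion()
        with pytest.raises(ValueError, match="support"):
            synthetic.generate_transients(m, inst, [395.0])

    def test_rejects_negative_noise_scale(self):
        with pytest.raises(ValueError, match="noise_scale"):
            InstrumentModel.upconversion(noise_scale=-1.0)


class TestSteadyState:
    def test_matches_quadrature_oracle(self, apo_f44w_model):
        """Per-lambda time integral of the signal model, by adaptive quadrature."""
        lam_grid = np.arange(300.0, 400.01, 0.25)
        ss = synthetic.generate_steady_state(apo_f44w_model, lam_grid)
        for lam in (315.0, 340.0, 365.0):
            oracle = sum(
                quad(
                    lambda t: synthetic.signal_at(apo_f44w_model, lam, np.array([t]))[0],
                    a, b, limit=400,
                )[0]
                for a, b in [(0.0, 10.0), (10.0, 1000.0), (1000.0, 1.2e5)]
            )
            got = float(ss.at(lam))
            assert got == pytest.approx(oracle, rel=1e-6)

    def test_delta_lifetime_limit_is_relaxed_band(self):
        """With very long lifetimes the spectrum is the fully relaxed band."""
        m = SpectralModel(peak_t0=30000.0, peak_inf=29000.0,
                          components=((1.0, 1.0),), lifetimes=((1.0, 1.0e7),))
        lam = np.arange(300.0, 400.01, 0.5)
        ss = synthetic.generate_steady_state(m, lam)
        from hydrodyn import bands
        relaxed = bands.intensity_wavenumber_to_nm(
            lam, bands.lognormal(bands.nm_to_wavenumber(lam), 1.0, 29000.0,
                                 m.width, m.asymmetry),
        )
        ratio = ss.intensity / relaxed
        assert np.ptp(ratio) / np.mean(ratio) < 2e-3

    def test_span_excluding_peak_flags(self, apo_f44w_model):
        with pytest.warns(UserWarning, match="excludes"):
            ss = synthetic.generate_steady_state(apo_f44w_model, np.arange(300.0, 320.0, 0.5))
        assert "peak_outside_span" in ss.flags

    def test_transient_time_sums_track_steady_state(self, apo_f44w_model):
        """Discrete time sums of noiseless transients scale with the spectrum."""
        inst = InstrumentModel.upconversion(n_points=2001)
        wl = [320.0, 340.0, 360.0]
        trs = synthetic.generate_transients(apo_f44w_model, inst, wl)
        ss = synthetic.generate_steady_state(apo_f44w_model, np.arange(300.0, 400.01, 0.25))
        sums = np.array([np.trapezoid(tr.intensity, tr.t) for tr in trs])
        targets = np.array([float(ss.at(l)) for l in wl])
        ratio = sums / targets
        # the 3 ns window truncates the 3.6 ns lifetime tail equally per
        # lambda; small residual spread comes from the discrete log grid
        assert np.ptp(ratio) / np.mean(ratio) < 5e-3


class TestPolarized:
    def test_no_wobbling_ratio_three(self):
        m = AnisotropyModel(r0=0.4, beta_t=0.4)
        life = SpectralModel(peak_t0=29000.0, peak_inf=29000.0,
                             lifetimes=((1.0, 1000.0),))
        par, perp = synthetic.generate_polarized(m, life, InstrumentModel.upconversion())
        assert np.allclose(par.intensity / perp.intensity, 3.0, rtol=1e-9)

    def test_inversion_roundtrip_exact_without_irf(self):
        """(I_par - I_perp)/(I_par + 2 I_perp) returns the model r(t) exactly."""
        m = presets.anisotropy_model("F281W", "apo")
        life = presets.spectral_model("F281W", "apo")
        inst = InstrumentModel.upconversion(irf_fwhm=0.0)
        par, perp = synthetic.generate_polarized(m, life, inst)
        r = (par.intensity - perp.intensity) / (par.intensity + 2 * perp.intensity)
        assert np.max(np.abs(r - m.r_at(par.t))) < 1e-10

    def test_tcspc_poisson_anisotropy_unbiased(self):
        """Mean r(t) over 100 Poisson realisations tracks the noiseless truth."""
        from hydrodyn.anisotropy import compute_r

        m = presets.anisotropy_model("F44W", "apo")
        life = presets.spectral_model("F44W", "apo")
        clean_inst = InstrumentModel.tcspc(noise_scale=0.0)
        par0, perp0 = synthetic.generate_polarized(m, life, clean_inst)
        r_true = compute_r(par0, perp0).r
        # restrict to delays with enough counts for the ratio estimator
        keep = (par0.intensity + 2 * perp0.intensity) > 0.05 * par0.peak
        acc = np.zeros_like(r_true)
        n_seeds = 100
        for k in range(n_seeds):
            inst = InstrumentModel.tcspc(noise_scale=1.0e4, seed=500 + k)
            par, perp = synthetic.generate_polarized(m, life, inst)
            with np.errstate(invalid="ignore"):
                r = (par.intensity - perp.intensity) / (
                    par.intensity + 2 * perp.intensity
                )
            acc += r
        bias = (acc / n_seeds - r_true)[keep]
        assert np.abs(bias).mean() < 0.002


class TestNoise:
    def test_gaussian_residuals_pass_normality(self):
        """KS normality holds for >= 95 of 100 seeds at n = 10^4 points."""
        clean = np.exp(-np.linspace(0, 2, 10000))  # floor >> sigma: no clipping
        inst = InstrumentModel.upconversion(noise_scale=0.01, n_points=10000)
        sigma = 0.01 * clean.max()
        passes = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy, _, _ = synthetic.apply_noise(clean, inst, rng)
            z = (noisy - clean) / sigma
            if kstest(z, "norm").pvalue > 0.01:
                passes += 1
        assert passes >= 95

    def test_poisson_counts_and_sigma(self):
        clean = np.exp(-np.linspace(0, 3, 200))
        inst = InstrumentModel.tcspc(noise_scale=1.0e4)
        rng = np.random.default_rng(0)
        noisy, sigma, _ = synthetic.apply_noise(clean, inst, rng)
        # counts are integers after undoing the scale
        counts = noisy * 1.0e4 / clean.max()
        assert np.allclose(counts, np.round(counts))
        assert sigma is not None and np.all(sigma > 0)

    def test_energy_bookkeeping_total_shift(self, apo_f44w_chain):
        """Generator total Stokes shift is recovered by the chain within 1%."""
        model = apo_f44w_chain["model"]
        solv = apo_f44w_chain["solv"]
        measured = solv.nu0 - solv.nu_inf
        assert measured == pytest.approx(model.total_shift, rel=0.01)
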