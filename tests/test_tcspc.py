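"""Polarised decay modelling, periodic reconvolution and global fitting."""

import numpy as np
import pytest

from allokit import DecayModel, TcspcModel, convolve_with_irf, model_decays
from allokit.exceptions import InvalidParameterError
from allokit.synthetic import gen_tcspc
from allokit.tcspc import estimate_g_factor

PERIOD = 12.5
T = np.arange(781) * (PERIOD / 781)


class TestModelDecays:
    def test_isotropic_emission_makes_channels_equal(self):
        m = DecayModel(r0=0.0, g=1.0)
        d_par, d_perp = model_decays(m, T, PERIOD)
        assert np.allclose(d_par, d_perp)

    def test_classical_anisotropy_identity_without_corrections(self):
        """With k1 = k2 = 0 and G = 1, (par-perp)/(par+2perp) = r(t)."""
        m = DecayModel(tau=3.0, phi=18.0, r0=0.3, g=1.0, k1=0.0, k2=0.0)
        d_par, d_perp = model_decays(m, T, PERIOD)
        r = (d_par - d_perp) / (d_par + 2.0 * d_perp)
        assert np.allclose(r, m.r0 * np.exp(-T / m.phi), rtol=1e-12)

    def test_total_intensity_identity_without_corrections(self):
        """F = d_par/G + 2 d_perp when the NA corrections vanish."""
        m = DecayModel(amplitude=7.0, tau=3.0, g=1.3, k1=0.0, k2=0.0)
        d_par, d_perp = model_decays(m, T, PERIOD)
        f = m.amplitude / (1 - np.exp(-PERIOD / m.tau)) * np.exp(-T / m.tau)
        assert np.allclose(d_par / m.g + 2.0 * d_perp, f, rtol=1e-12)

    def test_fast_decay_limit_removes_pileup_normalisation(self):
        m = DecayModel(amplitude=5.0, tau=0.1)     # T/tau = 125
        d_par, d_perp = model_decays(m, np.array([0.0]), PERIOD)
        f0 = d_par[0] / m.g / (1 + (2 - 3 * m.k1) * m.r0) * 3
        assert f0 == pytest.approx(m.amplitude, rel=1e-12)

    @pytest.mark.parametrize("bad", [dict(tau=-1.0), dict(phi=0.0),
                                     dict(r0=0.5)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            DecayModel(**bad)


class TestConvolution:
    def test_delta_irf_is_identity(self):
        d = np.exp(-T / 3.0)
        irf = np.zeros_like(d)
        irf[0] = 1.0
        assert np.allclose(convolve_with_irf(d, irf, 0.0), d, atol=1e-12)

    def test_shift_commutes_with_convolution(self):
        rng = np.random.default_rng(0)
        d = np.exp(-T / 2.0)
        irf = np.exp(-0.5 * ((T - 1.0) / 0.05) ** 2)
        a = convolve_with_irf(d, irf, 7.25)
        shifted_irf = np.interp((np.arange(T.size) - 7.25) % T.size,
                                np.arange(T.size), irf, period=T.size)
        b = convolve_with_irf(d, shifted_irf, 0.0)
        assert np.allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_periodic_wraparound_matches_multi_period_sum(self):
        """Circular convolution equals a brute-force sum over past periods."""
        tau = 8.0                      # comparable to the 12.5-ns period
        d_one = np.exp(-T / tau)       # single-period decay, no pile-up norm
        irf = np.exp(-0.5 * ((T - 1.0) / 0.05) ** 2)
        kernel = irf / irf.sum()
        # brute force: one excitation per period for 10 periods, linear
        # convolution over the long axis, then read the final window
        n = T.size
        t_long = np.arange(10 * n) * (PERIOD / n)
        single_shot = np.convolve(kernel, np.exp(-t_long / tau))[:10 * n]
        brute = np.zeros(n)
        for k in range(10):
            brute += single_shot[k * n:(k + 1) * n]
        periodic_d = d_one / (1.0 - np.exp(-PERIOD / tau))
        circ = convolve_with_irf(periodic_d, irf, 0.0)
        assert np.allclose(circ, brute, rtol=1e-4)
        # tail wrap: early bins exceed the non-periodic convolution
        nonper = np.convolve(d_one, kernel)[:n]
        assert circ[0] > nonper[0]

    def test_count_conservation(self):
        d = np.exp(-T / 3.0)
        irf = np.exp(-0.5 * ((T - 1.0) / 0.05) ** 2) * 42.0
        out = convolve_with_irf(d, irf, 3.5)
        assert out.sum() == pytest.approx(d.sum(), rel=1e-9)

    def test_empty_irf_rejected(self):
        with pytest.raises(InvalidParameterError):
            convolve_with_irf(np.ones(16), np.zeros(16))


class TestGlobalFit:
    def test_noise_free_exact_recovery(self):
        hist, truth = gen_tcspc(total_counts=1e6, poisson=False, seed=0)
        res = TcspcModel(hist).fit()
        assert res.tau == pytest.approx(truth.tau, rel=1e-4)
        assert res.phi == pytest.approx(truth.phi, rel=1e-4)
        assert res.model.r0 == pytest.approx(truth.r0, rel=1e-4)
        assert res.model.amplitude == pytest.approx(truth.amplitude, rel=1e-4)

    def test_poisson_recovery_of_rotational_correlation(self):
        """Free-fluorophore conditions: phi recovered near 18 ns."""
        phis = [TcspcModel(gen_tcspc(total_counts=1e6, seed=s)[0]).fit().phi
                for s in range(10)]
        assert abs(np.mean(phis) - 18.0) <= 2.0

    def test_slow_tumbling_has_wide_uncertainty(self):
        """phi far beyond the window is recovered with a large stderr."""
        slow = DecayModel(tau=3.0, phi=40.0, r0=0.38)
        fast = DecayModel(tau=3.0, phi=5.0, r0=0.38)
        se = {}
        for name, m in (("slow", slow), ("fast", fast)):
            hist, _ = gen_tcspc(model=m, total_counts=1e6, seed=1)
            res = TcspcModel(hist).fit()
            se[name] = res.stderr["phi"] / res.phi
        assert se["slow"] > 3 * se["fast"]

    def test_low_count_warning(self):
        hist, _ = gen_tcspc(total_counts=5e3, seed=2)
        with pytest.warns(RuntimeWarning, match="counts"):
            TcspcModel(hist)

    def test_recovery_bias_over_seeds(self):
        """tau and phi are unbiased within 3 MC standard errors (50 seeds)."""
        taus, phis = [], []
        for s in range(50):
            hist, _ = gen_tcspc(total_counts=1e6, seed=s)
            res = TcspcModel(hist).fit()
            taus.append(res.tau)
            phis.append(res.phi)
        taus, phis = np.array(taus), np.array(phis)
        assert abs(taus.mean() - 3.0) <= 3 * taus.std(ddof=1) / np.sqrt(50)
        assert abs(phis.mean() - 18.0) <= 3 * phis.std(ddof=1) / np.sqrt(50)


class TestGFactor:
    def _reference_hist(self, g, seed=0, sensitivity=1.0):
        # fast-tumbling dye: anisotropy gone well inside the window
        m = DecayModel(tau=4.0, phi=0.15, r0=0.38, g=g)
        hist, _ = gen_tcspc(model=m, total_counts=2e6, seed=seed)
        if sensitivity != 1.0:
            from dataclasses import replace
            hist = replace(hist, counts_par=hist.counts_par * sensitivity)
        return hist

    def test_reference_dye_recovers_g(self):
        g_hat = estimate_g_factor(self._reference_hist(1.061))
        assert g_hat == pytest.approx(1.061, rel=0.01)

    def test_unity_g(self):
        g_hat = estimate_g_factor(self._reference_hist(1.0))
        assert g_hat == pytest.approx(1.0, rel=0.01)

    def test_doubled_sensitivity_doubles_g(self):
        base = estimate_g_factor(self._reference_hist(1.0, seed=3))
        doubled = estimate_g_factor(self._reference_hist(1.0, seed=3,
                                                         sensitivity=2.0))
        assert doubled == pytest.approx(2.0 * base, rel=1e-9)

    def test_sparse_tail_warns(self):
        hist, _ = gen_tcspc(model=DecayModel(tau=2.0, phi=0.1, r0=0.3),
                            total_counts=2e4, seed=1)
        with pytest.warns(RuntimeWarning):
            estimate_g_factor(hist, tail_fraction=0.4)
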