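"""Spectral unmixing, sensitized-emission efficiency, population statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokit import (EmissionSpectrum, FretConfig, UnmixResult,
                     apparent_fret, population_stats, unmix)
from allokit.datasets import ReferenceSpectra
from allokit.exceptions import (InvalidParameterError, PairingError,
                                UnidentifiableError)
from allokit.fret import gaussian_histogram_fit, unpaired_test
from allokit.synthetic import gen_spectra


def _spectrum(refs, y, cell="c1"):
    return EmissionSpectrum(wavelengths=refs.wavelengths, intensities=y,
                            cell_id=cell)


class TestUnmix:
    def test_pure_donor_exact(self, refs):
        um = unmix(_spectrum(refs, 3.7 * refs.em_d), refs)
        assert um.k_d == pytest.approx(3.7, abs=1e-9)
        assert um.k_a == pytest.approx(0.0, abs=1e-9)

    def test_three_colour_exact_mixture(self, refs):
        y = 2.0 * refs.em_d + 5.0 * refs.em_a + 1.0 * refs.em_b
        um = unmix(_spectrum(refs, y), refs, n_colors=3)
        assert (um.k_d, um.k_a, um.k_b) == pytest.approx((2.0, 5.0, 1.0),
                                                         abs=1e-9)
        assert um.rss == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_exactness_on_random_mixtures(self, seed):
        """Noise-free mixtures are recovered to machine precision."""
        from allokit.synthetic import reference_spectra
        refs = reference_spectra()
        rng = np.random.default_rng(seed)
        k = rng.uniform(0.1, 10.0, 3)
        y = k[0] * refs.em_d + k[1] * refs.em_a + k[2] * refs.em_b
        um = unmix(_spectrum(refs, y), refs, n_colors=3)
        assert np.allclose([um.k_d, um.k_a, um.k_b], k, atol=1e-8)

    def test_plain_least_squares_matches_nnls_interior(self, refs):
        y = 2.0 * refs.em_d + 5.0 * refs.em_a
        a = unmix(_spectrum(refs, y), refs, nonneg=True)
        b = unmix(_spectrum(refs, y), refs, nonneg=False)
        assert a.k_d == pytest.approx(b.k_d, abs=1e-9)
        assert a.k_a == pytest.approx(b.k_a, abs=1e-9)

    def test_collinear_references_rejected(self, refs):
        bad = ReferenceSpectra(wavelengths=refs.wavelengths, em_d=refs.em_d,
                               em_a=refs.em_d * (1 - 1e-12))
        with pytest.raises(UnidentifiableError):
            unmix(_spectrum(bad, refs.em_d), bad)

    def test_grid_mismatch_rejected(self, refs):
        sp = EmissionSpectrum(wavelengths=refs.wavelengths + 1.0,
                              intensities=refs.em_d)
        with pytest.raises(Exception):
            unmix(sp, refs)

    def test_coefficient_errors_scale_with_noise(self, refs):
        """Coefficient scatter doubles when the spectral noise SD doubles."""
        spreads = []
        for noise in (0.01, 0.02):
            k_ds = []
            for seed in range(40):
                rng = np.random.default_rng(seed + int(noise * 1e4))
                y = 3.0 * refs.em_d + 4.0 * refs.em_a
                y = y + rng.normal(0, noise * y.max(), y.size)
                k_ds.append(unmix(_spectrum(refs, y), refs).k_d)
            spreads.append(np.std(k_ds, ddof=1))
        assert spreads[1] / spreads[0] == pytest.approx(2.0, rel=0.35)


class TestApparentFret:
    def test_no_donor_means_full_efficiency(self):
        e = apparent_fret(UnmixResult(k_d=0.0, k_a=5.0, k_b=None, rss=0.0))
        assert e == pytest.approx(100.0)

    def test_unit_coefficient_ratio_value(self):
        """k_D equal to the corrected k_A gives E = 100/(1 + 0.22/0.70*0.94)."""
        cfg = FretConfig()
        k_a_raw = 1.0 / (1.0 - cfg.direct_excitation_fraction)
        e = apparent_fret(UnmixResult(k_d=1.0, k_a=k_a_raw, k_b=None, rss=0.0))
        assert e == pytest.approx(100.0 / (1.0 + (0.22 / 0.70) * 0.94),
                                  abs=1e-9)
        assert e == pytest.approx(77.2, abs=0.1)

    def test_default_constants(self):
        cfg = FretConfig()
        assert (cfg.q_d, cfg.q_a, cfg.w_ratio,
                cfg.direct_excitation_fraction) == (0.70, 0.22, 0.94, 0.06)

    def test_no_acceptor_rejected(self):
        with pytest.raises(InvalidParameterError):
            apparent_fret(UnmixResult(k_d=1.0, k_a=0.0, k_b=None, rss=0.0))

    def test_strictly_decreasing_in_donor_acceptor_ratio(self):
        ratios = np.logspace(-2, 2, 50)
        es = [apparent_fret(UnmixResult(k_d=r, k_a=1.0, k_b=None, rss=0.0))
              for r in ratios]
        assert np.all(np.diff(es) < 0)

    def test_w_ratio_recomputation_close_to_default(self, refs):
        cfg = FretConfig.from_references(refs)
        assert cfg.w_ratio == pytest.approx(refs.spectral_integral_ratio())
        assert cfg.w_ratio > 0


class TestPopulation:
    def test_gaussian_mean_recovery(self):
        rng = np.random.default_rng(3)
        e = rng.normal(59.2, 7.7, 31)
        pop = population_stats(e)
        assert abs(pop.mu - 59.2) <= 3 * 7.7 / np.sqrt(31)
        assert pop.sigma == pytest.approx(e.std(ddof=0))

    def test_constant_input_degenerate_warning(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            pop = population_stats(np.full(10, 50.0))
        assert pop.sigma == pytest.approx(0.0)

    def test_paired_shift_recovery_over_seeds(self):
        """A fixed before/after shift is recovered within 3 SEM each seed."""
        shift = 21.6
        for seed in range(20):
            rng = np.random.default_rng(seed)
            before = rng.normal(60.0, 8.0, 26)
            after = before + rng.normal(shift, 11.2, 26)
            pop = population_stats(before, paired_after=after)
            sem = pop.delta_sd / np.sqrt(26)
            assert abs(pop.delta_mean - shift) <= 3 * sem

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(PairingError):
            population_stats(np.zeros(10) + 50, paired_after=np.zeros(9) + 50)

    def test_too_few_cells_rejected(self):
        with pytest.raises(InvalidParameterError):
            population_stats([50.0, 60.0])

    def test_histogram_fit_agrees_with_mle(self):
        rng = np.random.default_rng(12)
        e = rng.normal(60.0, 8.0, 500)
        mu_h, sigma_h, _ = gaussian_histogram_fit(e)
        assert mu_h == pytest.approx(e.mean(), abs=1.0)
        assert sigma_h == pytest.approx(e.std(), rel=0.2)

    def test_welch_test_detects_separated_groups(self):
        rng = np.random.default_rng(5)
        t, p = unpaired_test(rng.normal(50, 5, 30), rng.normal(70, 5, 30))
        assert p < 1e-6


class TestRoundTrip:
    def test_noise_free_round_trip_exact(self, refs):
        """Generator inversion and pipeline recovery agree to 1e-9."""
        spectra, e_true, _ = gen_spectra(n_cells=8, noise=0.0, seed=4,
                                         refs=refs)
        e_hat = [apparent_fret(unmix(sp, refs)) for sp in spectra]
        assert np.allclose(e_hat, e_true, atol=1e-9)

    def test_three_colour_round_trip(self, refs):
        spectra, e_true, _ = gen_spectra(n_cells=6, noise=0.0, k_b_mean=30.0,
                                         seed=9, refs=refs)
        e_hat = [apparent_fret(unmix(sp, refs, n_colors=3)) for sp in spectra]
        assert np.allclose(e_hat, e_true, atol=1e-6)

    def test_population_parameters_recovered(self, refs):
        spectra, _, _ = gen_spectra(mu=59.2, sigma=7.7, n_cells=31,
                                    noise=0.01, seed=1, refs=refs)
        e = [apparent_fret(unmix(sp, refs)) for sp in spectra]
        pop = population_stats(e)
        assert abs(pop.mu - 59.2) <= 4.0
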