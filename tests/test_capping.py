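"""Mechanistic capping kinetics: rate derivation, ODE simulation, protocols."""

import numpy as np
import pytest

from allokit import (MechanismParams, ModulationModel, Protocol, derive_rates,
                     dose_response, equilibrium_binding, simulate)
from allokit.capping import equilibration_time
from allokit.exceptions import InvalidParameterError
from conftest import random_mechanism


class TestDeriveRates:
    def test_neutral_cooperativity_leaves_rates_unchanged(self):
        p = MechanismParams(k_l=1e-9, k_a=1e-5, alpha=1.0, k_off_l=0.02,
                            k_off_a=10.0)
        r = derive_rates(p)
        assert r.k_on_al == pytest.approx(r.k_on_a)
        assert r.k_off_al == pytest.approx(r.k_off_a)

    @pytest.mark.parametrize("partition", ["inverse", "direct"])
    def test_ratio_identity_on_random_draws(self, partition):
        """k_-AL / k_+AL = alpha * K_A for any valid parameters."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = random_mechanism(rng)
            r = derive_rates(p, partition=partition)
            assert r.k_off_al / r.k_on_al == pytest.approx(
                p.alpha * p.k_a, rel=1e-10)

    def test_default_partition_exponent_is_two(self):
        assert MechanismParams(k_l=1e-9, k_a=1e-5, alpha=2.0,
                               k_off_l=0.02, k_off_a=10.0).j == 2

    def test_invalid_alpha_rejected(self):
        with pytest.raises(InvalidParameterError):
            MechanismParams(k_l=1e-9, k_a=1e-5, alpha=-1.0,
                            k_off_l=0.02, k_off_a=10.0)


class TestSimulate:
    def test_no_modulator_reduces_to_pseudo_first_order(self, capping_params):
        proto = Protocol(mode="simultaneous", l_conc=1e-8, a_conc=0.0,
                         post_incubation=600.0)
        sim = simulate(capping_params, proto)
        rates = derive_rates(capping_params)
        k_on_eff = rates.k_on_l * proto.l_conc
        rl_eq = capping_params.r_total * k_on_eff / (k_on_eff + rates.k_off_l)
        expected = rl_eq * (1.0 - np.exp(-(k_on_eff + rates.k_off_l)
                                         * sim.times))
        assert np.allclose(sim.bound_orthosteric, expected,
                           rtol=1e-6, atol=1e-12 * capping_params.r_total)

    def test_mass_conservation(self, capping_params):
        proto = Protocol(mode="A_first", l_conc=1e-8, a_conc=1e-4,
                         post_incubation=1000.0)
        sim = simulate(capping_params, proto)
        assert sim.conservation_error() <= 1e-9
        for state in (sim.r, sim.rl, sim.ar, sim.arl):
            assert np.all(state >= -1e-12 * capping_params.r_total)

    def test_long_time_limit_matches_closed_form(self, capping_params):
        """ODE relaxation agrees with the ternary-complex equilibrium."""
        rates = derive_rates(capping_params)
        for a in np.logspace(-7, -2, 12):
            t_eq = equilibration_time(rates, 1e-8, a)
            proto = Protocol(mode="simultaneous", l_conc=1e-8, a_conc=a,
                             post_incubation=t_eq)
            sim = simulate(capping_params, proto, times=np.array([t_eq]))
            occ = sim.bound_orthosteric[-1] / capping_params.r_total
            assert occ == pytest.approx(
                equilibrium_binding(capping_params, 1e-8, a), rel=1e-6)

    def test_partition_invariance_of_equilibrium(self):
        """j moves the kinetics but never the long-time limit."""
        base = dict(k_l=1e-9, k_a=1e-5, alpha=30.0, k_off_l=0.01,
                    k_off_a=5.0)
        finals = []
        for j in (0, 1, 2, 3):
            p = MechanismParams(**base, j=j)
            rates = derive_rates(p)
            t_eq = equilibration_time(rates, 1e-8, 1e-4)
            sim = simulate(p, Protocol(mode="simultaneous", l_conc=1e-8,
                                       a_conc=1e-4, post_incubation=t_eq),
                           times=np.array([t_eq]))
            finals.append(sim.bound_orthosteric[-1])
        assert np.allclose(finals, finals[0], rtol=1e-6)

    def test_capping_slows_equilibration_monotonically(self, capping_params):
        """For alpha > 1, time to 90% of equilibrium grows with [A]."""
        rates = derive_rates(capping_params)
        doses = [0.0, 1e-5, 1e-4, 1e-3]
        t_max = max(equilibration_time(rates, 1e-8, a) for a in doses[1:])
        grid = np.geomspace(1e-2, t_max, 2000)
        t90s = []
        for a in doses:
            eq = equilibrium_binding(capping_params, 1e-8, a) \
                * capping_params.r_total
            proto = Protocol(mode="simultaneous", l_conc=1e-8, a_conc=a,
                             post_incubation=t_max)
            sim = simulate(capping_params, proto, times=grid)
            start = sim.bound_orthosteric[0]
            gap = np.abs(sim.bound_orthosteric - eq) / abs(eq - start)
            t90s.append(sim.times[np.argmax(gap <= 0.1)])
        t90s = np.array(t90s)
        # allow the shared-grid resolution (about 1%) as slack
        assert np.all(np.diff(t90s) >= -0.02 * t90s[:-1])


class TestEquilibrium:
    def test_neutral_cooperativity_cancels(self):
        p = MechanismParams(k_l=1e-9, k_a=1e-5, alpha=1.0, k_off_l=0.02,
                            k_off_a=10.0)
        occs = [equilibrium_binding(p, 1e-8, a) for a in (0.0, 1e-6, 1e-3)]
        langmuir = 1e-8 / (p.k_l + 1e-8)
        assert np.allclose(occs, langmuir, rtol=1e-12)

    def test_no_modulator_is_langmuir(self, capping_params):
        occ = equilibrium_binding(capping_params, 3e-9, 0.0)
        assert occ == pytest.approx(3e-9 / (capping_params.k_l + 3e-9))

    def test_detailed_balance_over_random_mechanisms(self):
        """Long-time ODE state distribution equals the closed form, broadly."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_mechanism(rng)
            rates = derive_rates(p)
            l_conc, a_conc = 3.0 * p.k_l, 3.0 * p.k_a
            t_eq = equilibration_time(rates, l_conc, a_conc)
            sim = simulate(p, Protocol(mode="simultaneous", l_conc=l_conc,
                                       a_conc=a_conc, post_incubation=t_eq),
                           times=np.array([t_eq]))
            occ = sim.bound_orthosteric[-1] / p.r_total
            assert occ == pytest.approx(
                equilibrium_binding(p, l_conc, a_conc), rel=1e-6)


class TestProtocols:
    def test_order_of_addition_pattern(self, capping_params):
        """Pre-equilibration with the orthosteric ligand protects binding:
        a 3-h read after adding modulator shows little loss, while the
        simultaneous read at equilibrium is fully inhibited."""
        a_series = np.logspace(-6, -1, 8)
        l_first = Protocol(mode="L_first", pre_incubation=120.0,
                           post_incubation=180.0, l_conc=1e-8)
        sim_eq = Protocol(mode="simultaneous", post_incubation=1260.0,
                          l_conc=1e-8)
        curves_lf = dose_response(capping_params, l_first,
                                  np.concatenate([[0.0], a_series]), [180.0])
        curves_sim = dose_response(capping_params, sim_eq, a_series,
                                   ["equilibrium"])
        y_lf = next(iter(curves_lf.values())).response
        y_sim = next(iter(curves_sim.values())).response
        control = equilibrium_binding(capping_params, 1e-8, 0.0)
        # L-first: essentially flat relative to its own modulator-free read
        assert np.max(np.abs(y_lf[1:] - y_lf[0])) <= 0.1 * y_lf[0]
        # simultaneous equilibrium read: >80% inhibited at the top dose
        assert y_sim[-1] <= 0.2 * control
        # the equilibrium read never exceeds the protected read (tolerance
        # covers finite-time convergence at doses where they coincide)
        assert np.all(y_sim <= y_lf[1:] + 1e-3)

    def test_equilibrium_read_is_monophasic_unit_slope(self, capping_params,
                                                       simultaneous_protocol):
        """A capping mechanism read at equilibrium produces a monophasic
        inhibition curve with a unit Hill slope."""
        a_series = np.logspace(-7, -1, 14)
        curves = dose_response(capping_params, simultaneous_protocol,
                               a_series, ["equilibrium"])
        curve = next(iter(curves.values()))
        res = ModulationModel([curve], n_components=1, nh_policy="tested",
                              seed=0).fit()
        assert res.nh_fixed                    # nH indistinguishable from 1
        assert res.y0[0] > res.yinf[0]         # inhibitory

    def test_neutral_modulator_gives_flat_curve(self):
        p = MechanismParams(k_l=1e-9, k_a=1e-5, alpha=1.0, k_off_l=0.02,
                            k_off_a=10.0)
        proto = Protocol(mode="simultaneous", l_conc=1e-8,
                         post_incubation=2000.0)
        curves = dose_response(p, proto, np.logspace(-7, -2, 8),
                               ["equilibrium"])
        y = next(iter(curves.values())).response
        assert np.ptp(y) <= 1e-6 * y.mean()

    def test_read_times_differ_most_at_intermediate_doses(self, capping_params):
        proto = Protocol(mode="simultaneous", l_conc=1e-8,
                         post_incubation=1260.0)
        a_series = np.logspace(-7, -1, 13)
        curves = dose_response(capping_params, proto, a_series,
                               [5.0, "equilibrium"])
        times = sorted(curves)
        early, late = curves[times[0]].response, curves[times[1]].response
        gap = np.abs(early - late)
        assert gap.argmax() not in (0, gap.size - 1)
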