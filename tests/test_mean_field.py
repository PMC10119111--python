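"""Mean-field AdEx population model: transfer function, dynamics,
steady states and glutamate release."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvcsim import adex
from nvcsim.mean_field import (NeuronalState, glutamate,
                               mean_field_derivatives, steady_state,
                               transfer_function, _relax)


class TestTransferFunction:
    def test_quiescent_at_zero_input(self, neuronal_params):
        # the network shows no spontaneous activity
        assert transfer_function(0.0, 0.0, 0.0, neuronal_params) < 0.1
        assert transfer_function(0.0, 0.0, 0.0, neuronal_params, "i") < 0.1

    def test_monotone_in_excitation(self, neuronal_params):
        rates = [transfer_function(fe, 8.0, 50e-12, neuronal_params)
                 for fe in np.linspace(0.5, 12.0, 15)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert all(math.isfinite(r) and r >= 0 for r in rates)

    def test_non_increasing_in_adaptation(self, neuronal_params):
        rates = [transfer_function(6.0, 10.0, w, neuronal_params)
                 for w in np.linspace(0.0, 400e-12, 9)]
        assert all(b <= a + 1e-12 for a, b in zip(rates, rates[1:]))

    def test_strong_adaptation_silences(self, neuronal_params):
        assert transfer_function(6.0, 10.0, 5e-9, neuronal_params) < 1e-12

    def test_rejects_bad_arguments(self, neuronal_params):
        with pytest.raises(ValueError):
            transfer_function(float("nan"), 0.0, 0.0, neuronal_params)
        with pytest.raises(ValueError):
            transfer_function(-1.0, 0.0, 0.0, neuronal_params)

    def test_tabulated_override(self, neuronal_params):
        p = dataclasses.replace(neuronal_params,
                                transfer_table=lambda fe, fi, w: 7.5)
        assert transfer_function(3.0, 3.0, 0.0, p) == 7.5

    def test_matches_single_neuron_monte_carlo(self, neuronal_params):
        """Semi-analytic rate vs a direct AdEx Monte-Carlo at the
        operating point of the standard stimulus (within 2 SE)."""
        s = steady_state(4.0, neuronal_params)
        fe = s.nu_e + 4.0
        neuron = adex.AdExNeuron.from_population(neuronal_params, "e")
        mc, se = adex.simulate_rates([fe], [s.nu_i], [s.W], neuron,
                                     K_e=neuronal_params.K_e,
                                     K_i=neuronal_params.K_i,
                                     t_sim=60.0, seed=5, return_se=True)
        tf = transfer_function(fe, s.nu_i, s.W, neuronal_params)
        assert abs(tf - mc[0]) < 2.0 * se[0]


class TestDynamics:
    def test_quiescent_fixed_point(self, neuronal_params):
        d = mean_field_derivatives(NeuronalState(0, 0, 0), 0.0,
                                   neuronal_params)
        assert abs(d.nu_e) < 1e-9 and abs(d.nu_i) < 1e-9 and d.W == 0.0

    def test_adaptation_decays_exponentially(self, neuronal_params):
        # with F == 0 and b = 0, W(t) = W0 exp(-t / tau_w)
        p = dataclasses.replace(neuronal_params, b=0.0,
                                transfer_table=lambda fe, fi, w: 0.0)
        w0 = 100e-12
        out = _relax(NeuronalState(0, 0, w0), 0.0, p, t_sim=1.0, dt=1e-3)
        assert out.W == pytest.approx(w0 * math.exp(-1.0 / p.tau_w),
                                      rel=1e-6)

    def test_steady_state_contract(self, neuronal_params):
        s = steady_state(0.0, neuronal_params)
        assert (s.nu_e, s.nu_i, s.W) == (0.0, 0.0, 0.0)
        s4 = steady_state(4.0, neuronal_params)
        d = mean_field_derivatives(s4, 4.0, neuronal_params)
        assert abs(d.nu_e) * neuronal_params.T < 1e-8
        assert abs(d.nu_i) * neuronal_params.T < 1e-8

    def test_steady_state_matches_forward_integration(self, neuronal_params):
        """The fixed point equals the plateau of a long forward
        integration at the same drive."""
        s = steady_state(4.0, neuronal_params)
        fwd = _relax(NeuronalState(0, 0, 0), 4.0, neuronal_params,
                     t_sim=40.0, dt=5e-4)
        assert fwd.nu_e == pytest.approx(s.nu_e, rel=1e-6)
        assert fwd.nu_i == pytest.approx(s.nu_i, rel=1e-6)

    def test_equilibrium_curve_saturates(self, neuronal_params):
        """nu_e(nu_ext) is increasing with decreasing slope at high
        drive."""
        drives = [1.0, 2.0, 4.0, 6.0, 8.0]
        nu = [steady_state(d, neuronal_params).nu_e for d in drives]
        assert all(b > a for a, b in zip(nu, nu[1:]))
        slopes = np.diff(nu) / np.diff(drives)
        assert slopes[-1] < slopes[0]

    def test_rk4_matches_fine_euler_oracle(self, neuronal_params):
        """Production integration agrees with a much finer explicit
        Euler scheme on a transient."""
        p = neuronal_params
        coarse = _relax(NeuronalState(0, 0, 0), 3.0, p, t_sim=4.0, dt=1e-3)
        y = np.zeros(3)
        dt = 2e-5
        for k in range(int(4.0 / dt)):
            d = mean_field_derivatives(NeuronalState(*y), 3.0, p)
            y = y + dt * np.array([d.nu_e, d.nu_i, d.W])
            y[0] = max(y[0], 0.0)
            y[1] = max(y[1], 0.0)
        assert coarse.nu_e == pytest.approx(y[0], rel=1e-4)
        assert coarse.nu_i == pytest.approx(y[1], rel=1e-4)


class TestGlutamate:
    def test_zero_and_proportionality(self, neuronal_params):
        assert glutamate(0.0, 0.0, neuronal_params) == 0.0
        # with g_ext = 0, release is proportional to recurrent activity
        g1 = glutamate(1.0, 3.0, neuronal_params)
        g2 = glutamate(2.0, 7.0, neuronal_params)
        assert g2 == pytest.approx(2.0 * g1)

    @settings(max_examples=50, deadline=None)
    @given(nu_e=st.floats(0, 50), nu_ext=st.floats(0, 20),
           a=st.floats(0, 5), b=st.floats(0, 5))
    def test_superposition_exact(self, neuronal_params, nu_e, nu_ext, a, b):
        lhs = glutamate(a * nu_e, b * nu_ext, neuronal_params)
        rhs = (a * glutamate(nu_e, 0.0, neuronal_params)
               + b * glutamate(0.0, nu_ext, neuronal_params))
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-15)

    def test_rejects_negative_rates(self, neuronal_params):
        with pytest.raises(ValueError):
            glutamate(-1.0, 0.0, neuronal_params)
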