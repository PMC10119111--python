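"""Astrocyte calcium dynamics, IP3 turnover and the AA/PGE2 cascade."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import fsolve

from conftest import astro_euler
from nvcsim.astrocyte import (AstrocyteState, aa_pg_derivatives,
                              astro_derivatives, calcium_fluxes,
                              gating_dynamics, hill, ip3_derivative,
                              resting_astrocyte)

#: Sustained glutamate levels bracketing the calcium-spiking threshold
#: of the default astrocyte (found by bisection in the tests below).
GLU_SUB, GLU_SUPRA = 0.02, 0.25


def rk4_astro(params, glu_of_t, t_total, dt, y0):
    """Production-style classical RK4 on the astrocyte subsystem."""
    n = int(round(t_total / dt))
    out = np.empty((n, 5))
    y = np.asarray(y0, float).copy()
    for k in range(n):
        t = k * dt
        f = lambda yy, tt: astro_derivatives(
            AstrocyteState(*yy), glu_of_t(tt), params).as_array()
        k1 = f(y, t)
        k2 = f(y + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = f(y + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = f(y + dt * k3, t + dt)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        y[1] = min(max(y[1], 0.0), 1.0)
        out[k] = y
    return out


class TestHill:
    def test_anchor_points(self):
        assert hill(0.0, 1.0) == 0.0
        assert hill(2.0, 2.0) == 0.5
        assert hill(3.0, 1.0, 2) == pytest.approx(9.0 / 10.0)

    def test_rejects_nonpositive_constant(self):
        with pytest.raises(ValueError):
            hill(1.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(0.0, 100.0), dx=st.floats(1e-6, 10.0),
           K=st.floats(1e-3, 50.0))
    def test_strictly_increasing_and_bounded(self, x, dx, K):
        assert 0.0 <= hill(x, K) < 1.0
        assert hill(x + dx, K) > hill(x, K)


class TestCalciumFluxes:
    def test_channel_flux_vanishes_when_store_empty(self, astrocyte_params):
        p = astrocyte_params
        ca = p.C_T / (1.0 + p.rho_A)
        s = AstrocyteState(Ca=ca, h=0.8, IP3=0.5)
        J_C, _, _ = calcium_fluxes(s, p)
        assert J_C == pytest.approx(0.0, abs=1e-12)

    def test_pump_vanishes_at_zero_calcium(self, astrocyte_params):
        s = AstrocyteState(Ca=0.0, h=0.8, IP3=0.5)
        assert calcium_fluxes(s, astrocyte_params)[2] == 0.0

    def test_leak_sign_switch(self, astrocyte_params):
        s = AstrocyteState(Ca=0.3, h=0.8, IP3=0.3)
        p_minus = dataclasses.replace(astrocyte_params, leak_sign=-1)
        _, jl_plus, _ = calcium_fluxes(s, astrocyte_params)
        _, jl_minus, _ = calcium_fluxes(s, p_minus)
        # the printed (1 - rho) variant leaks more at positive calcium
        assert jl_minus > jl_plus

    def test_resting_point_balances_fluxes(self, astrocyte_params):
        """The resting state solves J_C + J_L - J_P = 0 (and the other
        derivatives vanish), cross-checked with an independent
        root-finder on the full right-hand side."""
        rest = resting_astrocyte(astrocyte_params, 0.0)
        J_C, J_L, J_P = calcium_fluxes(rest, astrocyte_params)
        assert J_C + J_L - J_P == pytest.approx(0.0, abs=1e-7)

        def rhs(v):
            return astro_derivatives(AstrocyteState(*v), 0.0,
                                     astrocyte_params).as_array()

        root = fsolve(rhs, rest.as_array())
        assert np.allclose(root, rest.as_array(), atol=1e-6)


class TestGating:
    def test_full_deinactivation_at_zero_calcium(self, astrocyte_params):
        h_inf, tau_h = gating_dynamics(AstrocyteState(Ca=0.0, IP3=0.3),
                                       astrocyte_params)
        assert h_inf == pytest.approx(1.0)
        assert tau_h > 0

    def test_binding_rate_scales_time_constant(self, astrocyte_params):
        s = AstrocyteState(Ca=0.2, IP3=0.4)
        p10 = dataclasses.replace(astrocyte_params,
                                  O_2=10 * astrocyte_params.O_2)
        _, tau1 = gating_dynamics(s, astrocyte_params)
        h10, tau10 = gating_dynamics(s, p10)
        assert tau10 == pytest.approx(tau1 / 10.0)
        assert h10 == pytest.approx(gating_dynamics(s, astrocyte_params)[0])


class TestIP3:
    def test_basal_fixed_point(self, astrocyte_params):
        rest = resting_astrocyte(astrocyte_params, 0.0)
        d = ip3_derivative(rest.IP3, rest.Ca, 0.0, astrocyte_params)
        assert d == pytest.approx(0.0, abs=1e-7)

    def test_production_saturates_in_glutamate(self, astrocyte_params):
        p = astrocyte_params
        d_inf = ip3_derivative(0.5, 0.3, 1e9, p)
        assert math.isfinite(d_inf)
        # bounded by the maximal PLC rates
        assert d_inf < p.O_beta + p.O_delta

    def test_spiking_threshold_in_glutamate(self, astrocyte_params):
        """A sustained glutamate step above threshold produces calcium
        spikes; below threshold it does not (threshold located by the
        full ODE oracle)."""
        rest = resting_astrocyte(astrocyte_params, 0.0)

        def max_rise(glu):
            tr = rk4_astro(astrocyte_params, lambda t: glu, 60.0, 2e-3,
                           rest.as_array())
            return tr[:, 0].max() - rest.Ca

        assert max_rise(GLU_SUB) < 0.25
        assert max_rise(GLU_SUPRA) > 0.4


class TestAAPG:
    def test_origin_is_fixed_point(self, astrocyte_params):
        assert aa_pg_derivatives(0.0, 0.0, 0.0, astrocyte_params) == (0, 0)

    def test_aa_steady_state_closed_form(self, astrocyte_params):
        p = astrocyte_params
        c = 0.4
        aa_star = p.tau_AA * p.O_AA * c / (p.K_AA + c)
        d_aa, _ = aa_pg_derivatives(aa_star, 0.0, c, p)
        assert d_aa == pytest.approx(0.0, abs=1e-12)

    def test_cascade_peak_ordering(self, astrocyte_params):
        """On a single calcium spike, AA peaks after Ca and PG after
        AA (the cascade lags accumulate)."""
        rest = resting_astrocyte(astrocyte_params, 0.0)
        glu = lambda t: GLU_SUPRA if 1.0 <= t < 3.0 else 0.0
        tr = rk4_astro(astrocyte_params, glu, 15.0, 1e-3,
                       rest.as_array())
        t_ca = np.argmax(tr[:, 0])
        t_aa = np.argmax(tr[:, 3])
        t_pg = np.argmax(tr[:, 4])
        assert t_ca < t_aa < t_pg


class TestIntegrationProperties:
    def test_gate_stays_in_unit_interval_and_matches_fine_oracle(
            self, astrocyte_params):
        """One spike integrated with RK4 at the production step matches
        a 10x-finer explicit-Euler oracle; h never leaves [0, 1]."""
        rest = resting_astrocyte(astrocyte_params, 0.0)
        glu = lambda t: GLU_SUPRA if 1.0 <= t < 3.0 else 0.0
        coarse = rk4_astro(astrocyte_params, glu, 8.0, 1e-3,
                           rest.as_array())
        fine = astro_euler(astrocyte_params, glu, 8.0, 1e-4,
                           rest.as_array())
        assert np.all(coarse[:, 1] >= 0.0) and np.all(coarse[:, 1] <= 1.0)
        ca_c = coarse[::1, 0]
        ca_f = fine[9::10, 0]
        scale = np.abs(ca_f).max()
        assert np.abs(ca_c - ca_f).max() / scale < 1e-3

    def test_post_stimulus_calcium_dips_below_basal(self, astrocyte_params):
        """After a stimulus ends, calcium undershoots its basal level
        while the IP3R gate recovers."""
        rest = resting_astrocyte(astrocyte_params, 0.0)
        glu = lambda t: 0.3 if 1.0 <= t < 13.0 else 0.0
        tr = rk4_astro(astrocyte_params, glu, 40.0, 2e-3, rest.as_array())
        post = tr[int(15.0 / 2e-3):, 0]
        assert post.min() < rest.Ca
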