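"""Astrocytic calcium dynamics and the vasodilator cascade.

Cytosolic calcium follows the Li-Rinzel reduction of IP3-receptor
kinetics: Ca2+ exchanges between cytosol and endoplasmic reticulum
through an IP3-gated channel flux J_C, a passive leak J_L and a SERCA
pump J_P,

    dCa/dt = J_C + J_L - J_P
    dh/dt  = (h_inf - h) / tau_h

with m_inf = H(IP3, d1) H(Ca, d5) and H the first-order Hill function.
IP3 turnover couples the astrocyte to neuronal activity: production by
glutamate-activated PLC-beta (mGluR pathway) and calcium-activated
PLC-delta, degradation by IP3-3-kinase and 5-phosphatase.  Rising
calcium activates phospholipase A2, releasing arachidonic acid (AA)
which is converted to prostaglandin E2 (PG); both follow
Michaelis-Menten production with linear decay.

Concentrations are uM, times s.  One astrocyte compartment represents
the process and end-foot jointly (propagation delays are negligible on
the vascular timescale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AstrocyteParams

__all__ = ["AstrocyteState", "hill", "calcium_fluxes", "gating_dynamics",
           "ip3_derivative", "aa_pg_derivatives", "astro_derivatives",
           "resting_astrocyte"]


@dataclass
class AstrocyteState:
    """Cytosolic Ca2+ (uM), IP3R gate h, IP3, AA and PG (uM)."""

    Ca: float = 0.07
    h: float = 0.9
    IP3: float = 0.05
    AA: float = 0.0
    PG: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.Ca, self.h, self.IP3, self.AA, self.PG])


def hill(x: float, K: float, n: int = 1) -> float:
    """Hill function x^n / (x^n + K^n), in [0, 1)."""
    if K <= 0:
        raise ValueError("Hill constant K must be > 0")
    if n == 1:
        return x / (x + K)
    xn = x ** n
    return xn / (xn + K ** n)


def calcium_fluxes(state: AstrocyteState,
                   p: AstrocyteParams) -> tuple[float, float, float]:
    """ER fluxes (J_C, J_L, J_P) in uM/s at the given state.

    J_C: IP3-gated calcium-induced calcium release; J_L: ER leak; J_P:
    SERCA re-uptake (Hill order ``p.pump_hill``).  The leak reservoir
    factor uses ``(1 + rho_A)`` by default (``leak_sign`` switches to
    the ``(1 - rho_A)`` variant).
    """
    m_inf = hill(state.IP3, p.d1) * hill(state.Ca, p.d5)
    reservoir = p.C_T - (1.0 + p.rho_A) * state.Ca
    J_C = p.Gamma_C * m_inf ** 3 * state.h ** 3 * reservoir
    leak_res = p.C_T - (1.0 + p.leak_sign * p.rho_A) * state.Ca
    J_L = p.Gamma_L * leak_res
    J_P = p.O_P * hill(state.Ca, p.K_P, p.pump_hill)
    return J_C, J_L, J_P


def gating_dynamics(state: AstrocyteState,
                    p: AstrocyteParams) -> tuple[float, float]:
    """IP3R gate steady state h_inf in (0, 1] and time constant tau_h (s)."""
    denom = p.d2 * (state.IP3 + p.d1) + (state.IP3 + p.d3) * state.Ca
    h_inf = p.d2 * (state.IP3 + p.d1) / denom
    tau_h = (state.IP3 + p.d3) / (p.O_2 * denom)
    return h_inf, tau_h


def ip3_derivative(IP3: float, Ca: float, Glu: float,
                   p: AstrocyteParams) -> float:
    """IP3 turnover (uM/s): PLC-beta + PLC-delta - 3K - 5P.

    The mGluR-driven PLC-beta term saturates in glutamate with a
    calcium-dependent affinity shift; PLC-delta is IP3-inhibited and
    calcium-activated; 3-kinase degradation is Hill-4 in calcium.
    """
    # PLC-beta: glutamate receptor activation
    K_glu = p.K_R * (1.0 + (p.K_p_glu / p.K_R) * hill(Ca, p.K_pi))
    if Glu > 0:
        g = Glu ** p.glu_exp
        gamma = g / (g + K_glu ** p.glu_exp)
    else:
        gamma = 0.0
    J_beta = p.O_beta * gamma
    # PLC-delta: calcium-activated, product-inhibited
    J_delta = (p.O_delta / (1.0 + IP3 / p.kappa_delta)
               * hill(Ca, p.K_delta, 2))
    # degradation
    J_3K = p.O_3K * hill(Ca, p.K_D, 4) * hill(IP3, p.K_3)
    J_5P = p.r_5P * IP3
    return J_beta + J_delta - J_3K - J_5P


def aa_pg_derivatives(AA: float, PG: float, Ca: float,
                      p: AstrocyteParams) -> tuple[float, float]:
    """Michaelis-Menten production / linear decay of AA and PGE2 (uM/s)."""
    dAA = -AA / p.tau_AA + p.O_AA * Ca / (p.K_AA + Ca)
    dPG = -PG / p.tau_PG + p.O_PG * AA / (p.K_PG + AA)
    return dAA, dPG


def astro_derivatives(state: AstrocyteState, Glu: float,
                      p: AstrocyteParams,
                      ca_for_aa: float | None = None) -> AstrocyteState:
    """Full astrocyte right-hand side at glutamate concentration ``Glu``.

    ``ca_for_aa`` optionally replaces the calcium concentration seen by
    the AA production term (used by the amplitude-clamp experiment);
    calcium dynamics itself is untouched.
    """
    J_C, J_L, J_P = calcium_fluxes(state, p)
    dCa = J_C + J_L - J_P
    h_inf, tau_h = gating_dynamics(state, p)
    dh = (h_inf - state.h) / tau_h
    dIP3 = ip3_derivative(state.IP3, state.Ca, Glu, p)
    ca_aa = state.Ca if ca_for_aa is None else ca_for_aa
    dAA, dPG = aa_pg_derivatives(state.AA, state.PG, ca_aa, p)
    return AstrocyteState(dCa, dh, dIP3, dAA, dPG)


def resting_astrocyte(p: AstrocyteParams, Glu: float = 0.0,
                      guess: AstrocyteState | None = None) -> AstrocyteState:
    """Quiescent fixed point of the astrocyte at constant glutamate.

    Solved by damped relaxation followed by a Newton polish.  Only
    meaningful below the oscillation threshold.
    """
    from scipy.optimize import fsolve

    x = (guess or AstrocyteState()).as_array()
    # short relaxation toward the attractor
    dt = 0.01
    for _ in range(20000):
        s = AstrocyteState(*x)
        d = astro_derivatives(s, Glu, p).as_array()
        x = x + dt * d
        x[0] = max(x[0], 1e-9)
        x[1] = min(max(x[1], 0.0), 1.0)
        x[2] = max(x[2], 0.0)

    def fun(y):
        s = AstrocyteState(max(y[0], 1e-9), min(max(y[1], 0.0), 1.0),
                           max(y[2], 0.0), y[3], y[4])
        return astro_derivatives(s, Glu, p).as_array()

    sol, info, ier, _ = fsolve(fun, x, full_output=True)
    if ier != 1:
        sol = x
    return AstrocyteState(max(sol[0], 1e-9), min(max(sol[1], 0.0), 1.0),
                          max(sol[2], 0.0), max(sol[3], 0.0),
                          max(sol[4], 0.0))
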