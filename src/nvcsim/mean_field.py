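"""Mean-field dynamics of an AdEx excitatory/inhibitory network.

The population model is the first-order conductance-based mean field of
a sparsely connected network of adaptive exponential integrate-and-fire
neurons (80% regular-spiking excitatory, 20% fast-spiking inhibitory):

    T dnu_x/dt = F_x(nu_e + nu_ext, nu_i, W) - nu_x      (x = e, i)
    dW/dt      = -W/tau_w + b nu_e + a (mu_V - E_L)

``F`` is the semi-analytic transfer function: Campbell-theorem moments
of the fluctuating membrane potential (mu_V, sigma_V, tau_V) feed a
Gaussian rate estimate with a phenomenological effective threshold
expressed as a second-order polynomial in the normalised moments.  The
polynomial coefficients are fitted against single-neuron simulations
and exposed in :class:`~nvcsim.params.NeuronalParams`; a user-supplied
tabulated transfer function may replace the semi-analytic form.

Synaptic glutamate in the perisynaptic space is proportional to the
mean excitatory conductance drive:

    [Glu] = (g_r nu_e + g_ext nu_ext) * p N_e Q_e tau_e
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import NeuronalParams

__all__ = [
    "NeuronalState", "transfer_function", "membrane_moments",
    "mean_field_derivatives", "steady_state", "glutamate",
    "ConvergenceError",
]

_SQRT2 = math.sqrt(2.0)
# Normalisation of the threshold polynomial domain (volts / dimensionless)
_MUV0, _DMUV0 = -60e-3, 10e-3
_SV0, _DSV0 = 4e-3, 6e-3
_TVN0, _DTVN0 = 0.5, 1.0
# Rate floor avoiding a degenerate zero-variance membrane distribution
_RATE_FLOOR = 1e-9


class ConvergenceError(RuntimeError):
    """Raised when the steady-state relaxation fails to settle."""


@dataclass
class NeuronalState:
    """Mean excitatory/inhibitory rates (Hz) and adaptation current (A)."""

    nu_e: float = 0.0
    nu_i: float = 0.0
    W: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.nu_e, self.nu_i, self.W], dtype=float)


def membrane_moments(nu_e_eff: float, nu_i: float, W: float,
                     p: NeuronalParams) -> tuple[float, float, float]:
    """Moments (mu_V, sigma_V, tau_V) of the membrane potential.

    ``nu_e_eff`` and ``nu_i`` are the presynaptic rates per synapse;
    ``W`` the adaptation current (A).  Uses the shot-noise (Campbell)
    expressions for conductance-based synapses.
    """
    fe = max(nu_e_eff, _RATE_FLOOR) * p.K_e
    fi = max(nu_i, _RATE_FLOOR) * p.K_i

    mu_Ge = fe * p.tau_e * p.Q_e
    mu_Gi = fi * p.tau_i * p.Q_i
    mu_G = p.g_L + mu_Ge + mu_Gi
    tau_m = p.C_m / mu_G
    mu_V = (mu_Ge * p.E_e + mu_Gi * p.E_i + p.g_L * p.E_L - W) / mu_G

    U_e = p.Q_e / mu_G * (p.E_e - mu_V)
    U_i = p.Q_i / mu_G * (p.E_i - mu_V)
    ue2 = fe * (U_e * p.tau_e) ** 2
    ui2 = fi * (U_i * p.tau_i) ** 2
    var = ue2 / (2.0 * (p.tau_e + tau_m)) + ui2 / (2.0 * (p.tau_i + tau_m))
    sigma_V = math.sqrt(max(var, 1e-30))
    tau_V = ((ue2 + ui2) /
             (ue2 / (p.tau_e + tau_m) + ui2 / (p.tau_i + tau_m)))
    return mu_V, sigma_V, tau_V


def _effective_threshold(mu_V: float, sigma_V: float, tau_VN: float,
                         P: tuple) -> float:
    V = (mu_V - _MUV0) / _DMUV0
    S = (sigma_V - _SV0) / _DSV0
    T = (tau_VN - _TVN0) / _DTVN0
    return (P[0] + P[1] * V + P[2] * S + P[3] * T
            + P[4] * V * V + P[5] * S * S + P[6] * T * T
            + P[7] * V * S + P[8] * V * T + P[9] * S * T)


def transfer_function(nu_e_eff: float, nu_i: float, W: float,
                      params: NeuronalParams,
                      population: str = "e") -> float:
    """Population firing rate (Hz) for given presynaptic input.

    Parameters
    ----------
    nu_e_eff, nu_i
        Excitatory (recurrent + external) and inhibitory presynaptic
        rates per synapse, Hz.
    W
        Mean adaptation current (A); shifts mu_V downward.
    population
        ``"e"`` (regular-spiking) or ``"i"`` (fast-spiking); selects the
        fitted threshold polynomial.
    """
    if not (math.isfinite(nu_e_eff) and math.isfinite(nu_i)
            and math.isfinite(W)):
        raise ValueError("transfer_function requires finite inputs")
    if nu_e_eff < 0 or nu_i < 0:
        raise ValueError("presynaptic rates must be >= 0")
    if params.transfer_table is not None:
        return max(float(params.transfer_table(nu_e_eff, nu_i, W)), 0.0)

    mu_V, sigma_V, tau_V = membrane_moments(nu_e_eff, nu_i, W, params)
    tau_VN = tau_V * p_ratio(params)
    P = params.P_e if population == "e" else params.P_i
    v_thre = _effective_threshold(mu_V, sigma_V, tau_VN, P)
    arg = (v_thre - mu_V) / (_SQRT2 * sigma_V)
    rate = 0.5 / tau_V * math.erfc(arg)
    return rate if rate > 0.0 else 0.0


def p_ratio(params: NeuronalParams) -> float:
    """g_L / C_m, the inverse membrane time used to normalise tau_V."""
    return params.g_L / params.C_m


def mean_mu_v(state: NeuronalState, nu_ext: float,
              params: NeuronalParams) -> float:
    """Mean membrane potential of the excitatory population (V)."""
    mu_V, _, _ = membrane_moments(state.nu_e + nu_ext, state.nu_i,
                                  state.W, params)
    return mu_V


def mean_field_derivatives(state: NeuronalState, nu_ext: float,
                           params: NeuronalParams) -> NeuronalState:
    """Time derivatives of (nu_e, nu_i, W).

    Implements ``T dnu/dt = F - nu`` for both populations with the
    effective excitatory drive ``nu_e + nu_ext``, and the adaptation
    equation ``dW/dt = -W/tau_w + b nu_e + a (mu_V - E_L)`` (the mu_V
    term only enters when a != 0).
    """
    nu_eff = state.nu_e + nu_ext
    F_e = transfer_function(nu_eff, state.nu_i, state.W, params, "e")
    F_i = transfer_function(nu_eff, state.nu_i, 0.0, params, "i")
    d_nu_e = (F_e - state.nu_e) / params.T
    d_nu_i = (F_i - state.nu_i) / params.T
    d_W = -state.W / params.tau_w + params.b * state.nu_e
    if params.a != 0.0:
        d_W += params.a * (mean_mu_v(state, nu_ext, params) - params.E_L)
    return NeuronalState(d_nu_e, d_nu_i, d_W)


def _relax(state: NeuronalState, nu_ext: float, params: NeuronalParams,
           t_sim: float, dt: float) -> NeuronalState:
    """Forward RK4 integration of the 3-dim neuronal system."""
    nu_e, nu_i, W = state.nu_e, state.nu_i, state.W
    n = int(round(t_sim / dt))
    for _ in range(n):
        s0 = NeuronalState(nu_e, nu_i, W)
        k1 = mean_field_derivatives(s0, nu_ext, params)
        s1 = NeuronalState(nu_e + 0.5 * dt * k1.nu_e,
                           nu_i + 0.5 * dt * k1.nu_i, W + 0.5 * dt * k1.W)
        k2 = mean_field_derivatives(s1, nu_ext, params)
        s2 = NeuronalState(nu_e + 0.5 * dt * k2.nu_e,
                           nu_i + 0.5 * dt * k2.nu_i, W + 0.5 * dt * k2.W)
        k3 = mean_field_derivatives(s2, nu_ext, params)
        s3 = NeuronalState(nu_e + dt * k3.nu_e, nu_i + dt * k3.nu_i,
                           W + dt * k3.W)
        k4 = mean_field_derivatives(s3, nu_ext, params)
        nu_e += dt / 6.0 * (k1.nu_e + 2 * k2.nu_e + 2 * k3.nu_e + k4.nu_e)
        nu_i += dt / 6.0 * (k1.nu_i + 2 * k2.nu_i + 2 * k3.nu_i + k4.nu_i)
        W += dt / 6.0 * (k1.W + 2 * k2.W + 2 * k3.W + k4.W)
        nu_e = max(nu_e, 0.0)
        nu_i = max(nu_i, 0.0)
    return NeuronalState(nu_e, nu_i, W)


def _residual(state: NeuronalState, nu_ext: float,
              params: NeuronalParams) -> float:
    """Max normalised derivative magnitude at ``state``."""
    d = mean_field_derivatives(state, nu_ext, params)
    return max(abs(d.nu_e) * params.T, abs(d.nu_i) * params.T,
               abs(d.W) * params.tau_w / max(abs(params.b) * 1.0, 1e-12)
               if params.b != 0 else abs(d.W) * params.tau_w)


def steady_state(nu_ext: float, params: NeuronalParams,
                 tol: float = 1e-8, max_time: float = 400.0,
                 dt: float = 5e-4) -> NeuronalState:
    """Fixed point of the mean-field equations at constant drive.

    Found by relaxation integration (chunks of ~10 adaptation times)
    followed by a Newton polish; the returned state has normalised
    residual below ``tol``.
    """
    if nu_ext < 0:
        raise ValueError("nu_ext must be >= 0")
    state = NeuronalState(0.0, 0.0, 0.0)
    if nu_ext == 0.0 and _residual(state, nu_ext, params) < tol:
        return state
    elapsed = 0.0
    chunk = max(10.0 * params.tau_w, 2.0)
    while elapsed < max_time:
        state = _relax(state, nu_ext, params, chunk, dt)
        elapsed += chunk
        polished = _newton_polish(state, nu_ext, params)
        if polished is not None and _residual(polished, nu_ext, params) < tol:
            return polished
        if _residual(state, nu_ext, params) < tol:
            return state
    res = _residual(state, nu_ext, params)
    raise ConvergenceError(
        f"steady_state did not converge (residual {res:.3e} after "
        f"{elapsed:.0f} s simulated)")


def _newton_polish(state: NeuronalState, nu_ext: float,
                   params: NeuronalParams):
    from scipy.optimize import fsolve

    def fun(x):
        s = NeuronalState(max(x[0], 0.0), max(x[1], 0.0), x[2])
        d = mean_field_derivatives(s, nu_ext, params)
        return [d.nu_e, d.nu_i, d.W]

    sol, info, ier, _ = fsolve(fun, state.as_array(), full_output=True)
    if ier != 1 or sol[0] < -1e-9 or sol[1] < -1e-9:
        return None
    return NeuronalState(max(sol[0], 0.0), max(sol[1], 0.0), sol[2])


def glutamate(nu_e: float, nu_ext: float, params: NeuronalParams) -> float:
    """Mean perisynaptic glutamate concentration (uM).

    Exactly linear in both rates: ``(g_r nu_e + g_ext nu_ext) * p N_e
    Q_e tau_e``.
    """
    if nu_e < 0 or nu_ext < 0:
        raise ValueError("rates must be >= 0")
    return (params.g_r * nu_e + params.g_ext * nu_ext) * params.syn_drive
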