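"""Single AdEx neuron Monte-Carlo and transfer-function calibration.

The semi-analytic transfer function of :mod:`nvcsim.mean_field` uses a
phenomenological effective threshold, a second-order polynomial in the
normalised membrane-potential moments.  This module provides

* a vectorised Monte-Carlo simulator of a single adaptive exponential
  integrate-and-fire neuron bombarded by Poisson conductance inputs,
  used both as the calibration target and as an independent test
  oracle for the semi-analytic formula; and
* the fitting harness that recovers the threshold polynomial from a
  grid of simulated firing rates (measured rate -> effective threshold
  by inverting the Gaussian rate formula, then linear least squares on
  the polynomial basis).

The default coefficients shipped in :mod:`nvcsim.params` were produced
by :func:`fit_threshold_polynomial` on a grid spanning the operating
range of the simulator (output rates ~0.1-30 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfcinv

from .params import NeuronalParams
from . import mean_field

__all__ = ["AdExNeuron", "simulate_rates", "effective_thresholds",
           "fit_threshold_polynomial", "default_grid"]


@dataclass
class AdExNeuron:
    """Single-cell AdEx parameters (SI units).

    Defaults describe the regular-spiking excitatory cell; use
    ``Delta_T=0.5e-3`` for the fast-spiking inhibitory cell.
    """

    C_m: float = 200e-12
    g_L: float = 10e-9
    E_L: float = -65e-3
    E_e: float = 0.0
    E_i: float = -80e-3
    V_T: float = -50e-3
    Delta_T: float = 2e-3
    V_reset: float = -65e-3
    V_spike: float = -30e-3
    t_ref: float = 5e-3
    Q_e: float = 1.5e-9
    Q_i: float = 5e-9
    tau_e: float = 5e-3
    tau_i: float = 5e-3

    @classmethod
    def from_population(cls, p: NeuronalParams,
                        population: str = "e") -> "AdExNeuron":
        delta = 2e-3 if population == "e" else 0.5e-3
        return cls(C_m=p.C_m, g_L=p.g_L, E_L=p.E_L, E_e=p.E_e, E_i=p.E_i,
                   Delta_T=delta, V_reset=p.E_L,
                   Q_e=p.Q_e, Q_i=p.Q_i, tau_e=p.tau_e, tau_i=p.tau_i)


def simulate_rates(nu_e, nu_i, W, neuron: AdExNeuron,
                   K_e: float = 400.0, K_i: float = 100.0,
                   t_sim: float = 40.0, dt: float = 5e-5,
                   seed: int = 0, return_se: bool = False):
    """Monte-Carlo output rates (Hz) for arrays of input points.

    Each entry of ``nu_e``/``nu_i``/``W`` defines one neuron receiving
    independent Poisson trains through ``K_e`` excitatory and ``K_i``
    inhibitory synapses; ``W`` is applied as a constant adaptation
    (hyperpolarising) current.  All points are advanced in lock-step
    with forward Euler.  Returns rates (and block-wise standard errors
    when ``return_se``).
    """
    nu_e = np.atleast_1d(np.asarray(nu_e, dtype=float))
    nu_i = np.atleast_1d(np.asarray(nu_i, dtype=float))
    W = np.atleast_1d(np.asarray(W, dtype=float))
    m = len(nu_e)
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_sim / dt))
    n_blocks = 8
    block_len = n_steps // n_blocks

    p = neuron
    de = math.exp(-dt / p.tau_e)
    di = math.exp(-dt / p.tau_i)
    V = np.full(m, p.E_L)
    ge = np.zeros(m)
    gi = np.zeros(m)
    ref = np.zeros(m)
    counts = np.zeros((n_blocks, m))

    lam_e = K_e * nu_e * dt
    lam_i = K_i * nu_i * dt
    chunk = 20000
    step = 0
    while step < n_steps:
        this = min(chunk, n_steps - step)
        arr_e = rng.poisson(lam_e, size=(this, m))
        arr_i = rng.poisson(lam_i, size=(this, m))
        for k in range(this):
            ge = ge * de + arr_e[k] * p.Q_e
            gi = gi * di + arr_i[k] * p.Q_i
            active = ref <= 0
            Vc = np.minimum(V, p.V_spike)
            dV = (-p.g_L * (V - p.E_L)
                  + p.g_L * p.Delta_T * np.exp((Vc - p.V_T) / p.Delta_T)
                  - ge * (V - p.E_e) - gi * (V - p.E_i) - W) / p.C_m
            V = np.where(active, V + dt * dV, p.V_reset)
            ref = np.where(active, ref, ref - dt)
            fired = active & (V > p.V_spike)
            if fired.any():
                counts[min((step + k) // block_len, n_blocks - 1)] += fired
                V = np.where(fired, p.V_reset, V)
                ref = np.where(fired, p.t_ref, ref)
        step += this

    rates = counts.sum(axis=0) / t_sim
    if return_se:
        block_rates = counts / (t_sim / n_blocks)
        se = block_rates.std(axis=0, ddof=1) / math.sqrt(n_blocks)
        return rates, se
    return rates


def effective_thresholds(points: np.ndarray, rates: np.ndarray,
                         params: NeuronalParams) -> np.ndarray:
    """Invert the Gaussian rate formula: measured rate -> threshold (V).

    ``points`` is (n, 3) of (nu_e, nu_i, W); only rates > 0 are
    meaningful (the inversion diverges at zero rate).
    """
    out = np.empty(len(points))
    for j, ((fe, fi, w), r) in enumerate(zip(points, rates)):
        mu_V, s_V, tau_V = mean_field.membrane_moments(fe, fi, w, params)
        x = min(max(2.0 * r * tau_V, 1e-12), 2.0 - 1e-12)
        out[j] = mu_V + math.sqrt(2.0) * s_V * erfcinv(x)
    return out


def _basis(points: np.ndarray, params: NeuronalParams) -> np.ndarray:
    rows = []
    for fe, fi, w in points:
        mu_V, s_V, tau_V = mean_field.membrane_moments(fe, fi, w, params)
        V = (mu_V - mean_field._MUV0) / mean_field._DMUV0
        S = (s_V - mean_field._SV0) / mean_field._DSV0
        T = (tau_V * params.g_L / params.C_m
             - mean_field._TVN0) / mean_field._DTVN0
        rows.append([1.0, V, S, T, V * V, S * S, T * T,
                     V * S, V * T, S * T])
    return np.array(rows)


def fit_threshold_polynomial(points: np.ndarray, rates: np.ndarray,
                             params: NeuronalParams,
                             min_rate: float = 0.05) -> np.ndarray:
    """Least-squares fit of the 10 threshold-polynomial coefficients.

    Points with measured rate below ``min_rate`` (Hz) are excluded
    (their effective threshold is ill-defined).
    """
    points = np.asarray(points, dtype=float)
    keep = rates > min_rate
    if keep.sum() < 10:
        raise ValueError("need at least 10 supra-floor points to fit")
    A = _basis(points[keep], params)
    y = effective_thresholds(points[keep], rates[keep], params)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


def default_grid() -> np.ndarray:
    """Calibration grid (nu_e, nu_i, W) spanning the operating domain.

    Excitatory input 0.5-14 Hz per synapse, inhibitory input roughly
    balanced around the self-consistent ratio of the network (nu_i ~
    2-3x nu_e) with a spread, adaptation currents 0-250 pA.
    """
    pts = []
    for fe in (0.5, 1.0, 2.0, 3.0, 4.5, 6.0, 8.0, 10.0, 12.0, 14.0):
        for ratio in (1.0, 2.0, 3.0, 4.5):
            for w in (0.0, 60e-12, 120e-12, 250e-12):
                pts.append((fe, ratio * fe, w))
    return np.array(pts)
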