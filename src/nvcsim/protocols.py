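"""Stimulus protocols and the coupled forward integration.

A :class:`StimulusProtocol` is a piecewise description of the external
excitatory drive nu_ext(t) (Hz): single events, block trains,
sinusoids, or a custom sampled trace, optionally riding on a constant
baseline drive.  :func:`run` integrates the full feedforward chain

    mean-field AdEx  ->  glutamate  ->  astrocyte Ca2+/IP3  ->
    AA/PGE2  ->  receptor/cAMP  ->  arteriole volume/CBF  ->
    Balloon  ->  BOLD

as a coupled 12-dimensional ODE with a fixed-step classical
Runge-Kutta scheme, starting from the computed resting fixed point.
The integration is deterministic: identical inputs give identical
outputs bit for bit on one platform.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import mean_field as mf
from .astrocyte import AstrocyteState, astro_derivatives, resting_astrocyte
from .mean_field import NeuronalState, glutamate, steady_state, transfer_function
from .params import SimulationConfig
from .vascular import (arteriole_volume, balloon_derivatives,
                       bold_from_balloon, receptor_camp_derivatives,
                       resting_vascular)

__all__ = ["StimulusProtocol", "make_event", "make_block", "make_sinusoid",
           "make_custom", "run", "SimulationResult", "IntegrationError",
           "COLUMNS"]

log = logging.getLogger(__name__)

#: Output column order (units in the names; BOLD in percent change).
COLUMNS = ("time_s", "nu_e_Hz", "nu_i_Hz", "W_pA", "Glu_uM", "Ca_uM", "h",
           "IP3_uM", "AA_uM", "PG_uM", "R_PG", "cAMP_uM", "CBV_A",
           "CBF_in", "v", "q", "CBF_out", "BOLD_pct")


class IntegrationError(RuntimeError):
    """Raised when a state variable becomes non-finite."""


@dataclass
class StimulusProtocol:
    """External-drive time course nu_ext(t) >= 0 with metadata.

    ``baseline`` is a constant drive present at all times; stimuli add
    on top of it.  ``onset`` is the start of the (first) stimulus, the
    reference for all reported latencies.
    """

    kind: str
    t_total: float
    amplitude: float = 0.0
    onset: float = 0.0
    duration: float = 0.0
    n_stim: int = 1
    isi: float = 0.0
    period: float = 0.0
    center: float = 0.0
    baseline: float = 0.0
    custom: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def sample(self, t: np.ndarray) -> np.ndarray:
        """nu_ext at the given times (vectorised, Hz)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "sinusoid":
            out = self.center + self.amplitude * np.sin(
                2.0 * math.pi * t / self.period)
            return np.clip(out, 0.0, None)
        if self.kind == "custom":
            return np.clip(self.custom(t) + self.baseline, 0.0, None)
        out = np.full_like(t, self.baseline)
        block = self.duration + self.isi
        for k in range(self.n_stim):
            start = self.onset + k * block
            out = np.where((t >= start) & (t < start + self.duration),
                           self.baseline + self.amplitude, out)
        return out

    def value(self, t: float) -> float:
        """nu_ext at a single time (scalar fast path for the integrator)."""
        if self.kind == "sinusoid":
            x = self.center + self.amplitude * math.sin(
                2.0 * math.pi * t / self.period)
            return x if x > 0.0 else 0.0
        if self.kind == "custom":
            return max(float(self.custom(np.array([t]))[0]) + self.baseline,
                       0.0)
        if t >= self.onset and self.duration > 0:
            block = self.duration + self.isi
            rel = t - self.onset
            k = int(rel // block) if block > 0 else 0
            if k < self.n_stim and rel - k * block < self.duration:
                return self.baseline + self.amplitude
        return self.baseline


def make_event(amplitude: float, duration: float, onset: float = 5.0,
               t_total: float = 45.0, baseline: float = 0.0) -> StimulusProtocol:
    """Single rectangular stimulus of given amplitude (Hz) and duration."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if onset + duration > t_total:
        raise ValueError("event does not fit in t_total")
    return StimulusProtocol("event", t_total, amplitude=amplitude,
                            onset=onset, duration=duration,
                            baseline=baseline)


def make_block(amplitude: float, stim_dur: float, isi: float, n_stim: int,
               onset: float = 5.0, t_total: float = 80.0,
               baseline: float = 0.0) -> StimulusProtocol:
    """Train of ``n_stim`` rectangles separated by ``isi`` seconds."""
    if n_stim < 1:
        raise ValueError("n_stim must be >= 1")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    span = n_stim * stim_dur + (n_stim - 1) * isi
    if onset + span > t_total:
        raise ValueError("block does not fit in t_total")
    return StimulusProtocol("block", t_total, amplitude=amplitude,
                            onset=onset, duration=stim_dur, isi=isi,
                            n_stim=n_stim, baseline=baseline)


def make_sinusoid(center: float, amplitude: float, period: float,
                  t_total: float = 120.0) -> StimulusProtocol:
    """Sinusoidal drive center + amplitude sin(2 pi t / period), >= 0."""
    if center < 0:
        raise ValueError("center must be >= 0")
    if center < amplitude:
        raise ValueError("center must be >= amplitude for a "
                         "non-negative drive")
    if period <= 0:
        raise ValueError("period must be > 0")
    return StimulusProtocol("sinusoid", t_total, amplitude=amplitude,
                            period=period, center=center)


def make_custom(fn: Callable[[np.ndarray], np.ndarray], t_total: float,
                onset: float = 0.0, baseline: float = 0.0) -> StimulusProtocol:
    """Arbitrary sampled drive (added to ``baseline`` and clipped at 0)."""
    return StimulusProtocol("custom", t_total, onset=onset,
                            baseline=baseline, custom=fn)


@dataclass
class SimulationResult:
    """Aligned time series of every model variable on the output grid."""

    data: pd.DataFrame
    protocol: StimulusProtocol
    config: SimulationConfig
    rest: dict

    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def bold(self) -> np.ndarray:
        """BOLD signal in percent change from baseline."""
        return self.data["BOLD_pct"].to_numpy()

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.8g")


def resting_point(config: SimulationConfig, baseline: float = 0.0):
    """Resting fixed point of the full chain at constant drive.

    Returns ``(y0, resolved_vascular_params, rest_info)`` where ``y0``
    is the 12-vector initial state and the vascular block has cAMP_o
    filled in self-consistently (resting arteriole volume exactly 1).
    """
    np_, ap, vp = config.neuronal, config.astrocyte, config.vascular
    if baseline == 0.0:
        neuro = NeuronalState(0.0, 0.0, 0.0)
    else:
        neuro = steady_state(baseline, np_)
    glu0 = glutamate(neuro.nu_e, baseline, np_)
    astro = resting_astrocyte(ap, glu0)
    vstate, camp_o = resting_vascular(astro.PG, vp)
    if vp.cAMP_o is None:
        vp = dataclasses.replace(vp, cAMP_o=camp_o)
    y0 = np.array([neuro.nu_e, neuro.nu_i, neuro.W,
                   astro.Ca, astro.h, astro.IP3, astro.AA, astro.PG,
                   vstate.R_PG, vstate.cAMP, 1.0, 1.0])
    rest = {"nu_e": neuro.nu_e, "nu_i": neuro.nu_i, "W": neuro.W,
            "Glu": glu0, "Ca": astro.Ca, "h": astro.h, "IP3": astro.IP3,
            "AA": astro.AA, "PG": astro.PG, "R_PG": vstate.R_PG,
            "cAMP": vstate.cAMP, "cAMP_o": vp.cAMP_o, "baseline": baseline}
    return y0, vp, rest


def run(config: SimulationConfig, protocol: StimulusProtocol) -> SimulationResult:
    """Integrate the coupled model for the given protocol.

    The initial state is the computed resting fixed point at the
    protocol's baseline drive.  Negative rate transients are clipped
    at zero (and counted in the log); the gate h is kept in [0, 1].
    """
    np_, ap = config.neuronal, config.astrocyte
    dt = config.dt
    n_steps = int(round(protocol.t_total / dt))
    stride = config.output_stride
    ca_clamp = config.ca_clamp
    clamp_after = config.clamp_after

    y0, vp, rest = resting_point(config, protocol.baseline)
    clamp_floor = rest["nu_e"]
    g_r, g_ext, drive = np_.g_r, np_.g_ext, np_.syn_drive
    inv_alpha_A = 1.0 / vp.alpha_A

    def rhs(t: float, y, nu_ext: float):
        (nu_e, nu_i, W, Ca, h, IP3, AA, PG, R_PG, cAMP, v, q) = y
        # neuronal
        nu_eff = nu_e + nu_ext
        F_e = transfer_function(nu_eff, nu_i, W, np_, "e")
        F_i = transfer_function(nu_eff, nu_i, 0.0, np_, "i")
        d_nu_e = (F_e - nu_e) / np_.T
        d_nu_i = (F_i - nu_i) / np_.T
        d_W = -W / np_.tau_w + np_.b * nu_e
        if np_.a != 0.0:
            d_W += np_.a * (mf.membrane_moments(nu_eff, nu_i, W, np_)[0]
                            - np_.E_L)
        # glutamate (optionally clamped to remove the neuronal undershoot)
        nu_e_glu, nu_ext_glu = nu_e, nu_ext
        if clamp_after is not None and t >= clamp_after:
            nu_e_glu = max(nu_e, clamp_floor)
            nu_ext_glu = max(nu_ext, protocol.baseline)
        Glu = (g_r * nu_e_glu + g_ext * nu_ext_glu) * drive
        # astrocyte
        ca_aa = Ca if ca_clamp is None else min(Ca, ca_clamp)
        a_state = AstrocyteState(Ca, h, IP3, AA, PG)
        d_astro = astro_derivatives(a_state, Glu, ap, ca_for_aa=ca_aa)
        # vascular
        d_R, d_cAMP = receptor_camp_derivatives(R_PG, cAMP, PG, vp)
        CBF_in = arteriole_volume(cAMP, vp) ** inv_alpha_A
        d_v, d_q, _ = balloon_derivatives(v, q, CBF_in, vp)
        return (d_nu_e, d_nu_i, d_W, d_astro.Ca, d_astro.h, d_astro.IP3,
                d_astro.AA, d_astro.PG, d_R, d_cAMP, d_v, d_q)

    n_out = n_steps // stride + 1
    out = np.empty((n_out, len(COLUMNS)))
    y = tuple(y0)
    clipped = 0
    row = 0

    def record(i_step: int, y, nu_ext: float):
        nonlocal row
        t = i_step * dt
        (nu_e, nu_i, W, Ca, h, IP3, AA, PG, R_PG, cAMP, v, q) = y
        nu_e_glu = nu_e
        if clamp_after is not None and t >= clamp_after:
            nu_e_glu = max(nu_e, clamp_floor)
        Glu = (g_r * nu_e_glu + g_ext * nu_ext) * drive
        CBV_A = arteriole_volume(cAMP, vp)
        CBF_in = CBV_A ** inv_alpha_A
        _, _, CBF_out = balloon_derivatives(v, q, CBF_in, vp)
        BOLD = 100.0 * bold_from_balloon(v, q, vp)
        vals = (t, nu_e, nu_i, W * 1e12, Glu, Ca, h, IP3, AA, PG, R_PG,
                cAMP, CBV_A, CBF_in, v, q, CBF_out, BOLD)
        for val in vals:
            if not math.isfinite(val):
                name = COLUMNS[vals.index(val)]
                raise IntegrationError(
                    f"non-finite value in {name} at t={t:.3f} s")
        out[row] = vals
        row += 1

    record(0, y, protocol.value(0.0))
    half = 0.5 * dt
    for i in range(n_steps):
        t = i * dt
        nu0 = protocol.value(t)
        nu_half = protocol.value(t + half)
        nu1 = protocol.value(t + dt)
        k1 = rhs(t, y, nu0)
        y2 = tuple(a + half * b for a, b in zip(y, k1))
        k2 = rhs(t + half, y2, nu_half)
        y3 = tuple(a + half * b for a, b in zip(y, k2))
        k3 = rhs(t + half, y3, nu_half)
        y4 = tuple(a + dt * b for a, b in zip(y, k3))
        k4 = rhs(t + dt, y4, nu1)
        y = tuple(a + dt / 6.0 * (b + 2 * c + 2 * d + e)
                  for a, b, c, d, e in zip(y, k1, k2, k3, k4))
        # physical bounds: rates and concentrations >= 0, h in [0, 1]
        lst = list(y)
        if lst[0] < 0.0 or lst[1] < 0.0:
            clipped += 1
        lst[0] = max(lst[0], 0.0)
        lst[1] = max(lst[1], 0.0)
        lst[3] = max(lst[3], 1e-12)
        lst[4] = min(max(lst[4], 0.0), 1.0)
        lst[5] = max(lst[5], 0.0)
        lst[6] = max(lst[6], 0.0)
        lst[7] = max(lst[7], 0.0)
        lst[8] = min(max(lst[8], 0.0), 1.0)
        y = tuple(lst)
        if (i + 1) % stride == 0:
            record(i + 1, y, nu1)

    if clipped:
        log.info("clipped %d negative rate transients to zero", clipped)
    df = pd.DataFrame(out[:row], columns=list(COLUMNS))
    cfg = dataclasses.replace(config, vascular=vp)
    return SimulationResult(df, protocol, cfg, rest)
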