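"""Vascular response and BOLD generation.

PGE2 released by the astrocyte binds EP4 receptors on arteriolar smooth
muscle (activated fraction R_PG), raising cAMP, which dilates the
arteriole.  The normalised arteriole volume sets the inflow through a
power law, and the Buxton-Friston Balloon model converts the inflow
time course into venous volume ``v``, deoxyhemoglobin ``q`` and the
BOLD signal.

All vascular variables are normalised to a resting value of 1; the
resting state (R_PG*, cAMP_o, CBV_A = CBF = v = q = 1, BOLD = 0) is an
exact fixed point of the assembled equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import VascularParams

__all__ = ["VascularState", "receptor_camp_derivatives", "arteriole_volume",
           "cbf_from_cbv", "balloon_derivatives", "bold_from_balloon",
           "bold_linear", "resting_vascular"]


@dataclass
class VascularState:
    """Receptor fraction, cAMP (uM) and normalised Balloon variables."""

    R_PG: float = 0.0
    cAMP: float = 0.0
    v: float = 1.0
    q: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.R_PG, self.cAMP, self.v, self.q])


def receptor_camp_derivatives(R_PG: float, cAMP: float, PG: float,
                              p: VascularParams) -> tuple[float, float]:
    """Time derivatives of the receptor fraction and cAMP concentration.

    dR/dt = -R/tau_R + O_R PG (1 - R);  dcAMP/dt = -cAMP/tau_cAMP +
    O_cAMP R.  The saturating binding term keeps R_PG in [0, 1]; basal
    PG (from resting calcium) maintains the basal cAMP level.
    """
    dR = -R_PG / p.tau_R + p.O_R * PG * (1.0 - R_PG)
    dcAMP = -cAMP / p.tau_cAMP + p.O_cAMP * R_PG
    return dR, dcAMP


def arteriole_volume(cAMP: float, p: VascularParams) -> float:
    """Normalised arteriole volume as a function of cAMP (uM).

    CBV_A = 1 + D_A (cAMP - cAMP_o) / (K_VA^2 + (cAMP - cAMP_o)^2);
    equal to 1 at basal cAMP, bounded within 1 +- D_A / (2 K_VA), with
    a constriction branch below basal cAMP (basal-tone mechanism).
    """
    if p.cAMP_o is None:
        raise ValueError("cAMP_o unset; resolve the resting state first")
    x = cAMP - p.cAMP_o
    return 1.0 + p.D_A * x / (p.K_VA ** 2 + x * x)


def cbf_from_cbv(CBV_A: float, alpha_A: float) -> float:
    """Inflow from arteriole volume through the power law CBV^(1/alpha)."""
    if alpha_A <= 0:
        raise ValueError("alpha_A must be > 0")
    if CBV_A <= 0:
        raise ValueError("CBV_A must be > 0")
    return CBV_A ** (1.0 / alpha_A)


def balloon_derivatives(v: float, q: float, CBF_in: float,
                        p: VascularParams) -> tuple[float, float, float]:
    """Balloon model right-hand side: (dv/dt, dq/dt, CBF_out).

    Outflow follows the venous power law with an optional viscoelastic
    term (tau_v > 0 resists volume change, delaying venous recovery):

        dv/dt  = (CBF_in - v^(1/alpha_V)) / (tau_0 + tau_v)
        f_out  = v^(1/alpha_V) + tau_v dv/dt
        dq/dt  = (CBF_in E(CBF_in)/E_0 - f_out q/v) / tau_0

    with the flow-extraction coupling E(f) = 1 - (1 - E_0)^(1/f).
    """
    f_el = v ** (1.0 / p.alpha_V)
    dv = (CBF_in - f_el) / (p.tau_0 + p.tau_v)
    f_out = f_el + p.tau_v * dv
    E = 1.0 - (1.0 - p.E_0) ** (1.0 / CBF_in)
    dq = (CBF_in * E / p.E_0 - f_out * q / v) / p.tau_0
    return dv, dq, f_out


def bold_from_balloon(v: float, q: float, p: VascularParams) -> float:
    """Fractional BOLD signal from the Balloon variables.

    BOLD = V_0 [k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)]; zero at rest.
    Multiply by 100 for percent change.
    """
    return p.V_0 * (p.k1 * (1.0 - q) + p.k2 * (1.0 - q / v)
                    + p.k3 * (1.0 - v))


def bold_linear(CBF_in: float, p: VascularParams) -> float:
    """First-order BOLD approximation k1' (CBF_in - 1) (fraction).

    The gain V_0 k1 matches the full model's leading deoxyhemoglobin
    term for small flow perturbations.
    """
    return p.V_0 * p.k1 * (CBF_in - 1.0)


def resting_vascular(PG_rest: float, p: VascularParams) -> tuple[VascularState, float]:
    """Resting fixed point given basal PGE2; returns (state, cAMP_o).

    R* solves the binding balance at basal PG, cAMP* = tau_cAMP O_cAMP
    R*, and cAMP_o is set to cAMP* so the resting arteriole volume is
    exactly 1 (hence CBF = v = q = 1 and BOLD = 0).
    """
    R = p.O_R * PG_rest / (p.O_R * PG_rest + 1.0 / p.tau_R)
    cAMP = p.tau_cAMP * p.O_cAMP * R
    return VascularState(R, cAMP, 1.0, 1.0), cAMP
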