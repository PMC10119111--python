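"""Parameter registry for the neurovascular-coupling simulator.

All parameters are plain dataclasses with SI units for electrical and
temporal quantities (seconds, siemens, volts, amperes) and micromolar
(uM) for concentrations.  Every constant is overridable from a TOML or
JSON config file; :func:`load_config` / :func:`dump_config` round-trip
the full registry.

The defaults describe a cortical population of 10,000 adaptive
exponential integrate-and-fire (AdEx) neurons (80% excitatory), a single
representative astrocyte following the Li-Rinzel calcium model with
glutamate-regulated IP3 turnover, a prostaglandin-E2 / cAMP arteriole
dilation cascade, and a Buxton-Friston Balloon model for the BOLD
signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


# ---------------------------------------------------------------------------
# Neuronal (mean-field) parameters
# ---------------------------------------------------------------------------

#: Second-order polynomial coefficients (volts) of the phenomenological
#: effective threshold used by the semi-analytic AdEx transfer function,
#: for regular-spiking (excitatory) and fast-spiking (inhibitory) cells.
#: Order: 1, V, S, T, V^2, S^2, T^2, V*S, V*T, S*T where V, S, T are the
#: normalised deviations of (mu_V, sigma_V, tau_V).
#: Values produced by nvcsim.adex.fit_threshold_polynomial on the
#: default calibration grid (40 s Monte-Carlo per point, then a
#: nonlinear polish in rate space).
P_COEFFS_RS = (-0.048898, 0.000317, 0.009032, -0.005688, 0.001098,
               0.010321, 0.019890, 0.000906, -0.000692, 0.028881)
P_COEFFS_FS = (-0.051188, 0.002955, -0.007347, 0.000707, 0.000425,
               0.007304, -0.018705, -0.002062, 0.003829, -0.030225)


@dataclass
class NeuronalParams:
    """Mean-field AdEx population parameters.

    The excitatory population carries a spike-triggered adaptation
    current ``W`` (pA scale, stored in amperes) with time constant
    ``tau_w``; subthreshold adaptation ``a`` is zero by default, in
    which case the mean membrane potential term of the adaptation
    equation vanishes.
    """

    T: float = 5e-3          # population response time (s)
    tau_w: float = 1.0       # adaptation time constant (s)
    a: float = 0.0           # subthreshold adaptation (S)
    b: float = 60e-12        # spike-triggered adaptation increment (A)
    # Network composition
    N_tot: int = 10000
    frac_exc: float = 0.8    # fraction of excitatory neurons
    p_conn: float = 0.05     # connection probability
    # Single-cell passive properties (shared by RS/FS populations)
    C_m: float = 200e-12     # membrane capacitance (F)
    g_L: float = 10e-9       # leak conductance (S)
    E_L: float = -65e-3      # leak reversal (V)
    E_e: float = 0.0         # excitatory reversal (V)
    E_i: float = -80e-3      # inhibitory reversal (V)
    Q_e: float = 1.5e-9      # excitatory quantal conductance (S)
    Q_i: float = 5e-9        # inhibitory quantal conductance (S)
    tau_e: float = 5e-3      # excitatory conductance decay (s)
    tau_i: float = 5e-3      # inhibitory conductance decay (s)
    # Effective-threshold polynomial coefficients (V)
    P_e: tuple = P_COEFFS_RS
    P_i: tuple = P_COEFFS_FS
    # Glutamate proportionality constants (uM per (S*s*Hz) of synaptic
    # drive).  g_r is calibrated so the calcium-spiking threshold of the
    # default astrocyte falls at an external drive of ~2.4 Hz.
    g_r: float = 1.832e7
    g_ext: float = 0.0
    # Optional tabulated transfer function overriding the semi-analytic
    # form: callable (nu_e_eff, nu_i, W) -> Hz, not serialised.
    transfer_table: Optional[object] = None

    @property
    def N_e(self) -> int:
        return int(round(self.N_tot * self.frac_exc))

    @property
    def N_i(self) -> int:
        return self.N_tot - self.N_e

    @property
    def K_e(self) -> float:
        """Mean number of excitatory synapses per neuron."""
        return self.p_conn * self.N_e

    @property
    def K_i(self) -> float:
        return self.p_conn * self.N_i

    @property
    def syn_drive(self) -> float:
        """p * N_e * Q_e * tau_e, the conductance-rate conversion (S*s)."""
        return self.p_conn * self.N_e * self.Q_e * self.tau_e

    def __post_init__(self) -> None:
        for name in ("T", "tau_w", "tau_e", "tau_i", "C_m", "g_L"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0 < self.p_conn <= 1:
            raise ParameterError("p_conn must lie in (0, 1]")
        if abs(self.frac_exc - 0.8) > 1e-9:
            # 80/20 split is assumed by the fitted transfer function.
            if not 0 < self.frac_exc < 1:
                raise ParameterError("frac_exc must lie in (0, 1)")
        if self.g_r < 0 or self.g_ext < 0:
            raise ParameterError("glutamate gains must be >= 0")
        if len(self.P_e) != 10 or len(self.P_i) != 10:
            raise ParameterError("threshold polynomials need 10 coefficients")


# ---------------------------------------------------------------------------
# Astrocyte parameters
# ---------------------------------------------------------------------------

@dataclass
class AstrocyteParams:
    """Li-Rinzel calcium dynamics with glutamate-regulated IP3 turnover
    and the downstream arachidonic-acid / PGE2 cascade.

    Calcium constants follow the G-ChI formulation (concentrations in
    uM, rates in uM/s).  ``leak_sign`` selects the reservoir factor of
    the ER leak: +1 uses ``C_T - (1 + rho_A) Ca`` (consistent with the
    channel flux and a conserved ER store, the default), -1 uses
    ``C_T - (1 - rho_A) Ca``.  ``pump_hill`` is the Hill exponent of
    the SERCA pump (2 in the source model).
    """

    # ER store / Li-Rinzel
    C_T: float = 2.0         # total ER-referenced calcium (uM)
    rho_A: float = 0.18      # ER-to-cytoplasm volume ratio
    Gamma_C: float = 6.0     # max channel flux rate (1/s)
    Gamma_L: float = 0.11    # leak rate (1/s)
    O_P: float = 1.2         # max SERCA pump rate (uM/s)
    K_P: float = 0.1         # pump affinity (uM)
    pump_hill: int = 2
    leak_sign: int = 1
    d1: float = 0.13         # IP3 binding (uM)
    d2: float = 1.049        # Ca inactivation (uM)
    d3: float = 0.9434       # IP3 binding (inactivated) (uM)
    d5: float = 0.08234      # Ca activation (uM)
    O_2: float = 0.2         # IP3R Ca-binding rate (1/(uM*s)); 0.2e3 (mM*s)^-1
    # IP3 production: glutamate-activated PLC-beta
    O_beta: float = 5.0      # max PLC-beta rate (uM/s)
    K_R: float = 1.3         # mGluR glutamate affinity (uM)
    K_p_glu: float = 10.0    # Ca-dependent affinity shift (uM)
    K_pi: float = 0.6        # Ca affinity of the shift (uM)
    glu_exp: float = 0.7     # mGluR Hill exponent
    # IP3 production: Ca-dependent PLC-delta
    O_delta: float = 0.45    # max PLC-delta rate (uM/s)
    kappa_delta: float = 1.5 # IP3 inhibition of PLC-delta (uM)
    K_delta: float = 0.03    # Ca affinity of PLC-delta (uM)
    # IP3 degradation: IP3-3K (Hill in Ca) and 5-phosphatase (linear)
    O_3K: float = 1.0        # max 3-kinase rate (uM/s)
    K_D: float = 0.4         # Ca affinity of 3K (uM)
    K_3: float = 1.0         # IP3 affinity of 3K (uM)
    r_5P: float = 1.2        # 5-phosphatase rate (1/s)
    # Arachidonic acid / PGE2 cascade
    tau_AA: float = 0.45     # AA decay time (s)
    O_AA: float = 1.333      # max AA production rate (uM/s)
    K_AA: float = 0.5        # Michaelis constant for Ca (uM)
    tau_PG: float = 0.45     # PGE2 decay time (s)
    O_PG: float = 1.333      # max PGE2 production rate (uM/s)
    K_PG: float = 0.3        # Michaelis constant for AA (uM)

    def __post_init__(self) -> None:
        if not 0 < self.rho_A < 1:
            raise ParameterError("rho_A must lie in (0, 1)")
        for name in ("C_T", "Gamma_C", "Gamma_L", "O_P", "K_P", "d1", "d2",
                     "d3", "d5", "O_2", "tau_AA", "tau_PG", "O_AA", "O_PG",
                     "K_AA", "K_PG"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.leak_sign not in (1, -1):
            raise ParameterError("leak_sign must be +1 or -1")


# ---------------------------------------------------------------------------
# Vascular / Balloon parameters
# ---------------------------------------------------------------------------

@dataclass
class VascularParams:
    """PGE2 receptor binding, cAMP, arteriole dilation and Balloon model.

    ``cAMP_o`` is the basal cAMP concentration entering the arteriole
    dilation law; when ``None`` it is computed self-consistently from
    the resting fixed point of the upstream cascade so that the resting
    arteriole volume is exactly 1.
    """

    tau_R: float = 2.4       # receptor relaxation time (s)
    O_R: float = 0.833       # PGE2 binding rate (1/(uM*s))
    tau_cAMP: float = 0.45   # cAMP relaxation time (s)
    O_cAMP: float = 2.222    # max cAMP production rate (uM/s)
    cAMP_o: Optional[float] = None  # basal cAMP (uM); None -> self-consistent
    D_A: float = 0.60        # arteriole dilation gain (uM)
    K_VA: float = 0.6        # arteriole dilation scale (uM)
    alpha_A: float = 0.38    # arteriole volume-flow exponent
    # Balloon model (Buxton-Friston, optional viscoelastic outflow)
    alpha_V: float = 0.38    # venous volume-flow exponent (Grubb)
    tau_0: float = 2.0       # mean venous transit time (s)
    tau_v: float = 18.0      # viscoelastic time constant (s); 0 disables
    E_0: float = 0.4         # resting oxygen extraction fraction
    V_0: float = 0.018       # resting venous blood volume fraction
    k1: Optional[float] = None  # BOLD weights; None -> 7*E_0, 2, 2*E_0-0.2
    k2: Optional[float] = None
    k3: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tau_R", "tau_cAMP", "tau_0"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0 < self.alpha_A <= 1 or not 0 < self.alpha_V <= 1:
            raise ParameterError("alpha exponents must lie in (0, 1]")
        if not 0 < self.E_0 < 1:
            raise ParameterError("E_0 must lie in (0, 1)")
        if self.tau_v < 0:
            raise ParameterError("tau_v must be >= 0")
        if self.k1 is None:
            self.k1 = 7.0 * self.E_0
        if self.k2 is None:
            self.k2 = 2.0
        if self.k3 is None:
            self.k3 = 2.0 * self.E_0 - 0.2


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Integrator settings plus the three stage parameter blocks.

    The model is deterministic; ``seed`` only feeds the multi-start
    nonlinear fits of the analysis layer.
    """

    dt: float = 1e-3             # fixed RK4 step (s)
    output_stride: int = 10      # decimation of the stored grid
    seed: int = 0
    neuronal: NeuronalParams = field(default_factory=NeuronalParams)
    astrocyte: AstrocyteParams = field(default_factory=AstrocyteParams)
    vascular: VascularParams = field(default_factory=VascularParams)
    # Optional calcium clamp (uM) applied to the AA-production input only;
    # used by the amplitude-clamp decomposition experiment.
    ca_clamp: Optional[float] = None
    # Optional neuronal clamp: after time ``clamp_after`` (s), the rate
    # feeding glutamate release is floored at its baseline steady value
    # (removes the post-stimulus neuronal undershoot).
    clamp_after: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.output_stride < 1:
            raise ParameterError("output_stride must be >= 1")


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

_BLOCKS = {"neuronal": NeuronalParams, "astrocyte": AstrocyteParams,
           "vascular": VascularParams}


def config_to_dict(config: SimulationConfig) -> dict:
    """Serialise a config (and its parameter blocks) to plain types."""
    out: dict = {"dt": config.dt, "output_stride": config.output_stride,
                 "seed": config.seed, "ca_clamp": config.ca_clamp,
                 "clamp_after": config.clamp_after}
    for name, cls in _BLOCKS.items():
        block = dataclasses.asdict(getattr(config, name))
        block.pop("transfer_table", None)
        for key, val in list(block.items()):
            if isinstance(val, tuple):
                block[key] = list(val)
        out[name] = block
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a config from a nested dict, applying defaults elsewhere."""
    kwargs: dict = {}
    for key in ("dt", "output_stride", "seed", "ca_clamp", "clamp_after"):
        if key in data:
            kwargs[key] = data[key]
    for name, cls in _BLOCKS.items():
        block = dict(data.get(name, {}))
        for key, val in list(block.items()):
            if isinstance(val, list):
                block[key] = tuple(val)
        kwargs[name] = cls(**block)
    return SimulationConfig(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a TOML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib
        data = tomllib.loads(text)
    else:
        data = json.loads(text)
    return config_from_dict(data)


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the full parameter registry as JSON (round-trippable)."""
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2))
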