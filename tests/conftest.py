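"""Shared fixtures: default parameter sets and reference runs.

Expensive simulations are session-scoped so the whole suite reuses
them.
"""

from __future__ import annotations

import numpy as np
import pytest

from nvcsim.params import (AstrocyteParams, NeuronalParams, SimulationConfig,
                           VascularParams)
from nvcsim.protocols import make_event, run


@pytest.fixture(scope="session")
def neuronal_params() -> NeuronalParams:
    return NeuronalParams()


@pytest.fixture(scope="session")
def astrocyte_params() -> AstrocyteParams:
    return AstrocyteParams()


@pytest.fixture(scope="session")
def vascular_params() -> VascularParams:
    return VascularParams()


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def std_event(default_config):
    """Reference event run: 2 s stimulus at nu_ext = 4 Hz, onset 5 s."""
    prot = make_event(4.0, 2.0, onset=5.0, t_total=50.0)
    return run(default_config, prot)


def astro_euler(params: AstrocyteParams, glu_of_t, t_total: float,
                dt: float, y0: np.ndarray) -> np.ndarray:
    """Independent explicit-Euler oracle for the astrocyte subsystem.

    Returns the (n, 5) state trajectory (Ca, h, IP3, AA, PG).
    """
    from nvcsim.astrocyte import AstrocyteState, astro_derivatives

    n = int(round(t_total / dt))
    out = np.empty((n, 5))
    y = np.asarray(y0, float).copy()
    for k in range(n):
        d = astro_derivatives(AstrocyteState(*y), glu_of_t(k * dt), params)
        y = y + dt * d.as_array()
        y[1] = min(max(y[1], 0.0), 1.0)
        y[0] = max(y[0], 1e-12)
        out[k] = y
    return out
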