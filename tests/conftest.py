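import dataclasses

import numpy as np
import pytest

from curlipulse import (
    ExpressionParams,
    LineageTrace,
    SimulationConfig,
    simulate_mother_machine,
    simulate_pulse_traces,
)


def noiseless_config(**overrides) -> SimulationConfig:
    """Config with all measurement and partitioning noise switched off."""
    expr = overrides.pop("expression", ExpressionParams(noise_cv=0.0, beta_cv=0.0))
    div = overrides.pop("division", None)
    cfg = SimulationConfig(expression=expr, **overrides)
    if div is not None:
        cfg = dataclasses.replace(cfg, division=div)
    return cfg


@pytest.fixture(scope="session")
def default_traces():
    """One default regulated simulation, reused across read-only tests."""
    return simulate_mother_machine(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_pulses():
    """200 deterministically-timed noiseless pulses (beta=40, g=0.004, 300 min on)."""
    cfg = noiseless_config(seed=2)
    return simulate_pulse_traces(cfg, t_on=600.0, on_duration=300.0, n_traces=200)


def make_trace(fluorescence, times=None, lengths=None, divisions=None,
               trap_id="t0") -> LineageTrace:
    f = np.asarray(fluorescence, dtype=float)
    n = f.size
    if times is None:
        times = 10.0 * np.arange(n)
    if lengths is None:
        lengths = np.full(n, 2.0)
    if divisions is None:
        divisions = np.zeros(n, dtype=bool)
    return LineageTrace(trap_id=trap_id, times=np.asarray(times, float),
                        lengths=np.asarray(lengths, float), fluorescence=f,
                        division_flags=np.asarray(divisions, bool))
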