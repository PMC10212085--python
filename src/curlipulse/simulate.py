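"""Synthetic mother-machine lineages and flow-cytometry-like endpoint samples.

The generator reproduces the statistical structure the downstream analysis
assumes, not the physics of the device: one mother cell per trap, exponential
elongation with a growth-rate drop after the medium switch, sloppy size-control
divisions, telegraph (two-state) reporter switching with per-pulse production
rates, first-order dilution/degradation of a stable reporter, and
multiplicative measurement noise.

All randomness flows from a single root seed through named substreams
(``init``, ``division``, ``expression``, ``noise``, ``replicate``) so that
enabling or disabling one noise source does not perturb the draws of another.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .errors import ConfigurationError, InvalidTraceError

__all__ = [
    "LineageTrace",
    "PopulationSample",
    "simulate_mother_machine",
    "simulate_pulse_traces",
    "sample_flow_population",
]

_STREAMS = {"init": 0, "division": 1, "expression": 2, "noise": 3, "replicate": 4}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named, reproducible child RNG of a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[name], int(index)]))


@dataclass
class LineageTrace:
    """One mother cell's time series of length, fluorescence and divisions.

    ``division_flags[i]`` is True on the first frame after a division.
    ``on_state`` is the simulator's hidden ground-truth expression state
    (None for traces read from disk); it is never serialized.
    """

    trap_id: str
    times: np.ndarray          # min, strictly increasing, uniform spacing
    lengths: np.ndarray        # um per frame, > 0
    fluorescence: np.ndarray   # AU per frame, >= 0
    division_flags: np.ndarray  # bool per frame
    strain_label: str = ""
    on_state: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.division_flags = np.asarray(self.division_flags, dtype=bool)
        n = self.times.size
        if n == 0:
            raise InvalidTraceError(f"trace {self.trap_id}: empty")
        if not (self.lengths.size == self.fluorescence.size
                == self.division_flags.size == n):
            raise InvalidTraceError(f"trace {self.trap_id}: ragged arrays")
        if np.any(self.lengths <= 0):
            raise InvalidTraceError(f"trace {self.trap_id}: non-positive length")
        if np.any(self.fluorescence < 0):
            raise InvalidTraceError(f"trace {self.trap_id}: negative fluorescence")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidTraceError(f"trace {self.trap_id}: times not increasing")

    @property
    def frame_interval(self) -> float:
        if self.times.size < 2:
            return float("nan")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class PopulationSample:
    """Per-cell endpoint fluorescence for one biological replicate."""

    replicate_id: str
    strain_label: str
    fluorescence: np.ndarray  # AU per cell, > 0

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)

    @property
    def n_cells(self) -> int:
        return int(self.fluorescence.size)


def _mean_growth_rate(t0: np.ndarray, t1: np.ndarray,
                      cfg: SimulationConfig) -> np.ndarray:
    """Exact frame-average of g(t) = g_cond + (g_fresh-g_cond)e^{-(t-ts)/tau}."""
    g = cfg.growth
    ts, tau = cfg.t_switch, g.tau_relax
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    dt = t1 - t0
    pre = np.clip(np.minimum(t1, ts) - t0, 0.0, None)   # time spent before switch
    a = np.maximum(t0, ts) - ts
    b = np.maximum(t1, ts) - ts
    if tau > 0:
        relax = tau * (np.exp(-a / tau) - np.exp(-b / tau))
    else:
        relax = np.zeros_like(dt)
    integral = g.g_fresh * pre + g.g_cond * (dt - pre) + (g.g_fresh - g.g_cond) * relax
    return integral / dt


def _lognormal_params(median: float, cv: float) -> tuple[float, float]:
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return math.log(median) if median > 0 else -math.inf, sigma


def _apply_noise(x: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv <= 0:
        return x
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return x * np.exp(rng.normal(0.0, sigma, size=x.shape))


def simulate_mother_machine(config: SimulationConfig) -> list[LineageTrace]:
    """Simulate one mother-machine experiment; one trace per trap.

    Per frame: the expression state may toggle (off->on only after
    ``t_switch + lag``), fluorescence integrates
    ``dF/dt = beta*[on] - (g+delta)*F`` with the exact frame-averaged growth
    rate, the cell elongates exponentially and divides when it exceeds its
    sampled division length (daughter ratio ~ N(0.5, ratio_sd), clipped to
    [0.4, 0.6]). Measurement noise is applied last.
    """
    if not isinstance(config, SimulationConfig):
        raise ConfigurationError("config: expected a SimulationConfig")
    n = config.n_traps
    nf = config.n_frames
    dt = config.frame_interval
    times = dt * np.arange(nf)
    d, e = config.division, config.expression

    rng_init = substream(config.seed, "init")
    rng_div = substream(config.seed, "division")
    rng_expr = substream(config.seed, "expression")
    rng_noise = substream(config.seed, "noise")

    L = d.L_birth_mean * np.exp(rng_init.normal(0.0, max(d.cv_div, 0.0), n))
    div_target = _sample_div_length(rng_init, d, n)
    on = np.zeros(n, dtype=bool)
    beta = np.zeros(n)
    F = np.full(n, e.F0)

    lengths = np.empty((nf, n))
    fluor = np.empty((nf, n))
    flags = np.zeros((nf, n), dtype=bool)
    states = np.zeros((nf, n), dtype=bool)
    lengths[0], fluor[0] = L, F

    mu_b, sd_b = _lognormal_params(e.beta_median, e.beta_cv)
    p_on = 1.0 - math.exp(-e.k_on * dt)
    p_off = 1.0 - math.exp(-e.k_off * dt)

    for i in range(1, nf):
        t0, t1 = times[i - 1], times[i]
        # telegraph switching decided at the start of the interval
        u_on = rng_expr.random(n)
        u_off = rng_expr.random(n)
        turn_on = (~on) & (t0 >= config.t_switch + e.lag) & (u_on < p_on)
        turn_off = on & (u_off < p_off)
        if np.any(turn_on):
            draws = rng_expr.normal(mu_b, sd_b, n)  # fixed-size draw keeps streams aligned
            beta = np.where(turn_on, np.exp(draws) if e.beta_median > 0 else 0.0, beta)
        on = (on | turn_on) & ~turn_off
        states[i] = on

        gbar = float(_mean_growth_rate(t0, t1, config))
        k = gbar + e.delta
        if k > 0:
            decay = math.exp(-k * dt)
            F = F * decay + np.where(on, beta * (1.0 - decay) / k, 0.0)
        else:
            F = F + np.where(on, beta * dt, 0.0)
        F = np.maximum(F, e.F0)
        fluor[i] = F

        L = L * math.exp(gbar * dt)
        ratio = np.clip(rng_div.normal(0.5, d.ratio_sd, n), 0.4, 0.6)
        new_target = _sample_div_length(rng_div, d, n)
        divided = L >= div_target
        L = np.where(divided, ratio * L, L)
        div_target = np.where(divided, new_target, div_target)
        flags[i] = divided
        lengths[i] = L

    lengths = _apply_noise(lengths, e.noise_cv, rng_noise)
    fluor = _apply_noise(fluor, e.noise_cv, rng_noise)
    fluor = np.maximum(fluor, 0.0)

    width = len(str(n - 1))
    return [
        LineageTrace(
            trap_id=f"trap{j:0{width}d}",
            times=times.copy(),
            lengths=lengths[:, j],
            fluorescence=fluor[:, j],
            division_flags=flags[:, j],
            strain_label=config.preset,
            on_state=states[:, j],
        )
        for j in range(n)
    ]


def _sample_div_length(rng: np.random.Generator, d, n: int) -> np.ndarray:
    sd = d.cv_div * d.L_div_mean
    target = rng.normal(d.L_div_mean, sd, n)
    # keep the target above any plausible birth length
    return np.maximum(target, 1.2 * d.L_birth_mean)


def simulate_pulse_traces(config: SimulationConfig, t_on: float,
                          on_duration: float, n_traces: int) -> list[LineageTrace]:
    """Deterministically-timed activation pulses for estimator validation.

    Every lineage grows at the constant post-switch rate ``g_cond`` and is
    forced into the on state exactly during ``[t_on, t_on + on_duration)``;
    production rates still follow the configured per-pulse lognormal and
    measurement noise still applies. This isolates the fluorescence pulse
    shape from the stochastic switching times of the full simulator.
    """
    e = config.expression
    g = config.growth.g_cond
    dt = config.frame_interval
    nf = config.n_frames
    times = dt * np.arange(nf)
    d = config.division

    rng_init = substream(config.seed, "init")
    rng_div = substream(config.seed, "division")
    rng_expr = substream(config.seed, "expression")
    rng_noise = substream(config.seed, "noise")

    n = n_traces
    L = d.L_birth_mean * np.exp(rng_init.normal(0.0, max(d.cv_div, 0.0), n))
    div_target = _sample_div_length(rng_init, d, n)
    mu_b, sd_b = _lognormal_params(e.beta_median, e.beta_cv)
    beta = np.exp(rng_expr.normal(mu_b, sd_b, n)) if e.beta_median > 0 else np.zeros(n)
    F = np.full(n, e.F0)

    lengths = np.empty((nf, n))
    fluor = np.empty((nf, n))
    flags = np.zeros((nf, n), dtype=bool)
    states = np.zeros((nf, n), dtype=bool)
    lengths[0], fluor[0] = L, F

    k = g + e.delta
    for i in range(1, nf):
        on = (times[i - 1] >= t_on) and (times[i - 1] < t_on + on_duration)
        states[i] = on
        if k > 0:
            decay = math.exp(-k * dt)
            F = F * decay + (beta * (1.0 - decay) / k if on else 0.0)
        else:
            F = F + (beta * dt if on else 0.0)
        F = np.maximum(F, e.F0)
        fluor[i] = F

        L = L * math.exp(g * dt)
        ratio = np.clip(rng_div.normal(0.5, d.ratio_sd, n), 0.4, 0.6)
        new_target = _sample_div_length(rng_div, d, n)
        divided = L >= div_target
        L = np.where(divided, ratio * L, L)
        div_target = np.where(divided, new_target, div_target)
        flags[i] = divided
        lengths[i] = L

    lengths = _apply_noise(lengths, e.noise_cv, rng_noise)
    fluor = np.maximum(_apply_noise(fluor, e.noise_cv, rng_noise), 0.0)

    width = len(str(n - 1))
    return [
        LineageTrace(
            trap_id=f"pulse{j:0{width}d}",
            times=times.copy(),
            lengths=lengths[:, j],
            fluorescence=fluor[:, j],
            division_flags=flags[:, j],
            strain_label=config.preset,
            on_state=states[:, j],
        )
        for j in range(n)
    ]


def sample_flow_population(
    f_positive: float,
    mu_neg: float = 2.0,
    sigma_neg: float = 0.25,
    mu_pos: float = 4.0,
    sigma_pos: float = 0.25,
    n_cells: int = 50_000,
    n_replicates: int = 3,
    seed: int = 0,
    strain_label: str = "",
) -> list[PopulationSample]:
    """Endpoint flow-cytometry-like samples from a two-component log10 mixture.

    Each cell is curli-positive with probability ``f_positive``; its log10
    fluorescence is drawn from the corresponding normal component. Replicates
    use independent substreams of the root seed.
    """
    if not (0.0 <= f_positive <= 1.0):
        raise ConfigurationError("f_positive: must be in [0, 1]")
    if sigma_neg <= 0 or sigma_pos <= 0:
        raise ConfigurationError("sigma_neg/sigma_pos: must be > 0")
    if mu_pos <= mu_neg:
        raise ConfigurationError("mu_pos: modes not ordered (mu_pos <= mu_neg)")
    if n_cells < 1 or n_replicates < 1:
        raise ConfigurationError("n_cells/n_replicates: must be >= 1")

    samples = []
    for r in range(n_replicates):
        rng = substream(seed, "replicate", r)
        positive = rng.random(n_cells) < f_positive
        log10f = np.where(
            positive,
            rng.normal(mu_pos, sigma_pos, n_cells),
            rng.normal(mu_neg, sigma_neg, n_cells),
        )
        samples.append(PopulationSample(
            replicate_id=f"r{r + 1}",
            strain_label=strain_label,
            fluorescence=10.0 ** log10f,
        ))
    return samples
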