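"""Parameterization of the synthetic mother-machine and cytometry generators.

The simulation emulates the canonical medium-switch experiment: lineages of
mother cells grow in fresh medium for a few hours, are switched to conditioned
(spent) medium which sharply reduces growth, and thereafter stochastically
fire transient pulses of curli reporter expression in a subpopulation.

Units are minutes and 1/min throughout; lengths in micrometres; fluorescence
in arbitrary units (AU). The AU scale is a package convention: the negative
(curli-off) mode sits near 10^2 AU and the positive mode near 10^4 AU, so the
conventional 10^3 AU gate separates them.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

__all__ = [
    "GrowthParams",
    "DivisionParams",
    "ExpressionParams",
    "SimulationConfig",
    "PRESETS",
    "PRESET_NAMES",
    "load_config",
    "config_hash",
]


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{name}: {msg}")


@dataclass(frozen=True)
class GrowthParams:
    """Specific elongation rate before/after the medium switch.

    The rate relaxes exponentially from ``g_fresh`` to ``g_cond`` with time
    constant ``tau_relax`` after the switch:
    ``g(t) = g_cond + (g_fresh - g_cond) * exp(-max(0, t - t_switch)/tau_relax)``.
    """

    g_fresh: float = 0.02    # 1/min, ~35 min doubling in fresh rich medium
    g_cond: float = 0.004    # 1/min, strongly reduced growth in conditioned medium
    tau_relax: float = 30.0  # min, relaxation time of the rate after the switch


@dataclass(frozen=True)
class DivisionParams:
    """Division-size control: divide near a target length, split near 1:2."""

    L_birth_mean: float = 2.5  # um
    L_div_mean: float = 5.0    # um
    cv_div: float = 0.1        # CV of the sampled division length
    ratio_sd: float = 0.05     # s.d. of daughter/mother ratio around 0.5


@dataclass(frozen=True)
class ExpressionParams:
    """Two-state (telegraph) reporter kinetics with per-pulse production rates.

    A lineage can switch off->on only after ``t_switch + lag``; each activation
    pulse draws its own production rate ``beta`` from a lognormal with median
    ``beta_median`` and coefficient of variation ``beta_cv``. Fluorescence
    follows ``dF/dt = beta*[on] - (g + delta)*F`` (dilution by growth plus
    optional degradation), floored at the autofluorescence baseline ``F0``.
    Multiplicative lognormal measurement noise with CV ``noise_cv`` is applied
    last, to both length and fluorescence readouts.
    """

    k_on: float = 4e-4         # 1/min, off->on switching rate after the lag
    lag: float = 120.0         # min after the switch before activation is possible
    k_off: float = 1.0 / 300.0  # 1/min, on->off rate (pulses last ~5 h)
    beta_median: float = 40.0  # AU/min production rate in the on state
    beta_cv: float = 0.25      # lognormal cell-to-cell CV of beta
    delta: float = 0.0         # 1/min reporter degradation (stable GFP ~ 0)
    F0: float = 100.0          # AU baseline (autofluorescence)
    noise_cv: float = 0.03     # multiplicative measurement noise CV


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic mother-machine experiment."""

    frame_interval: float = 10.0  # min per frame
    t_total: float = 1800.0       # min (4 h fresh + up to 26 h total)
    t_switch: float = 240.0       # min, fresh -> conditioned medium
    n_traps: int = 300
    growth: GrowthParams = field(default_factory=GrowthParams)
    division: DivisionParams = field(default_factory=DivisionParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    preset: str = "regulated"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.frame_interval > 0, "frame_interval", "must be > 0")
        _require(self.t_total > 0, "t_total", "must be > 0")
        _require(0 <= self.t_switch < self.t_total, "t_switch",
                 "must satisfy 0 <= t_switch < t_total")
        _require(self.n_traps >= 1, "n_traps", "must be >= 1")
        g, d, e = self.growth, self.division, self.expression
        for name, val in [
            ("growth.g_fresh", g.g_fresh), ("growth.g_cond", g.g_cond),
            ("growth.tau_relax", g.tau_relax),
            ("division.L_birth_mean", d.L_birth_mean),
            ("division.L_div_mean", d.L_div_mean),
            ("division.cv_div", d.cv_div), ("division.ratio_sd", d.ratio_sd),
            ("expression.k_on", e.k_on), ("expression.lag", e.lag),
            ("expression.k_off", e.k_off),
            ("expression.beta_median", e.beta_median),
            ("expression.beta_cv", e.beta_cv), ("expression.delta", e.delta),
            ("expression.F0", e.F0), ("expression.noise_cv", e.noise_cv),
        ]:
            _require(math.isfinite(val) and val >= 0, name,
                     "must be finite and >= 0")
        _require(d.L_birth_mean > 0 and d.L_div_mean > d.L_birth_mean,
                 "division.L_div_mean", "must exceed L_birth_mean > 0")
        _require(e.F0 > 0, "expression.F0", "must be > 0")
        _require(self.preset in PRESET_NAMES, "preset",
                 f"must be one of {sorted(PRESET_NAMES)}")

    @property
    def n_frames(self) -> int:
        return int(round(self.t_total / self.frame_interval)) + 1

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        data = dict(data)
        preset = data.get("preset", "regulated")
        if preset not in PRESETS:
            raise ConfigurationError(f"preset: must be one of {sorted(PRESETS)}")
        base = PRESETS[preset]
        kwargs: dict[str, Any] = {"preset": preset}
        for fld, klass in [("growth", GrowthParams), ("division", DivisionParams),
                           ("expression", ExpressionParams)]:
            merged = dataclasses.asdict(getattr(base, fld))
            merged.update(data.pop(fld, {}) or {})
            try:
                kwargs[fld] = klass(**merged)
            except TypeError as exc:
                raise ConfigurationError(f"{fld}: {exc}") from None
        for fld in ("frame_interval", "t_total", "t_switch", "n_traps", "seed"):
            if fld in data:
                kwargs[fld] = data.pop(fld)
        data.pop("preset", None)
        if data:
            raise ConfigurationError(f"unknown config fields: {sorted(data)}")
        return cls(**kwargs)

    def with_preset(self, preset: str) -> "SimulationConfig":
        """Return a copy with the given preset's expression bundle applied."""
        if preset not in PRESETS:
            raise ConfigurationError(f"preset: must be one of {sorted(PRESETS)}")
        return dataclasses.replace(
            self, preset=preset, expression=PRESETS[preset].expression)


PRESET_NAMES = ("regulated", "deregulated")

# "deregulated" encodes the qualitative contrast of the strain lacking the
# c-di-GMP regulatory network: faster and more heterogeneous induction,
# modeled as 2x production-rate median with 2x its cell-to-cell CV.
PRESETS: dict[str, SimulationConfig] = {
    "regulated": SimulationConfig(preset="regulated"),
    "deregulated": SimulationConfig(
        preset="deregulated",
        expression=ExpressionParams(beta_median=80.0, beta_cv=0.5)),
}


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML or JSON config file mirroring :class:`SimulationConfig`."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    return SimulationConfig.from_dict(data)


def config_hash(config: SimulationConfig) -> str:
    """Stable digest of the fully-resolved configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
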