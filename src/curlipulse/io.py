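"""Tidy CSV interchange for traces, populations, and derived tables.

Trace CSV dialect: one row per (trap_id, frame) with columns
``trap_id, time_min, length_um, fluor_au, division, strain``; UTF-8, header
row, '.' decimal separator. Files lacking the ``division`` column are
accepted — divisions are then recovered from length drops. Population CSV:
``replicate_id, strain, fluor_au``.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError, SchemaError
from .features import AlignedProfile, GrowthRateSeries, TraceFeatures, detect_divisions
from .population import FractionPositiveSummary, MixtureFit
from .simulate import LineageTrace, PopulationSample

__all__ = [
    "read_traces", "write_traces",
    "read_population", "write_population",
    "write_features", "write_aligned_profile", "write_growth_rates",
    "write_population_summary",
    "RunManifest", "write_manifest",
]

TRACE_COLUMNS = ["trap_id", "time_min", "length_um", "fluor_au", "division", "strain"]
_REQUIRED_TRACE = ["trap_id", "time_min", "length_um", "fluor_au"]


def write_traces(traces: list[LineageTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame({
            "trap_id": tr.trap_id,
            "time_min": tr.times,
            "length_um": tr.lengths,
            "fluor_au": tr.fluorescence,
            "division": tr.division_flags.astype(int),
            "strain": tr.strain_label,
        })
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[LineageTrace]:
    """Load lineage traces, grouped by trap and sorted by time.

    Validates uniform frame spacing per trace (within 1% of the modal step)
    and recovers division flags from length drops when the column is absent.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _REQUIRED_TRACE:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    has_div = "division" in df.columns
    has_strain = "strain" in df.columns
    traces = []
    for trap_id, grp in df.groupby("trap_id", sort=True):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=float)
        if times.size > 1:
            steps = np.diff(times)
            dt = float(np.median(steps))
            if dt <= 0 or np.any(np.abs(steps - dt) > 0.01 * dt):
                raise FormatError(
                    f"trace {trap_id}: non-uniform frame spacing beyond 1%")
        lengths = grp["length_um"].to_numpy(dtype=float)
        flags = (grp["division"].to_numpy().astype(bool) if has_div
                 else detect_divisions(lengths))
        traces.append(LineageTrace(
            trap_id=str(trap_id),
            times=times,
            lengths=lengths,
            fluorescence=grp["fluor_au"].to_numpy(dtype=float),
            division_flags=flags,
            strain_label=str(grp["strain"].iloc[0]) if has_strain else "",
        ))
    return traces


def write_population(samples: list[PopulationSample], path: str | Path) -> None:
    frames = [
        pd.DataFrame({
            "replicate_id": s.replicate_id,
            "strain": s.strain_label,
            "fluor_au": s.fluorescence,
        })
        for s in samples
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_population(path: str | Path) -> list[PopulationSample]:
    """Load per-cell endpoint samples; non-positive readings are dropped."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("replicate_id", "fluor_au"):
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    has_strain = "strain" in df.columns
    samples = []
    for rep, grp in df.groupby("replicate_id", sort=True):
        vals = grp["fluor_au"].to_numpy(dtype=float)
        n_dropped = int(np.sum(vals <= 0))
        if n_dropped:
            vals = vals[vals > 0]
        samples.append(PopulationSample(
            replicate_id=str(rep),
            strain_label=str(grp["strain"].iloc[0]) if has_strain else "",
            fluorescence=vals,
        ))
    return samples


def write_features(features: list[TraceFeatures], path: str | Path) -> None:
    pd.DataFrame([
        {
            "trap_id": f.trap_id,
            "crossing_time_min": f.crossing_time,
            "max_rate_au_per_min": f.max_rate,
            "peak_time_min": f.peak_time,
            "peak_amplitude_au": f.peak_amplitude,
            "decay_half_time_min": f.decay_half_time,
            "censor_reasons": ";".join(sorted(f.censor_reasons)),
        }
        for f in features
    ]).to_csv(path, index=False)


def write_aligned_profile(profile: AlignedProfile, path: str | Path) -> None:
    pd.DataFrame({
        "rel_time_min": profile.rel_times,
        "median": profile.median,
        "q25": profile.q25,
        "q75": profile.q75,
        "n": profile.n_per_bin,
    }).to_csv(path, index=False)


def write_growth_rates(series: GrowthRateSeries, path: str | Path) -> None:
    pd.DataFrame({
        "time_min": series.times,
        "median_rate_per_min": series.median_rate,
        "q25": series.q25,
        "q75": series.q75,
        "n_cells": series.n_cells,
    }).to_csv(path, index=False)


def write_population_summary(
    rows: list[tuple[str, FractionPositiveSummary, MixtureFit | None]],
    path: str | Path,
) -> None:
    """One row per strain: gate summary plus mixture parameters."""
    records = []
    for strain, summary, fit in rows:
        rec: dict = {
            "strain": strain,
            "gate_au": summary.gate,
            "mean_fraction": summary.mean_fraction,
            "sem": summary.sem,
            "n_replicates": summary.n_replicates,
        }
        for i, f in enumerate(summary.per_replicate_fractions, start=1):
            rec[f"fraction_r{i}"] = f
        if fit is not None:
            rec.update({
                "mix_weight_low": fit.weights[0], "mix_weight_high": fit.weights[1],
                "mix_mean_low_log10": fit.means[0], "mix_mean_high_log10": fit.means[1],
                "mix_sd_low_log10": fit.sds[0], "mix_sd_high_log10": fit.sds[1],
                "bimodal": fit.bimodal, "converged": fit.converged,
            })
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


@dataclass
class RunManifest:
    """Provenance of one pipeline run; re-running an identical manifest
    reproduces byte-identical CSV outputs."""

    config_hash: str
    seed: int
    tool_version: str
    created_utc: str
    outputs: dict[str, str]

    @classmethod
    def create(cls, config_hash: str, seed: int,
               outputs: dict[str, str]) -> "RunManifest":
        return cls(
            config_hash=config_hash,
            seed=seed,
            tool_version=__version__,
            created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            outputs=outputs,
        )


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True) + "\n")
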