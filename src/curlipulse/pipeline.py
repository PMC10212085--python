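"""End-to-end pipeline: simulate -> trace features -> population -> report.

One run simulates the configured presets (by default the regulated wild-type
bundle and the deregulated bundle emulating loss of the c-di-GMP network),
extracts all per-lineage induction statistics, summarizes endpoint
population samples, and writes a statistical report comparing the feature
distributions between the two strains with Welch's t-test. All outputs are
tidy CSVs plus PNG figures and a JSON manifest.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from .config import SimulationConfig, config_hash
from .features import (
    DEFAULT_THRESHOLD,
    align_traces,
    extract_features,
    fraction_positive_over_time,
    growth_rate_series,
)
from .io import (
    RunManifest,
    write_aligned_profile,
    write_features,
    write_growth_rates,
    write_manifest,
    write_population,
    write_population_summary,
    write_traces,
)
from .population import auto_gate, fit_two_component_mixture, gate_fraction_positive
from .simulate import sample_flow_population, simulate_mother_machine
from .stats import welch_t_test
from . import plotting

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("curlipulse")

# Endpoint positive fractions emulating overnight flask cultures: near half
# the population for the regulated strain, lower without the network.
_DEFAULT_POPULATION = {
    "regulated": 0.46,
    "deregulated": 0.30,
}


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig)
    presets: tuple[str, ...] = ("regulated", "deregulated")
    threshold: float = DEFAULT_THRESHOLD
    gate: float = DEFAULT_THRESHOLD
    use_auto_gate: bool = False
    population_fractions: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_POPULATION))
    n_cells: int = 50_000
    n_replicates: int = 3


def run_pipeline(config: PipelineConfig, output_dir: str | Path,
                 seed: int = 1, make_plots: bool = True) -> RunManifest:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    features_by_strain: dict[str, list] = {}
    growth_by_strain = {}
    profiles = {}
    kde_snapshots: dict[str, dict[float, np.ndarray]] = {}
    pop_rows = []

    for preset in config.presets:
        sim = dataclasses.replace(
            config.simulation.with_preset(preset), seed=seed)
        logger.info("simulate: preset=%s traps=%d", preset, sim.n_traps)
        traces = simulate_mother_machine(sim)
        trace_path = out / f"traces_{preset}.csv"
        write_traces(traces, trace_path)
        outputs[f"traces_{preset}"] = trace_path.name

        feats = [extract_features(tr, threshold=config.threshold)
                 for tr in traces]
        features_by_strain[preset] = feats
        n_censored = sum(bool(f.censor_reasons) for f in feats)
        logger.info("features: preset=%s traces=%d censored=%d",
                    preset, len(feats), n_censored)
        fpath = out / f"features_{preset}.csv"
        write_features(feats, fpath)
        outputs[f"features_{preset}"] = fpath.name

        growth = growth_rate_series(traces)
        gpath = out / f"growth_rate_{preset}.csv"
        write_growth_rates(growth, gpath)
        outputs[f"growth_rate_{preset}"] = gpath.name
        growth_by_strain[preset] = growth

        if any(f.crossing_time is not None for f in feats):
            profile = align_traces(traces, threshold=config.threshold)
            ppath = out / f"aligned_profile_{preset}.csv"
            write_aligned_profile(profile, ppath)
            outputs[f"aligned_profile_{preset}"] = ppath.name
            profiles[preset] = profile

        times, frac, n_cells = fraction_positive_over_time(
            traces, threshold=config.threshold)
        np.savetxt(out / f"fraction_positive_{preset}.csv",
                   np.column_stack([times, frac, n_cells]),
                   delimiter=",", header="time_min,fraction,n_cells",
                   comments="", fmt="%.6g")
        outputs[f"fraction_positive_{preset}"] = f"fraction_positive_{preset}.csv"

        snap_times = [sim.t_switch, (sim.t_switch + sim.t_total) / 2, sim.t_total]
        snaps = {}
        for t in snap_times:
            idx = min(int(round(t / sim.frame_interval)), sim.n_frames - 1)
            snaps[t] = np.array([tr.fluorescence[idx] for tr in traces])
        kde_snapshots[preset] = snaps

        # endpoint flow-cytometry-like population for this strain
        f_pos = config.population_fractions.get(preset, 0.3)
        samples = sample_flow_population(
            f_pos, n_cells=config.n_cells, n_replicates=config.n_replicates,
            seed=seed, strain_label=preset)
        pop_path = out / f"population_{preset}.csv"
        write_population(samples, pop_path)
        outputs[f"population_{preset}"] = pop_path.name
        gate = (auto_gate(samples[0], fallback_gate=config.gate)
                if config.use_auto_gate else config.gate)
        summary = gate_fraction_positive(samples, gate=gate)
        fit = fit_two_component_mixture(samples[0])
        pop_rows.append((preset, summary, fit))

    sum_path = out / "population_summary.csv"
    write_population_summary(pop_rows, sum_path)
    outputs["population_summary"] = sum_path.name

    report_path = out / "report.txt"
    report_path.write_text(_strain_report(features_by_strain, pop_rows))
    outputs["report"] = report_path.name

    if make_plots:
        plotting.plot_growth_rate(
            growth_by_strain, config.simulation.t_switch, out / "growth_rate.png")
        if profiles:
            plotting.plot_aligned_profile(profiles, out / "aligned_profile.png")
        plotting.plot_kde_snapshots(kde_snapshots, out / "kde_snapshots.png")
        plotting.plot_feature_histograms(
            features_by_strain, out / "feature_histograms.png")
        outputs.update({
            "growth_rate_plot": "growth_rate.png",
            "kde_plot": "kde_snapshots.png",
            "feature_histograms_plot": "feature_histograms.png",
        })

    manifest = RunManifest.create(
        config_hash=config_hash(config.simulation), seed=seed, outputs=outputs)
    write_manifest(manifest, out / "manifest.json")
    return manifest


def _strain_report(features_by_strain, pop_rows) -> str:
    """Welch comparisons of each induction feature between strain pairs."""
    lines = ["curlipulse strain comparison report", ""]
    strains = list(features_by_strain)
    feats = [
        ("crossing_time", "threshold crossing time (min)"),
        ("max_rate", "max induction rate (AU/min)"),
        ("peak_amplitude", "first-peak amplitude (AU)"),
        ("decay_half_time", "decay half-time (min)"),
    ]
    for a in range(len(strains)):
        for b in range(a + 1, len(strains)):
            sa, sb = strains[a], strains[b]
            lines.append(f"== {sa} vs {sb} ==")
            for attr, label in feats:
                xa = np.array([getattr(f, attr) for f in features_by_strain[sa]
                               if getattr(f, attr) is not None])
                xb = np.array([getattr(f, attr) for f in features_by_strain[sb]
                               if getattr(f, attr) is not None])
                if xa.size < 2 or xb.size < 2:
                    lines.append(f"{label}: insufficient uncensored traces")
                    continue
                r = welch_t_test(xa, xb)
                lines.append(
                    f"{label}: median {np.median(xa):.3g} (n={xa.size}) vs "
                    f"{np.median(xb):.3g} (n={xb.size}); "
                    f"Welch t={r.t_statistic:.3f}, dof={r.dof:.1f}, "
                    f"p={r.p_value:.3g}")
            lines.append("")
    lines.append("== endpoint populations ==")
    for strain, summary, fit in pop_rows:
        lines.append(
            f"{strain}: fraction positive {summary.mean_fraction:.3f} "
            f"+/- {summary.sem:.4f} (gate {summary.gate:.0f} AU, "
            f"n={summary.n_replicates} replicates); bimodal={fit.bimodal}, "
            f"weights=({fit.weights[0]:.3f}, {fit.weights[1]:.3f}), "
            f"means=({fit.means[0]:.2f}, {fit.means[1]:.2f}) log10 AU")
    lines.append("")
    return "\n".join(lines)
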