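"""Figure output for pipeline runs (Agg backend; PNG files)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .features import AlignedProfile, GrowthRateSeries, TraceFeatures, expression_kde

__all__ = [
    "plot_growth_rate",
    "plot_aligned_profile",
    "plot_kde_snapshots",
    "plot_feature_histograms",
]


def plot_growth_rate(series_by_strain: dict[str, GrowthRateSeries],
                     t_switch: float, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for strain, s in series_by_strain.items():
        t = s.times - t_switch
        ax.plot(t / 60, s.median_rate, label=strain)
        ax.fill_between(t / 60, s.q25, s.q75, alpha=0.25)
    ax.axvline(0, color="k", ls="--", lw=0.8)
    ax.set_xlabel("time after medium switch (h)")
    ax.set_ylabel("instantaneous growth rate (1/min)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_aligned_profile(profiles: dict[str, AlignedProfile],
                         path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for strain, p in profiles.items():
        ax.plot(p.rel_times / 60, p.median, label=f"{strain} (n={p.n_traces})")
        ax.fill_between(p.rel_times / 60, p.q25, p.q75, alpha=0.25)
    ax.set_yscale("log")
    ax.set_xlabel("time relative to threshold crossing (h)")
    ax.set_ylabel("fluorescence (AU)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_kde_snapshots(snapshots: dict[str, dict[float, np.ndarray]],
                       path: str | Path) -> None:
    """KDE of log10 expression per strain at selected time points (minutes)."""
    strains = list(snapshots)
    fig, axes = plt.subplots(1, len(strains), figsize=(4.5 * len(strains), 3.2),
                             squeeze=False)
    for ax, strain in zip(axes[0], strains):
        for t, values in sorted(snapshots[strain].items()):
            grid, dens = expression_kde(values)
            ax.plot(grid, dens, label=f"{t / 60:.0f} h")
        ax.set_title(strain)
        ax.set_xlabel("log10 fluorescence (AU)")
        ax.set_ylabel("density")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_feature_histograms(features_by_strain: dict[str, list[TraceFeatures]],
                            path: str | Path) -> None:
    """2x2 panel: crossing times, max rates, peak amplitudes, half-times."""
    panels = [
        ("crossing_time", "crossing time (min)"),
        ("max_rate", "max induction rate (AU/min)"),
        ("peak_amplitude", "first-peak amplitude (AU)"),
        ("decay_half_time", "decay half-time (min)"),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for ax, (attr, label) in zip(axes.ravel(), panels):
        for strain, feats in features_by_strain.items():
            vals = [getattr(f, attr) for f in feats if getattr(f, attr) is not None]
            if vals:
                ax.hist(vals, bins=20, alpha=0.5, label=f"{strain} (n={len(vals)})")
        ax.set_xlabel(label)
        ax.set_ylabel("traces")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
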