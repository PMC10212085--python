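"""Single-cell trace statistics for pulsatile reporter activation.

Given mother-machine lineage traces (length + fluorescence per frame), this
module extracts the quantities used to characterize stochastic curli
induction: instantaneous growth rate, threshold-crossing time, threshold-
aligned median expression profiles, maximum induction rate, first-peak
amplitude, post-peak decay half-time, the time-resolved fraction of positive
cells, and kernel density estimates of log-fluorescence distributions.

Traces that never cross the activation threshold, show no peak, or end before
half-decay are censored for the corresponding statistic: they are excluded
from histograms and summaries but always counted, so reported n values stay
interpretable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .errors import (
    EmptyProfileError,
    InsufficientDataError,
    InvalidArgumentsError,
    InvalidTraceError,
)
from .simulate import LineageTrace

__all__ = [
    "DEFAULT_THRESHOLD",
    "TraceFeatures",
    "AlignedProfile",
    "GrowthRateSeries",
    "instantaneous_growth_rate",
    "growth_rate_series",
    "detect_divisions",
    "threshold_crossing_time",
    "align_traces",
    "max_induction_rate",
    "first_peak_amplitude",
    "decay_half_time",
    "extract_features",
    "fraction_positive_over_time",
    "expression_kde",
]

#: Conventional activation gate (AU); positive cells exceed 10^3 units.
DEFAULT_THRESHOLD = 1000.0

CENSOR_REASONS = frozenset(
    {"never_crossed", "no_peak", "decay_unfinished", "trace_too_short"})


@dataclass
class TraceFeatures:
    """Induction statistics for one lineage; None marks a censored value."""

    trap_id: str
    crossing_time: float | None = None   # min
    max_rate: float | None = None        # AU/min
    peak_time: float | None = None       # min
    peak_amplitude: float | None = None  # AU
    decay_half_time: float | None = None  # min
    censor_reasons: set[str] = field(default_factory=set)


@dataclass
class AlignedProfile:
    """Median/quartile expression profile over threshold-aligned traces."""

    rel_times: np.ndarray  # min relative to crossing (0 at the crossing frame)
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    n_per_bin: np.ndarray
    n_traces: int


@dataclass
class GrowthRateSeries:
    """Population summary of per-cell instantaneous growth rates."""

    times: np.ndarray
    median_rate: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    n_cells: np.ndarray


def _segments(division_flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open inter-division segments [a, b); a flag at i starts a segment."""
    n = division_flags.size
    starts = [0] + [i for i in range(1, n) if division_flags[i]]
    return [(a, b) for a, b in zip(starts, starts[1:] + [n])]


def instantaneous_growth_rate(trace: LineageTrace, window: int = 3) -> np.ndarray:
    """Per-frame specific elongation rate (1/min) from log-length slopes.

    The rate at frame i is the least-squares slope of log(length) over a
    centered window of ``window`` frames, restricted to the current
    inter-division segment; frames near a division or the trace boundary use
    the one-sided frames available. Single-frame segments yield NaN.
    """
    if len(trace) < 2:
        raise InvalidTraceError(f"trace {trace.trap_id}: need >= 2 frames")
    if window < 1 or window % 2 == 0:
        raise InvalidArgumentsError("window: must be odd and >= 1")
    if np.any(trace.lengths <= 0):
        raise InvalidTraceError(f"trace {trace.trap_id}: non-positive length")
    logl = np.log(trace.lengths)
    t = trace.times
    half = max(window // 2, 1)  # window=1 still needs a 2-point slope
    out = np.full(len(trace), np.nan)
    for a, b in _segments(trace.division_flags):
        if b - a < 2:
            continue
        for i in range(a, b):
            lo = max(a, i - half)
            hi = min(b, i + half + 1)
            tt, yy = t[lo:hi], logl[lo:hi]
            tm = tt - tt.mean()
            out[i] = float(tm @ (yy - yy.mean()) / (tm @ tm))
    return out


def growth_rate_series(traces: list[LineageTrace], window: int = 3) -> GrowthRateSeries:
    """Median and interquartile growth rate across traces, per frame.

    Traces must share a common time grid (as mother-machine movies do).
    """
    if not traces:
        raise InsufficientDataError("no traces")
    times = traces[0].times
    rates = np.full((len(traces), times.size), np.nan)
    for i, tr in enumerate(traces):
        if tr.times.size != times.size or not np.allclose(tr.times, times):
            raise InvalidTraceError("traces do not share a common time grid")
        rates[i] = instantaneous_growth_rate(tr, window=window)
    n = np.sum(np.isfinite(rates), axis=0)
    with np.errstate(all="ignore"):
        med = np.nanmedian(rates, axis=0)
        q25 = np.nanpercentile(rates, 25, axis=0)
        q75 = np.nanpercentile(rates, 75, axis=0)
    return GrowthRateSeries(times=times.copy(), median_rate=med,
                            q25=q25, q75=q75, n_cells=n)


def detect_divisions(lengths: np.ndarray, drop_fraction: float = 0.25) -> np.ndarray:
    """Flag frames whose length dropped by more than ``drop_fraction``.

    Frame i is flagged iff lengths[i] < (1 - drop_fraction) * lengths[i-1];
    frame 0 is never flagged.
    """
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise InvalidTraceError("non-positive length")
    flags = np.zeros(lengths.size, dtype=bool)
    if lengths.size > 1:
        flags[1:] = lengths[1:] < (1.0 - drop_fraction) * lengths[:-1]
    return flags


def threshold_crossing_time(
    trace: LineageTrace,
    threshold: float = DEFAULT_THRESHOLD,
    interpolate: bool = False,
) -> float | None:
    """Time of the first frame with fluorescence >= threshold, or None.

    With ``interpolate=True`` the crossing time is linearly interpolated
    between the bracketing frames (frame-resolution reporting is the default).
    A trace already above the threshold at its first frame crosses at time 0.
    """
    if len(trace) == 0:
        raise InvalidTraceError("empty trace")
    if threshold <= 0:
        raise InvalidArgumentsError("threshold: must be > 0")
    above = trace.fluorescence >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if interpolate and i > 0:
        f0, f1 = trace.fluorescence[i - 1], trace.fluorescence[i]
        frac = (threshold - f0) / (f1 - f0) if f1 > f0 else 1.0
        return float(trace.times[i - 1] + frac * (trace.times[i] - trace.times[i - 1]))
    return float(trace.times[i])


def _crossing_index(trace: LineageTrace, threshold: float) -> int | None:
    above = trace.fluorescence >= threshold
    return int(np.argmax(above)) if above.any() else None


def align_traces(
    traces: list[LineageTrace],
    threshold: float = DEFAULT_THRESHOLD,
    window_before: float = 300.0,
    window_after: float = 900.0,
) -> AlignedProfile:
    """Median expression profile of traces aligned at threshold crossing.

    Traces without a crossing are excluded; each contributing trace is shifted
    so its crossing frame sits at relative time 0. Per relative frame, the
    median and quartiles are taken over the traces that have data there.
    """
    crossers = [(tr, _crossing_index(tr, threshold)) for tr in traces]
    crossers = [(tr, k) for tr, k in crossers if k is not None]
    if not crossers:
        raise EmptyProfileError("no trace crosses the threshold")
    dt = crossers[0][0].frame_interval
    lo = -int(window_before // dt)
    hi = int(window_after // dt)
    rel_frames = np.arange(lo, hi + 1)
    mat = np.full((len(crossers), rel_frames.size), np.nan)
    for row, (tr, k) in enumerate(crossers):
        idx = k + rel_frames
        ok = (idx >= 0) & (idx < len(tr))
        mat[row, ok] = tr.fluorescence[idx[ok]]
    n = np.sum(np.isfinite(mat), axis=0)
    keep = n > 0
    with np.errstate(all="ignore"):
        med = np.nanmedian(mat[:, keep], axis=0)
        q25 = np.nanpercentile(mat[:, keep], 25, axis=0)
        q75 = np.nanpercentile(mat[:, keep], 75, axis=0)
    return AlignedProfile(
        rel_times=rel_frames[keep] * dt,
        median=med, q25=q25, q75=q75,
        n_per_bin=n[keep], n_traces=len(crossers))


def _smooth(f: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return f
    if window % 2 == 0:
        raise InvalidArgumentsError("smooth_window: must be odd")
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(f, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def max_induction_rate(
    trace: LineageTrace,
    threshold: float = DEFAULT_THRESHOLD,
    smooth_window: int = 1,
) -> float | None:
    """Maximum forward finite-difference rate of fluorescence increase (AU/min).

    Computed only for traces that cross ``threshold`` (None otherwise, reason
    never_crossed); an optional centered moving average of ``smooth_window``
    frames is applied first. A non-positive maximum is censored.
    """
    if len(trace) < 2:
        return None
    if _crossing_index(trace, threshold) is None:
        return None
    f = _smooth(trace.fluorescence, smooth_window)
    rates = np.diff(f) / np.diff(trace.times)
    best = float(np.max(rates))
    return best if best > 0 else None


def first_peak_amplitude(
    trace: LineageTrace,
    threshold: float = DEFAULT_THRESHOLD,
    prominence_fraction: float = 0.1,
) -> tuple[float, float] | None:
    """(peak_time, peak_amplitude) of the first qualifying post-crossing peak.

    The first local maximum at or after the crossing whose prominence is at
    least ``prominence_fraction * (max(F) - F0_est)`` qualifies, where F0_est
    is the median fluorescence before the crossing (the trace minimum when the
    trace starts above threshold). Prominence filtering keeps noise blips from
    terminating a pulse early. None if the trace is still rising at its end.
    """
    k = _crossing_index(trace, threshold)
    if k is None:
        return None
    f = trace.fluorescence
    f0_est = float(np.median(f[:k])) if k > 0 else float(np.min(f))
    prom = prominence_fraction * max(float(np.max(f)) - f0_est, 0.0)
    peaks, _ = signal.find_peaks(f, prominence=prom if prom > 0 else None)
    peaks = peaks[peaks >= k]
    if peaks.size == 0:
        return None
    i = int(peaks[0])
    return float(trace.times[i]), float(f[i])


def decay_half_time(
    trace: LineageTrace,
    peak_time: float,
    peak_amplitude: float,
    baseline: float,
) -> float | None:
    """Minutes from the peak until fluorescence halves toward ``baseline``.

    The half level is ``baseline + 0.5*(peak_amplitude - baseline)``; the
    crossing is linearly interpolated between the bracketing frames. None
    (decay unfinished) if the level is never reached before the trace ends.
    """
    if baseline >= peak_amplitude:
        raise InvalidArgumentsError("baseline: must be below peak_amplitude")
    half = baseline + 0.5 * (peak_amplitude - baseline)
    i0 = int(np.searchsorted(trace.times, peak_time))
    f, t = trace.fluorescence, trace.times
    below = np.nonzero(f[i0 + 1:] <= half)[0]
    if below.size == 0:
        return None
    j = i0 + 1 + int(below[0])
    f_prev, f_next = f[j - 1], f[j]
    if f_prev > f_next:
        frac = (f_prev - half) / (f_prev - f_next)
    else:
        frac = 1.0
    t_half = t[j - 1] + frac * (t[j] - t[j - 1])
    return float(t_half - peak_time)


def extract_features(
    trace: LineageTrace,
    threshold: float = DEFAULT_THRESHOLD,
    smooth_window: int = 1,
    prominence_fraction: float = 0.1,
) -> TraceFeatures:
    """All induction statistics for one trace, with censoring bookkeeping."""
    feats = TraceFeatures(trap_id=trace.trap_id)
    if len(trace) < 2:
        feats.censor_reasons.add("trace_too_short")
        return feats
    ct = threshold_crossing_time(trace, threshold)
    if ct is None:
        feats.censor_reasons.add("never_crossed")
        return feats
    feats.crossing_time = ct
    feats.max_rate = max_induction_rate(trace, threshold, smooth_window)
    if feats.max_rate is None:
        # crossed but never increased: no rising phase, hence no peak either
        feats.censor_reasons.add("no_peak")
    peak = first_peak_amplitude(trace, threshold, prominence_fraction)
    if peak is None:
        feats.censor_reasons.add("no_peak")
        return feats
    feats.peak_time, feats.peak_amplitude = peak
    k = _crossing_index(trace, threshold)
    baseline = (float(np.median(trace.fluorescence[:k])) if k and k > 0
                else float(np.min(trace.fluorescence)))
    if baseline >= feats.peak_amplitude:
        feats.censor_reasons.add("decay_unfinished")
        return feats
    dht = decay_half_time(trace, feats.peak_time, feats.peak_amplitude, baseline)
    if dht is None:
        feats.censor_reasons.add("decay_unfinished")
    else:
        feats.decay_half_time = dht
    return feats


def fraction_positive_over_time(
    traces: list[LineageTrace],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, fraction, n_cells): share of traces at/above threshold per frame."""
    if not traces:
        raise InsufficientDataError("no traces")
    times = traces[0].times
    counts = np.zeros(times.size)
    n = np.zeros(times.size, dtype=int)
    for tr in traces:
        if tr.times.size != times.size or not np.allclose(tr.times, times):
            raise InvalidTraceError("traces do not share a common time grid")
        counts += tr.fluorescence >= threshold
        n += 1
    return times.copy(), counts / n, n


def expression_kde(
    values: np.ndarray,
    grid: np.ndarray | None = None,
    bandwidth: str | float = "silverman",
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of log10 fluorescence on a log10-AU grid.

    Returns (grid, density); the density integrates to ~1 over a grid that
    covers the sample support. Bandwidth follows Silverman's rule unless
    overridden with a scalar factor.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("need >= 2 values for a KDE")
    if np.any(values <= 0):
        raise InvalidArgumentsError("values: must be > 0 (log-representable)")
    logv = np.log10(values)
    kde = stats.gaussian_kde(logv, bw_method=bandwidth)
    if grid is None:
        pad = 4.0 * kde.factor * logv.std(ddof=1)
        grid = np.linspace(logv.min() - pad, logv.max() + pad, 512)
    density = kde(grid)
    return np.asarray(grid, dtype=float), density
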