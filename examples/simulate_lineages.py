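"""Simulate a mother-machine experiment and summarize growth and activation.

Lineages grow in fresh medium for 4 h, then switch to conditioned medium:
growth slows sharply and a subpopulation later fires transient curli pulses.
"""
import numpy as np

from curlipulse import (
    SimulationConfig,
    fraction_positive_over_time,
    growth_rate_series,
    simulate_mother_machine,
)

cfg = SimulationConfig(seed=1)
traces = simulate_mother_machine(cfg)
print(f"simulated {len(traces)} lineages, {len(traces[0])} frames "
      f"({cfg.frame_interval:g} min apart)")

series = growth_rate_series(traces)
pre = series.times < cfg.t_switch - 20
post = series.times > cfg.t_switch + 300
print(f"median growth rate: {np.nanmedian(series.median_rate[pre]):.4f}/min "
      f"in fresh medium -> {np.nanmedian(series.median_rate[post]):.4f}/min "
      "in conditioned medium")

times, frac, n = fraction_positive_over_time(traces, threshold=1000.0)
print(f"fraction of cells above 10^3 AU at the last frame: {frac[-1]:.2f} "
      f"(of n={n[-1]} cells)")
print("-> growth collapses ~5x after the switch while only a subpopulation "
      "ever activates the reporter.")
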