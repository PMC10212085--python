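"""Extract per-lineage induction statistics from simulated traces.

For every lineage: threshold-crossing time, maximum induction rate,
first-peak amplitude, and post-peak decay half-time, with explicit
censoring for lineages that never activate or end mid-pulse.
"""
from collections import Counter

import numpy as np

from curlipulse import SimulationConfig, extract_features, simulate_mother_machine

traces = simulate_mother_machine(SimulationConfig(seed=1))
feats = [extract_features(tr, threshold=1000.0, smooth_window=3)
         for tr in traces]

censored = Counter(r for f in feats for r in f.censor_reasons)
print(f"{len(feats)} lineages; censoring tally: {dict(censored)}")

for attr, unit in [("crossing_time", "min"), ("max_rate", "AU/min"),
                   ("peak_amplitude", "AU"), ("decay_half_time", "min")]:
    vals = [getattr(f, attr) for f in feats if getattr(f, attr) is not None]
    print(f"median {attr}: {np.median(vals):.1f} {unit} (n={len(vals)})")
print("-> each feature is reported only for the lineages where it is "
      "observable; n values stay interpretable because censored lineages "
      "are counted, not dropped silently.")
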