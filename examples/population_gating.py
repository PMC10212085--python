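"""Quantify bimodality and the positive fraction in endpoint samples.

Draws three 50,000-cell replicates from a bimodal log10 mixture with 46%
positives (an overnight-flask-like regime), then recovers that fraction with
a fixed 10^3 AU gate and with a mixture-based auto-gate.
"""
from curlipulse import (
    auto_gate,
    fit_two_component_mixture,
    gate_fraction_positive,
    sample_flow_population,
)

samples = sample_flow_population(0.46, n_cells=50_000, n_replicates=3, seed=1)

fixed = gate_fraction_positive(samples, gate=1000.0)
print(f"fixed gate 1000 AU: fraction positive "
      f"{fixed.mean_fraction:.3f} +/- {fixed.sem:.4f} "
      f"(mean of {fixed.n_replicates} replicates +/- SEM)")

gate = auto_gate(samples[0])
auto = gate_fraction_positive(samples, gate=gate)
print(f"auto gate {gate:.0f} AU (mixture posterior-equality point): "
      f"fraction positive {auto.mean_fraction:.3f} +/- {auto.sem:.4f}")

fit = fit_two_component_mixture(samples[0])
print(f"mixture fit: weights ({fit.weights[0]:.3f}, {fit.weights[1]:.3f}), "
      f"means ({fit.means[0]:.2f}, {fit.means[1]:.2f}) log10 AU, "
      f"bimodal={fit.bimodal}")
print("-> both estimators recover the generating positive fraction; the "
      "mixture additionally certifies that the sample is bimodal.")
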