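"""Compare induction dynamics with and without c-di-GMP regulation.

The "deregulated" preset emulates a strain lacking the DgcE/PdeH and
DgcM/PdeR network: same activation frequency, but faster and more
heterogeneous induction. The contrast is tested per feature with Welch's
unequal-variance t-test.
"""
import numpy as np

from curlipulse import (
    PRESETS,
    extract_features,
    simulate_mother_machine,
    welch_t_test,
)
import dataclasses

reg = simulate_mother_machine(
    dataclasses.replace(PRESETS["regulated"], seed=1, n_traps=300))
der = simulate_mother_machine(
    dataclasses.replace(PRESETS["deregulated"], seed=2, n_traps=520))

fr = [extract_features(t, smooth_window=3) for t in reg]
fd = [extract_features(t, smooth_window=3) for t in der]

mr_r = np.array([f.max_rate for f in fr if f.max_rate is not None])
mr_d = np.array([f.max_rate for f in fd if f.max_rate is not None])
w = welch_t_test(mr_d, mr_r)
print(f"max induction rate: regulated median {np.median(mr_r):.1f} AU/min "
      f"(n={mr_r.size}) vs deregulated {np.median(mr_d):.1f} AU/min "
      f"(n={mr_d.size})")
print(f"Welch t={w.t_statistic:.2f}, dof={w.dof:.0f}, p={w.p_value:.2g}")

iqr = lambda x: np.percentile(x, 75) - np.percentile(x, 25)
pa_r = np.array([f.peak_amplitude for f in fr if f.peak_amplitude is not None])
pa_d = np.array([f.peak_amplitude for f in fd if f.peak_amplitude is not None])
print(f"first-peak amplitude IQR: regulated {iqr(pa_r):.0f} AU vs "
      f"deregulated {iqr(pa_d):.0f} AU")
print("-> without the regulatory network, cells induce roughly twice as "
      "fast and with visibly wider cell-to-cell spread.")
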