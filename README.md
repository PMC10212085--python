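# curlipulse

Quantitative analysis of **bimodal, pulsatile curli reporter activation** in
*E. coli* single cells.

Curli amyloid fibers — the backbone of the *E. coli* biofilm matrix — are
expressed in an all-or-none fashion: in a population entering stationary
phase only a fraction of cells turns the *csgBAC* reporter on, and in
single-cell mother-machine experiments that activation is stochastic,
delayed, and transient. This package is for researchers analyzing such
data: it extracts per-lineage induction statistics from mother-machine
traces, quantifies bimodality and the positive fraction in flow-cytometry
endpoint samples, and ships a synthetic generator that emulates both data
types so every estimator is testable without any experimental download.

## What it computes

For a lineage with length \(L(t)\) and reporter fluorescence \(F(t)\):

* **instantaneous growth rate** — the slope of \(\log L\) over a centered
  3-frame window within each inter-division segment;
* **threshold crossing time** — first frame with \(F \ge 10^3\) AU;
* **aligned profile** — median and interquartile \(F\) over traces shifted
  so their crossing sits at time 0;
* **max induction rate** — \(\max_i (F_{i+1}-F_i)/\Delta t\);
* **first-peak amplitude** — first prominent local maximum after crossing;
* **decay half-time** — time from the peak to
  \(F = F_0 + \tfrac12(F_\text{peak}-F_0)\).

For endpoint populations (log10 AU): the gated positive fraction summarized
as mean ± SEM over biological replicates, and a two-component Gaussian
mixture fitted by EM with a bimodality flag and a posterior-equality
auto-gate. Strain contrasts use Welch's unequal-variance t-test.

The generator is a telegraph model on top of exponential growth: off→on at
rate \(k_\text{on}\) (only after a lag following the switch to conditioned
medium), on→off at \(k_\text{off}\), and
\(\dot F = \beta\,[\text{on}] - (g+\delta)F\) with per-pulse lognormal
\(\beta\). See `docs/methods.md` for parameters, defaults, and rationale.

## Worked example

```python
import numpy as np
from curlipulse import (SimulationConfig, simulate_mother_machine,
                        extract_features, growth_rate_series)

traces = simulate_mother_machine(SimulationConfig(seed=1))
series = growth_rate_series(traces)
feats = [extract_features(tr, threshold=1000.0, smooth_window=3)
         for tr in traces]
crossed = [f for f in feats if f.crossing_time is not None]
print(len(traces), len(crossed))
print(np.median([f.max_rate for f in crossed if f.max_rate is not None]))
```

prints `300 124` and `38.6...`: of 300 lineages, 124 activate the reporter
after the medium switch, with a median maximum induction rate of
≈39 AU/min — the remaining 176 lineages are censored (`never_crossed`)
rather than silently dropped, so the n of every histogram stays
interpretable. Running `python examples/strain_contrast.py` compares this
against the "deregulated" preset (no c-di-GMP regulatory network):

```
max induction rate: regulated median 38.6 AU/min (n=124) vs deregulated 79.7 AU/min (n=222)
Welch t=15.91, dof=252, p=6.1e-40
first-peak amplitude IQR: regulated 3890 AU vs deregulated 10623 AU
```

i.e. without the regulatory network cells induce about twice as fast with a
much wider cell-to-cell spread. The other scripts in `examples/` cover
simulation, feature extraction, and population gating, one capability each.

## Command line

A thin CLI wraps the library for shell use:

```bash
curlipulse simulate --preset regulated --seed 1 --out traces.csv
curlipulse traces --in traces.csv --threshold 1000 --out features.csv
curlipulse population --in pop.csv --gate 1000 --auto-gate --out summary.csv
curlipulse pipeline --out results/ --seed 1
```

`pipeline` runs simulate → features → population → report end to end and
writes tidy CSVs, figures, and a JSON manifest; re-running with the same
config and seed reproduces byte-identical CSVs.

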