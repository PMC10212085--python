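# Methods

## The problem

Curli amyloid fibers, the main protein component of the *E. coli* biofilm
matrix, are expressed by only a subpopulation of cells: endpoint
flow-cytometry snapshots of a *csgBAC* transcriptional reporter are bimodal,
and time-lapse imaging of single lineages in a mother-machine device shows
that the curli-positive state is reached stochastically, after a delay, and
is only metastable — individual cells fire a transient pulse of reporter
expression and later switch off again. `curlipulse` implements the
quantitative layer of such an experiment: a synthetic generator with that
statistical structure, per-lineage induction statistics, population-level
bimodality estimators, and the small amount of inference (Welch's t-test,
replicate SEM) the comparisons require.

## Synthetic generator

One "trap" is one mother cell followed for the whole movie; daughters are
discarded at division, matching what the downstream trace analysis consumes.
The generator does not model device geometry, imaging, or the c-di-GMP
reaction network — it produces traces with the assumed statistical
structure, which is exactly what the estimators need to be testable.

**Growth.** Cell length elongates exponentially at
`g(t) = g_cond + (g_fresh − g_cond)·exp(−max(0, t−t_switch)/tau_relax)`.
Frame updates use the exact integral of `g` over the frame, so noiseless
traces are exactly log-linear within a regime. Defaults: `g_fresh = 0.02/min`
(≈35 min doubling, rich medium at 30 °C), `g_cond = 0.004/min` (≈3 h
doubling in conditioned medium), `tau_relax = 30 min`, switch at
`t_switch = 240 min`, 10-min frames, 1800 min total, 300 traps.

**Division.** A cell divides when its length exceeds a per-cycle target
drawn as `N(L_div_mean, cv_div·L_div_mean)` (defaults 5.0 µm, CV 0.1); the
retained cell keeps a fraction `ratio ~ N(0.5, 0.05)` of the grown length.
Ratios are clipped to [0.4, 0.6] so that under the fastest default growth a
division always registers as a >25 % length drop in noiseless traces — the
same rule the division detector uses.

**Expression.** A telegraph (two-state) process: off→on at rate `k_on`, but
only after `t_switch + lag` (activation requires a period of slow growth);
on→off at rate `k_off`. Each pulse draws its own production rate β from a
lognormal with median `beta_median` and CV `beta_cv`, capturing stable
cell-to-cell differences in induction strength. Fluorescence integrates
`dF/dt = β·[on] − (g + δ)·F`, i.e. production minus dilution by growth (and
optional degradation δ, 0 for stable GFP), floored at the autofluorescence
baseline `F0`. Defaults: `k_on = 4×10⁻⁴/min`, so ≈44 % of lineages activate
within the ~24 h post-switch window — the ratio of analyzed to observed
lineages in mother-machine curli experiments; `lag = 120 min` (a few
generations of slow growth); `k_off = 1/300 min⁻¹` (pulses last ≈5 h);
`beta_median = 40 AU/min`, `beta_cv = 0.25`; `F0 = 100 AU`. With
`g_cond = 0.004/min` the on-state plateau is `β/g ≈ 10⁴ AU`, so the
fluorescence scale is calibrated by convention: negative mode near 10² AU,
positive mode near 10⁴ AU, and the conventional 10³ AU gate separates them.

**Presets.** `"regulated"` is the default bundle above. `"deregulated"`
encodes the qualitative behaviour of a strain lacking the DgcE/PdeH +
DgcM/PdeR c-di-GMP network: induction is about twice as fast and twice as
heterogeneous (`beta_median` and `beta_cv` both doubled), while activation
frequency, growth, and timing are unchanged. The multipliers are free
parameters with these defaults, not measured quantities.

**Noise.** Multiplicative lognormal measurement noise (CV `noise_cv`,
default 0.03 — a few-percent segmentation/photometry error) is applied to
both length and fluorescence readouts, after the dynamics. Setting
`noise_cv = beta_cv = 0` gives bit-reproducible noiseless traces used by the
exactness tests.

**Randomness.** A single root seed feeds named `SeedSequence` substreams
(`init`, `division`, `expression`, `noise`, `replicate`), so switching one
noise source on or off does not perturb the draws of the others, and
identical (config, seed) pairs are bit-identical across runs.

**Controlled pulses.** `simulate_pulse_traces` forces every lineage on
during a fixed window at constant growth. It exists because the closed-form
pulse shape — rise toward `β/(g+δ)`, peak
`F0 + (β/(g+δ))(1 − e^{−(g+δ)T_on})`, dilution-limited decay with half-life
`ln 2/(g+δ)` — is only defined for a known on-window; the recovery tests
compare estimator medians over 200 such pulses against those expressions.

**What the generator does not emulate.** Cell-cycle–dependent expression,
partitioning noise at division acting on fluorescence (dilution is treated
as continuous), trap-loss and filamentation artifacts, photobleaching,
second activation pulses with different β, and any mechanistic c-di-GMP
dynamics. Passing tests therefore demonstrate estimator correctness on data
with the assumed structure, not robustness to every artifact of real movies.

## Trace features

* **Instantaneous growth rate**: least-squares slope of log(length) over a
  centered 3-frame window, computed within inter-division segments only;
  boundary frames use the one-sided frames available; single-frame segments
  are missing. The log-slope makes the estimator exactly invariant to length
  rescaling. Three frames is the shortest window that averages any noise at
  all while still resolving the growth-rate collapse at the medium switch;
  it is a config parameter.
* **Division detection** (for input files without flags): a frame is a
  division iff length drops by more than 25 % from the previous frame.
* **Threshold crossing**: first frame with F ≥ 10³ AU, reported at frame
  resolution (10 min) to match how such data are acquired; linear
  interpolation is available behind a flag but off by default. A trace
  already above threshold at frame 0 crosses at time 0 (cells loaded from
  overnight culture can start positive).
* **Aligned profile**: traces with a crossing are shifted so the crossing
  frame sits at relative time 0; median and quartiles are computed per
  relative frame over the traces with data there, with per-bin n reported.
* **Max induction rate**: maximum forward finite difference of F, optionally
  after a centered moving average. The default is raw (window 1); analyses
  of noisy data should use window 3, which suppresses the upward bias that
  taking a maximum over noisy differences otherwise produces.
* **First peak**: first local maximum after the crossing with prominence
  ≥ 10 % of the trace's dynamic range above its pre-induction baseline
  (median F before the crossing). The prominence floor keeps few-percent
  noise blips from terminating a pulse early; it is configurable.
* **Decay half-time**: time from the peak until F falls to
  `baseline + 0.5·(peak − baseline)`, linearly interpolated between frames.
  Halving is measured relative to the pre-induction baseline, not zero: a
  stable reporter diluted by slow growth never returns to zero within a
  movie, so absolute halving would censor nearly everything.
* **Censoring**: `never_crossed`, `no_peak` (still rising at the end of the
  movie, or crossed without ever increasing), `decay_unfinished`,
  `trace_too_short`. Censored lineages are excluded from histograms and
  medians but always counted.

## Population bimodality

All population analysis is on log10 fluorescence; non-positive readings
(instrument artifacts) are dropped before the transform.

* **Fixed gate** (default 10³ AU, consistent with the trace threshold):
  per-replicate positive fraction, summarized as mean ± SEM
  (sample sd/√n, 0 for one replicate).
* **Mixture fit**: two-component Gaussian EM with means initialized at the
  25th/75th percentiles, both sds at the pooled sd, weights at ½. The
  log-likelihood is non-decreasing per iteration (asserted in tests);
  convergence is an improvement < 10⁻⁸. The fit is deterministic given the
  data. A sample is flagged *bimodal* iff both weights ≥ 0.02 and the means
  are ≥ 2 pooled-max sds apart (an Ashman-D ≥ 2√2 style separation rule).
* **Auto gate**: if bimodal, the gate is the log10 point where the two
  components have equal posterior responsibility (solved by root finding;
  verified against a brute-force grid in tests), mapped back to AU;
  otherwise the fixed gate is used. The fallback means that extreme samples
  whose minority component is below the 2 % weight floor are still gated
  sensibly.

## Inference

Welch's unequal-variance two-sample t-test (two-sided, the conservative
default where sidedness is unstated) with Welch–Satterthwaite degrees of
freedom, implemented from the formulas and cross-checked against
`scipy.stats.ttest_ind(equal_var=False)` in the tests. Two constant samples
with equal means return t = 0, p = 1 by convention. No multiple-testing
correction is applied across the four feature comparisons. The per-feature
comparisons can be run pooled across replicate experiments or per replicate.

## Problem sizes and numerical choices

The test suite and acceptance script run the generator at its default scale
(300 regulated / 520 deregulated traps, 181 frames; endpoint samples of
3 × 50,000 cells; 200 pulses for recovery; 20 seeds for the strain
contrast; 1000 repetitions for type-I calibration) — the same sizes the
defaults encode as the experimental regime. Stochastic checks use binomial
3-standard-error bands; exactness checks use 10⁻⁹ relative tolerance on
noiseless inputs. Ties in peak finding resolve to the earliest frame;
crossing with no frame ≥ threshold is censored rather than extrapolated.

## Known limitations

Only the mother cell is analyzed — no lineage trees, no sister-cell
correlations. The mixture model is restricted to two components; samples
with an intermediate (partially induced) mode will fit poorly and may be
flagged unimodal. The KDE integrates to 1 only over a grid that covers the
sample support, as the tests document. FCS files are not parsed; population
input is CSV (one configured channel, singlet-gated upstream).
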