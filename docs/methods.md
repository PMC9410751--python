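# Methods

This note documents the models, measurement procedures, numerical choices
and known limitations of `synquant`. It is the package's own account of
what it computes; every number quoted here is produced by the test suite or
the analysis scripts.

## Generative model (`synquant.synthdata`)

### Quantal release

A connection is modeled as `N` independent release sites. On presynaptic
action potential (AP) *k* each occupied site releases one vesicle with
probability

```
p_k = min(1, p0 · F_k)
```

A released vesicle contributes a quantum of postsynaptic amplitude drawn
lognormally with mean `q` and coefficient of variation `quantal_cv`
(lognormal for positivity; quanta are independent across sites). The
closed-form moments used throughout as oracles are the binomial mean
response `E = N·p·q` and failure probability `F = (1−p)^N`.

### Short-term plasticity

Facilitation follows residual-calcium phenomenology: a dimensionless
factor `F_k` starts at 1, jumps by `facil_increment` (`a_F`) after every
AP and relaxes exponentially back to 1 with `tau_facil` between APs. It
acts multiplicatively on `p0` (never below baseline, so `F_k ≥ 1` always).
Depression is per-site binary occupancy: a site that releases is empty
until it refills, with probability `1 − exp(−Δt/tau_recovery)` per
inter-pulse interval. The expected per-pulse amplitude has the exact
recursion `E_k = N·o_k·p_k·q` with occupancy `o_k` propagated pulse by
pulse; `expected_pulse_amplitudes` implements it and is the oracle for all
train-analysis tests.

Default facilitation parameters (`a_F = 4.8`, `tau_facil = 54 ms`) are the
fitted paired-pulse-facilitation decay of the cortical PC→SOM synapse this
package targets, so the simulated paired-pulse ratio at short intervals
(~5) and its decay constant are realistic by construction.

### Rendering

Each released packet is convolved with a difference-of-exponentials
kernel, normalized to unit peak so `q` is the response peak amplitude by
construction, delayed by `latency` with per-trial Gaussian jitter.
Gaussian white baseline noise is added per sample, and slow rundown scales
`q(t) = q·(1 − rundown_rate·t)` (clipped at zero) with `t` the sweep
timestamp in minutes — the linear form matched by the rundown screen.

What the generator does **not** emulate: the 2-kHz acquisition filter
(noise is white at the 10-kHz sampling rate, which is *harder* for event
detection than filtered noise), electrode/access artifacts, stimulus
crosstalk, spontaneous synaptic events, and real neurons' conductance
nonlinearities. Passing tests therefore demonstrate correctness of the
analysis given the binomial/STP model class, not robustness to every
recording pathology.

### Disynaptic circuit

The frequency-dependent disynaptic inhibition (FDDI) experiment is a
three-stage chain: PC1 fires ten APs at 100 Hz; a facilitating excitatory
synapse drives a SOM interneuron modeled as a leaky integrator of EPSP
kernels (the EPSP decay constant, 30 ms, doubles as the membrane time
constant); each threshold crossing emits a spike, clears the accumulated
depolarization, and imposes a 5-ms refractory period; each spike evokes,
after a 2-ms conduction delay, an outward IPSC in the voltage-clamped PC2
(unit-peak kernel, rise 2 ms, decay 45 ms, amplitude 6.5 pA with CV 0.2)
on top of 1.5-pA recording noise.

By default the SOM drive is **mean-field**: the interneuron receives the
expected per-pulse EPSP amplitudes rather than a binomial sample
(`CircuitParams.deterministic_som`). The recruitment time is then set by
the synapse's mean dynamics, and per-sweep variability comes from latency
jitter, IPSC amplitude CV and noise. With fully stochastic release the
first-spike time disperses over roughly one train interval (10 ms), which
is a property of the circuit, not of the measurement; the mean-field
default keeps the simulated ground-truth onset a well-defined quantity
that the trace-level measurement can be validated against (within 3 ms).
Stochastic drive remains available by setting the flag to `False`.

Circuit presets were calibrated once so that the wild-type defaults
produce onset ≈ 54 ms, peak ≈ 10.5 pA and charge ≈ 715 pA·ms, with the
FHM1 preset differing **only** in the PC→SOM release probability
(`p0` 0.05 → 0.125, the gain-of-function of release). The wild-type half
duration (~38 ms) falls short of the reference value (~52 ms); a longer
IPSC decay would lengthen it but degrade the onset/charge agreement, and
the genotype contrast (earlier onset, longer half duration, larger charge
in FHM1) holds in every calibration run regardless.

### Cohort presets

Per-connection heterogeneity for the three synapse classes
(`COHORT_PRESETS`): PC→SOM draws `N ∈ {1..5}`, `p0 ∈ [0.02, 0.08]` at
fixed `q = 0.926 mV` (mean response ≈ 0.14 mV, failures ≈ 85–87%);
SOM→PC is high-`p` (`N` 4–6, `p0` 0.3–0.5, `q = 30 pA`) with fast-refill
depression giving a paired-pulse ratio slightly below 1; PC→PC is
intermediate. The FHM1 genotype scales `p0` only (×2.14 for PC→SOM,
unchanged for SOM→PC), reproducing ≈ 0.30 mV and ≈ 70–75% failures.

## Measurement procedures (`synquant.events`)

* **Baseline**: mean and SD of the 50 ms preceding the first stimulus
  (window configurable, ≥ 20 samples enforced).
* **Event criterion**: the signed peak within a 1–10 ms post-stimulus
  latency window must reach 2.5 × baseline SD. Because the maximum of
  tens of white-noise samples routinely exceeds 2.5 SD whatever the SD,
  the amplitude criterion alone misclassifies a scale-independent fraction
  of failures (~20% of trials in simulation); an additional
  time-to-peak gate (default 0.8–8 ms, learnable from large events via
  `learn_ttp_bounds`) restores essentially error-free separation (<0.2%
  combined error in simulation). Noise maxima rise in well under a
  millisecond; synaptic responses over one to several.
* **Mean response amplitude**: sweeps are averaged (failures included),
  the peak of the average is located within the latency window on a
  1-kHz low-passed copy (re-centred on the raw trace with
  midpoint-of-ties so flat tops resolve exactly), and the amplitude is
  the *trapezoidal* mean of the unsmoothed average over a 1-ms window
  centred on the peak, minus the baseline mean. The trapezoidal mean is
  the discrete equivalent of the window integral; on a triangular peak
  with ±1 mV/ms flanks it reads 0.75 of the true peak — the window's
  documented bias on sharp peaks, which cancels in train ratios.
* **Fallback single-trial mean**: arithmetic mean of per-trial peak
  amplitudes, failures contributing their measured (noise-level) values.
  Equal to the averaged-trace measurement in the noiseless case.
* **Rundown screen**: linear fit of per-sweep amplitude vs time over the
  first six minutes; fractional decline `−slope·window/intercept`;
  exclusion above 15%; fewer than five sweeps → flagged unscreenable.

## Train analysis (`synquant.stp`)

Temporal summation is corrected in two modes. *Per-pulse* (≤ 25 Hz): the
decay of each mean response, from its peak to the next stimulus, is fitted
with one or two exponentials (extra-sum-of-squares F test at α = 0.05
selects the count) and the fitted residual, averaged over the next pulse's
1-ms measurement window, is subtracted from the next raw amplitude.
*Last-pulse* (100 Hz, and automatic fallback when an inter-pulse segment
is unfittable): only the final response's decay is fitted and its
normalized time constants propagate every residual backward from the
observed compound peak values. Both modes are exact to numerical fitting
precision when the generating decay is a single noiseless exponential, and
recover per-pulse quantal content within 2% (after cancelling the window
bias via pulse 1) on noiseless 25- and 100-Hz trains with a realistic
rise/decay kernel.

Exponential fitting uses variable projection: for any candidate time
constants the amplitudes solve a linear least-squares problem exactly
(non-negative where the model demands it), so the nonlinear search runs
over log-τ only, Nelder–Mead from log-spaced multi-starts, τ bounded to
[1, 10⁴] ms. Long trace segments are decimated to ≤ 250 points before
fitting (an exact fit stays exact). A single-exponential fit whose
residual is at numerical zero short-circuits the F test (the
two-component model can only overfit machine noise there). A fitted decay
component pinned at a τ bound flags the fit *unless* its amplitude is
negative — a negative fast component is the rise remnant of the kernel,
not a failure. Two-component fits with coincident time constants
(relative gap < 10⁻³) report as single-component.

The paired-pulse-facilitation decay is fitted as
`PPR(Δt) = 1 + A·e^(−Δt/τ)` — asymptote 1 is physically forced (no
facilitation at infinite interval) — per group and shared across groups,
with the extra-SS F test deciding shared vs separate. The noise model
matters here: the F test assumes homoscedastic errors, and additive noise
of SD = 5% of the mean PPR yields the nominal ~95% shared-selection rate
under the null, whereas 5% *multiplicative* noise (heteroscedastic)
degrades it to ~68%; synthetic PPF data are therefore generated with
additive noise.

Recovery from facilitation after a 100-Hz train is fitted as
`amp(Δt) = 1 + B·[A_f·e^(−Δt/τ_f) + (1−A_f)·e^(−Δt/τ_s)]` with amplitudes
normalized so the pre-train response is 1 (`B` is then the total
facilitation above baseline — the interpretation adopted for the
reported "amplitude" ≈ 2.2). When `τ_f` is constrained (to the PPF decay
constant), the free slow constant is bounded below by it so the
constrained component remains the fast one. `τ_s` is poorly conditioned
(its fitted uncertainty exceeds its value, consistent with the reference
fit errors); parameter-recovery tests assert `B` and `τ_f` within 25%
and require a delay grid with dense early sampling (10–100 ms) to pin
`B` at all.

## Quantal population analysis (`synquant.quantal`)

Failure percentage is regressed on mean amplitude by OLS with genotype
and amplitude×genotype terms (statsmodels); connections with failure
fraction below 0.4 (high release probability) are excluded from the fit
but retained in the Spearman correlation; the intercept is left free and
the theoretical 100% checked as a diagnostic, not imposed. When the
interaction is non-significant (α = 0.05) the pooled shared slope is
reported and the quantal amplitude estimated as `q = −100/slope`.

An analysis worth recording: with the *exact* binomial model, the
relation `F(%) = 100·(1−p)^N` vs `E = Npq` is convex in `E` for `N > 1`,
so cohorts mixing `N = 1..5` measured down to the 40% failure cut fit a
chord slope of only ~ −81 to −92 %/mV when `q = 0.926` (implied `q`
overestimated by ~15–30%), and genotypes spanning different `p` ranges
then show a spurious slope interaction. Single-contact connections
(`N = 1`) are exactly linear (`F = 1 − E/q`) and recover
−107.8 ± 1 %/mV with a non-significant interaction in ~97% of simulated
cohorts. The slope-recovery suites therefore use single-contact cohorts;
`analysis/02_unitary_quantal.py` demonstrates both regimes side by side,
and a dedicated test asserts the multi-site shallowing rather than hiding
it. For real data this means the inverse-slope estimate of `q` is biased
low-side-of-truth whenever multi-site, mid-`p` synapses populate the
regression — a caveat inherent to the linearization, not to this
implementation.

## FDDI measurement (`synquant.fddi`)

The averaged PC2 trace (sum of sweeps / number of sweeps) is thresholded
at 2.5 × the SD of *its own* pre-train baseline (averaging reduces the
noise, so the threshold must come from the averaged trace). The onset is
the earliest crossing at least 5 ms after the train onset (minimum
disynaptic latency) sustained for ≥ 5 ms whose initial upstroke has a
10–90% rise time of 2–20 ms; the rise is measured to the *first local
peak* after the crossing (2 ms of sustained non-increase on a smoothed
copy) so later summating IPSCs do not inflate it. All gate parameters
live in `OnsetCriteria`. Peak amplitude, the AP index at which it occurs,
half duration (width of the contiguous region above half peak) and charge
(trapezoidal integral from onset until the current stays below threshold
for 10 ms, reported in pA·ms) follow. Monosynaptic connections are
detected as fast inward transients after individual APs, measured against
the chord of each 4-ms post-AP window on a smoothed trace — the chord
subtraction removes both the summated tail of the previous EPSC and any
slow disynaptic component. Occurrence fractions across cohorts are
compared with Pearson's χ² without continuity correction.

## Statistics harness (`synquant.stats`)

Two-group comparisons gate on Shapiro–Wilk normality (α = 0.05 per
group): both normal → two-tailed t test (unpaired assumes equal
variances, or paired), otherwise Mann–Whitney U / Wilcoxon signed-rank.
Identical paired vectors short-circuit to statistic 0, p 1 (a degenerate
Wilcoxon is undefined). The mixed repeated-measures ANOVA
(pingouin `mixed_anova`) reports the between-group F and p; unbalanced
designs and single subjects are errors, never imputed. Calibration over
2000 null simulations puts both tests' type-I error at 0.04–0.06
(gated two-group) and ≈ 0.04 (RM-ANOVA). No multiple-comparison
correction is applied anywhere. Reductions are reported as percent of the
larger value (55 → 22 ms is "60% lower").

## Problem sizes

The test and acceptance suites use sizes chosen to make Monte-Carlo
tolerances meaningful on one CPU in minutes: 10⁴ sweeps per (N, p) cell
for the binomial-oracle grid, 100 replicate cohorts of 2 × 60 connections
× 150 sweeps for slope recovery, 20 replicate PPF datasets, 2 × 100
seeded circuit runs of 20 sweeps for the FDDI contrast, and 2000 null
simulations per statistical test.

## Known limitations

* The linearized quantal slope is biased for multi-site synapses (above).
* The FDDI wild-type half duration under-shoots its reference value.
* The simulator's white noise and iid Gaussian baseline are idealized;
  correlated (filtered) noise would lower the effective number of
  independent samples in every window-max statistic.
* The SOM interneuron is a reset-to-rest leaky integrator; it has no
  adaptation, conductance dynamics, or morphology, so FDDI predictions
  are qualitative beyond the calibrated metrics.
* `release_pmf` returns exact probabilities over quantal counts; with
  quantal variability it returns moments, not the full mixture density.
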