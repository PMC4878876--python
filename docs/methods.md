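# Methods

`cbnephys` analyses whole-cell recordings from large cerebellar-nucleus (CbN)
neurons: voltage-clamp responses to 100-Hz, 200-ms trains of Purkinje-evoked
GABA_A IPSCs at a −40 mV holding potential, and current-clamp spike trains
around a 500-ms inhibitory stimulus.  This note documents the models, the
defaults, what the synthetic generator does and does not emulate, and the
design choices that were genuinely open.

## Sign convention and units

Voltage-clamp current is outward-positive: GABAergic IPSCs at −40 mV are
positive deflections, while mGluR- and TBOA-dependent standing currents are
negative (inward).  Currents are in pA, voltages in mV, time in ms.

## IPSC decay kinetics

The decay phase of an IPSC is fit with a double exponential

    I(t) = baseline + A·[F_f·exp(−t/τ_f) + F_s·exp(−t/τ_s)],

F_f + F_s = 1, τ_f ≤ τ_s, and summarised by the weighted time constant
τ_w = F_f·τ_f + F_s·τ_s (each component scaled by its fractional amplitude
contribution).  Fitting uses bounded nonlinear least squares
(τ ∈ [0.1, 100] ms) with peeling initialization: a log-linear regression on
the last third of the window seeds the slow component; subtracting it and
regressing the early residual seeds the fast one.  The optimizer restarts
from three perturbed seeds before reporting non-convergence.  Fits whose
time constants converge within 5%, or whose minor fraction falls below 0.02,
collapse to a single exponential with F_f = 1.

Two conditioning choices matter in practice:

* **Baseline.**  Over a window much shorter than τ_s, a free baseline is
  nearly collinear with the slow component and weighted-τ estimates blow up
  under realistic noise.  The first IPSC of a train therefore pins the
  baseline to the measured 50-ms pre-stimulus mean, which is the physically
  correct constraint there.  Mid-train IPSCs sit on an unknown residual
  tonic current, so their baseline is fitted freely.
* **Window.**  Within a train the decay window runs from 0.2 ms after the
  detected peak to the next stimulus minus the artifact blank.  The last
  (or an isolated) IPSC has no following stimulus; its window extends up to
  40 ms into the tail, which makes both the slow component and the free
  baseline well conditioned.

On noiseless synthetic data these fits recover the generating parameters to
machine precision; at the generator's default noise (4 pA on a 400-pA IPSC)
the median weighted-τ error is ~1% for the first IPSC.  Last-in-train fits
carry a small (~5%) upward bias because residual slow components of earlier
IPSCs are superposed on the fitted decay — a feature of real train data too,
not an artifact of the implementation.

## Phasic/tonic train decomposition

During 100-Hz trains the current does not decay fully between stimuli, so
the phasic current of each stimulus rides on the accumulated ("tonic")
current.  Per stimulus n (baseline = mean over the 50 ms before the train):

* T_n = I(t_n + 8.4 ms) − baseline, with T_0 = 0.  The 8.4-ms latency is the
  10-ms inter-stimulus interval less stimulus-artifact and IPSC rise time.
  A ±0.2-ms median suppresses single-sample noise at the measurement point.
* peak_n = max over (t_n + artifact blank, t_n + 3.5 ms] − baseline.
* P_n = peak_n − T_{n−1}; percentages are normalised to P_1.

A trace whose P_1 does not exceed five baseline standard deviations is
rejected as unevoked.  The group-level mGluR contribution is the difference
in mean tonic current over stimuli 5–10 between mGluR-antagonist and control
conditions; the difference is reported antagonist-minus-control, so the
tonic outward current unmasked by blocking the mGluR inward component is a
positive number.

Whether the tonic sample should be referenced to the same or the following
stimulus onset is ambiguous in the field's usage; this package measures at
t_n + 8.4 ms and records the choice here.  For uniform 100-Hz trains the two
readings differ only by where within the inter-stimulus interval the sample
falls, which shifts tonic amplitudes by a predictable decay factor (see
"Known limitations").

## Predicted tonic current

Given biexponential fits of the first and last IPSC, the tonic current
expected from GABA_A kinetics alone is predicted recursively:

    D_n = F_fn·e^(−8.4/τ_fn) + F_sn·e^(−8.4/τ_sn)
    T_n = (P_n + T_{n−1})·D_n,    T_0 = 0,

with per-stimulus kinetics interpolated linearly between the first- and
last-IPSC fits to capture the gradual slowing of IPSC decay over the train.
The default interpolation uses fixed weights (1−(n−1)/20, (n−1)/20)
regardless of the train length, reproducing the original computation
faithfully — including the property that stimulus 20 receives weight 0.95
and never exactly reaches the last-IPSC fit.  An `endpoint_exact` mode
(weights (n−1)/(N−1)) is provided for sensitivity analysis.  Two further
faithfulness flags exist: `slow_from_fast_typo` anchors the slow-τ
interpolation at the first *fast* time constant, reproducing a
dimensionally inconsistent variant of the formula verbatim (the default
interpolates τ_s from τ_s, which we consider the intended reading); and
`decay_accumulated=False` decays only P_n, the alternative grouping of the
recursion.  P_n inputs are the phasic components (peak minus preceding
tonic); raw peaks can be passed instead since the function is agnostic.

`exact_superposition_tonic` is an independent oracle that computes
T_n = Σ_{k≤n} P_k·g_k(8.4 + 10·(n−k)) by direct linear superposition.  For
constant single-exponential kinetics with inter-stimulus interval equal to
the latency the recursion is algebraically identical to superposition; for
the physical 10-ms interval the recursion compresses inter-stimulus decay
into the 8.4-ms factor, and the oracle quantifies that approximation
(e.g. three 100-pA pulses with τ = 10 ms: recursion T_3 ≈ 69.85 pA,
superposition ≈ 64.90 pA).  The recursion is implemented as defined, not
"corrected": a comparison of predicted against measured tonic current is
meaningful precisely because the prediction is the standard computation.

An interpretation note: predicted > measured tonic current indicates a
current source not captured by GABA_A kinetics — in CbN cells a tonic
mGluR1/5-dependent inward current that subtracts from the net outward tonic
component.

## Spike metrics

Spikes are detected at upward crossings of dV/dt ≥ 20 mV/ms followed by a
peak ≥ −20 mV within 2 ms, with a 1-ms refractory period; both thresholds
are conventional for high-rate cerebellar neurons and are exposed as
arguments.  The half-width is the duration at half amplitude, amplitude
measured from the dV/dt-threshold voltage to the peak, crossings linearly
interpolated.  The rebound metric compares the firing rate in the 300 ms
after an inhibitory train against the 500 ms before it,
100·(post − pre)/pre; the post window starts at train end (if referenced to
the last stimulus onset instead, values shift by at most the 10-ms final
inter-stimulus interval).  The mGluR-dependent rebound component is the
cell-by-cell paired difference of percent changes, control minus
antagonist.

## Group statistics

The native comparison is the unpaired difference of group means with SEMs
combined in quadrature: μ = μ_A − μ_B, SEM = √(SEM_A² + SEM_B²).  A minus
sign inside this radical appears in some descriptions of the computation;
that form is not a valid variance combination for independent groups (it
can go imaginary) and the quadrature sum is what a bootstrap of the
difference reproduces, so the sum is implemented.  ANOVA families and
post-hoc tests are standard machinery and are delegated to scipy
(`welch_ttest`), not re-derived.

## The synthetic generator

The generator emulates the study conditions so that every analysis stage is
testable with exact ground truth.

**Evoked trains.**  Each IPSC rises as 1 − exp(−t/0.3 ms), normalised to
reach the biexponential decay curve at its peak 0.8 ms after stimulus onset
(after the 0.6-ms artifact blank, within the ~1.5 ms rise budget implied by
the 8.4-ms latency).  Decay amplitude and fractions are referenced at the
peak, so the measured peak equals the generating P_n and a decay fit
recovers the generating kinetics exactly on noiseless data.  Kinetics drift
linearly from first- to last-IPSC values across the train; peaks depress as
P_n = P_1·(d + (1−d)·e^(−(n−1)/k)) with plateau d = 0.55 and rate k = 2
stimuli (an invented, qualitatively calibrated depression model — the
source data are graphical); an optional mGluR-like inward current steps at
each stimulus as amplitude·(1 − e^(−(n−1)/2)) and holds after the train.
Gaussian noise (default 4 pA) is added; a large decaying artifact transient
is confined strictly to the blank window.  Sampling is 50 kHz.

**Spiking traces.**  Spike times follow a gamma-interval renewal process
(shape 10, ISI CV ≈ 0.32, typical of regular CbN firing), each segment
started several mean intervals early so counts are free of start-up
transients.  Rates: baseline before the 500-ms suppression train, 2 Hz
during it, a rebound rate for 300 ms after it, then baseline.  Spikes are
Gaussian templates (45 mV, σ = 0.15 ms) on a −55 mV baseline with 0.5 mV
noise, sampled at 20 kHz.

**Cohorts.**  Four presets encode the sex × genotype groups.  Anchored
values: first/last weighted τ 2.3/4.4 ms (wild-type males), 2.5/3.2
(mutant males), 1.8/2.3 (wild-type females), 1.8/3.1 (mutant females), with
the fast/slow split chosen on a common (τ_f, τ_s) grid so the weighted τ is
exact; spontaneous rates 65/92/98/96 spikes/s; holding currents
−565/−491/−406/−424 pA; TBOA-unmasked mGluR currents −297/−419/−184/−184 pA;
antagonist-sensitive rebound components 7/53/39/25 percentage points.
Chosen-once qualitative calibrations (graphical sources): first-peak
amplitude 400 pA for all groups; evoked mGluR tonic amplitudes 0/−30/−25/−20
pA (wild-type males carry none, mutant males the largest); control rebound
changes 50/90/80/70% on a 40-Hz pre-stimulus rate.  Cell-to-cell
variability is multiplicative lognormal with CV 0.3 (CV/2 for time
constants, scaling each fast/slow pair jointly); positive-only parameters
and heavy-ish tails are typical of ephys cohorts.  The antagonist condition
removes the mGluR tonic component and the mGluR rebound component,
emulating CPCCOEt.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no conductance-based membrane model, no
stochastic vesicle release, no series-resistance or space-clamp errors, no
correlated (1/f or line) noise, no electrode drift, and depression that is
deterministic rather than history-dependent.  Tests against this generator
validate the *analysis*, not biological conclusions.

## Numerical choices and degenerate inputs

* Tonic measurement uses a ±0.2-ms median; peaks use a sample maximum over
  the post-blank window.
* The tonic latency must exceed the artifact blank and be shorter than the
  inter-stimulus interval; measurement points outside the trace raise
  errors rather than clip.
* A perfectly flat trace decomposes to all-zero phasic and tonic currents
  (its noise floor is zero, and the rejection test is strict).
* `predict_tonic` accepts arbitrary positive time constants; τ → ∞ yields
  the cumulative phasic sum, τ → 0 yields zero, and both limits are tested.
* CSV round-trips use 17 significant digits so write-then-read is
  bit-faithful at double precision.

## Problem sizes

Default analyses run a 4-group × 11-cell cohort (the scale of the original
per-group samples) in ~10 s on one core.  Monte-Carlo validations use 200
replicate seeds for fit-error and rebound-bias estimates and 50 cohort
seeds for the predicted-vs-measured group pattern.

## Known limitations

* With the tonic sample at t_n + 8.4 ms and the generator's peak 0.8 ms
  after stimulus onset, the effective own-IPSC decay interval is 7.6 ms
  while the recursion decays by 8.4 ms; on GABA-only synthetic cohorts the
  prediction therefore under-predicts the measured tonic current by ~1.5%
  of P_1 (wild-type-male kinetics).  The injected mGluR components
  (≥ 5% of P_1) dominate this bias, so the group-level
  predicted-vs-measured pattern is robust to it.
* The depression model and evoked mGluR amplitudes are qualitative
  calibrations; only their ordering and rough magnitude are meaningful.
* Half-width estimates depend on the detection threshold through the
  amplitude reference; comparisons should hold the threshold fixed.
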