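# Methods

`lag1` is a moment-by-moment simulation of category learning with eye
movements: a dynamic neural field (DNF) model in which three control systems
— visuospatial processing, saccade timing, and associative learning — are
coupled so that what the model knows changes where it looks, and where it
looks changes what it learns.  This note documents the model equations as
implemented, the fixed constants and how they were chosen, what the
simulated experiments do and do not emulate, and the numerical decisions a
user should know about.

## Field and node dynamics

Every field and neuron obeys the Amari relaxation form

    tau du/dt = -u + h + s(t) + [k * f(u)] - w_inh * sum f(u) + q xi(t)

with a logistic output `f(u) = 1 / (1 + exp(-beta (u - theta)))`, a Gaussian
excitatory kernel `k(d) = A exp(-d^2 / 2 sigma^2)`, uniform global
inhibition, and additive white noise with Euler–Maruyama scaling
(`q sqrt(dt)` per step).  Discrete neurons drop the lateral term.  The
original LAG-1 implementation's exact closed-form equations are not
publicly archived, so the forms here are this package's own standard-DNF
constructions, chosen to reproduce every described behaviour of the
architecture; all scaling constants were calibrated from scratch (see
"Calibration" below).

Integration is explicit Euler at `dt = 10 ms`.  Gaze is sampled every step,
approximating a 120 Hz eye tracker.  Halving `dt` changes trajectories at
O(dt), which the test suite checks; nothing in the model depends on
integrating more finely than the 10 ms grid.

A practical note on kernels: a 2-D Gaussian kernel of width `sigma` carries
mass `A 2 pi sigma^2`, so seemingly small amplitudes recruit large
neighbourhood excitation.  The attention and motor fields run in an
input-driven "sharpening" regime (effective recruitment ~3 units); truly
self-sustaining bumps need a steeper sigmoid and stronger kernel (e.g.
`beta = 4`, `A = 0.6` at `sigma = 2`), a regime exercised by the tests but
not used by the task fields, whose persistence instead lives in the discrete
detector neurons.

## Visuospatial processing

The **Visual Field** is retinotopic: stimulus input arrives as a stack of
per-feature-value layers, each a Gaussian blob (width 2.5 units) at the
feature's retinotopic position, scaled by a foveal acuity factor

    a(e) = floor + (1 - floor) exp(-e^2 / 2 (k sigma_f)^2)

of eccentricity `e` (`sigma_f = 5`, `k = 3`, `floor = 0.5`).  The floor
models coarse peripheral localisation: far features remain visible as
locations while their values are unreadable — value readout uses the much
narrower foveal mask (width `sigma_f`), so only the fixated feature drives
its detector.  Saccades translate the Visual Field by the saccade vector;
cells shifted in from outside start at rest.

The **Spatial Attention Field** is spatiotopic and receives (i) the
spatially remapped Visual Field output, (ii) expectation-driven boosts at
feature locations (top-down spatial priority), and (iii) a foveal boost from
the Fixation Neuron.  The **Saccade Motor Field** receives the attention
output minus a strong Gaussian inhibition centred on the current gaze
position (width 7, amplitude 14), making it a map of *candidate* targets:
the currently fixated location cannot win.  Saccade targets are the motor
argmax (greedy; ties break to the lowest row-major index) or, for free
viewing, a sample proportional to the sigmoided motor output.

Top-down expectation reenters at two places: multiplicative per-value-layer
gains on the Visual Field input (feature-based attention) and additive
location boosts on the attention field (spatial attention).  Visual search
uses only the first path, since item locations are unknown to the searcher.

## Saccade timing

Three neurons time each fixation.  The Gaze Change Neuron `u_g` integrates a
geometric urgency signal `g(t)`, reset to `g_0 = 0.72` at every fixation
onset and compounded continuously as `g *= lambda_P2^(dt / 100 ms)`.
`lambda_P2` is the **Fixation Impatience** free parameter (1.5–1.9).  The
Fixation Neuron `u_x` integrates the total foveal drive and suppresses
saccades while a feature is being inspected.  The Saccade Initiation Neuron
integrates

    12 f(u_g) - 6 f(u_x) + 7 f(max motor field)

and a saccade fires when it crosses zero, taking 30 ms, during which samples
are flagged and excluded from fixation detection.  Two things follow from
this wiring.  First, fixation durations fall with `lambda_P2` (the urgency
accumulator crosses sooner).  Second, once learning sharpens the motor peak
at the next target, the third term shifts the race and saccades fire tens of
milliseconds earlier — the mechanism behind the learned decline in fixation
durations, which reaches ~30–60 ms at the high impatience and learning-rate
levels.

The 100 ms compounding tick is a fixed model constant.  With the printed
impatience factors (1.5–2.05) a per-integration-step compounding would cross
threshold within a few steps and, because geometric growth compresses input
differences logarithmically, would leave saccade initiation insensitive to
learned priority; the 100 ms (fixation) and 400 ms (trial) ticks put the
accumulators in the 300–500 ms / 3–4 s regimes the behaviour requires.

## Learning system

Each feature slot has two value detectors with strong self-excitation
(working memory: ~300 ms of foveal drive sustains output above 0.5 for >5 s),
within-pair inhibition, and weak global inhibition.  Category neurons
receive detector output through the bounded association matrix `W` (K × 2L,
entries in [0, 1], initialised at 0.5 ± U(0.05)), compete by global
inhibition, and are self-sustaining once strongly excited.  The same `W`
carries activation backwards from categories to feature-expectation
neurons, which are inhibited by already-active detectors — so expectations
rank *unseen* diagnostic features highest, producing ordered within-trial
sampling.

Both directions are modulated by a diagnosticity gain: for category `i` and
location `l` with paired weights `W_a, W_b`,

    d(i, l) = |W_a - W_b|,   gain = 1 + kappa d   (kappa = 1.2).

A location whose two values connect equally to a category tells you nothing
about it; a large contrast marks it as informative.  This single quantity is
the bridge from associative learning to attentional priority.

During every feedback timestep three learning terms apply, at rate
`r = learning_rate * 4` per ms (the free **Learning Rate** is quoted on the
2.5e-6–1.65e-5 scale; the ×4 is a fixed internal scaling constant):

1. Hebbian: `dW(correct, j) += r dt fd_j (1 - W)` — gated on the correct
   category being above threshold, which normally requires fixating the
   feedback button (its foveation boosts the correct category neuron).
   Credit is linear in co-activation time: 800 ms of viewing earns 4× the
   pre-bound increment of 200 ms.
2. Homeostatic: all weights decay by the mean Hebbian increment.
3. Anti-Hebbian (wrong answers only): `dW(chosen, j) -= r dt fd_j W`.

The soft bounds `(1 - W)` and `W` give asymptotes at 1 and 0.

The Click Decision Neuron integrates the maximum category output (weight
8.5), its own geometric urgency (**Trial Impatience**, 1.6–2.05, 400 ms
tick), and a feedback-on-screen signal.  Crossing the first threshold emits
the category response — sampled by the Luce rule over sigmoided category
outputs — and starts the feedback phase (urgency restarts); crossing the
second ends the trial.  With saturated category knowledge the second
threshold falls within a few hundred milliseconds of the first: the
feedback-skipping "double-click".

## Simulated experiments

Two experiments are built in.  The 4-category structure (8 stimuli, 3 binary
features; Feature 1 separates the A from the B pair, Feature 2 splits A1/A2
and is irrelevant for B, Feature 3 the reverse) runs 360 self-paced trials;
its signature phenomenon is stimulus-specific attention.  The 5/4 structure
(9 training stimuli over 4 binary features, 2 categories; Feature 1 low,
Feature 2 medium, Features 3–4 high diagnosticity) trains until 189 trials
or 18 correct in a row, then tests all 16 stimuli twice without feedback.
Trial sequencing is block-randomised (one shuffled pass through the training
set per block).  Per-subject counterbalancing permutes feature-to-location
assignment and value identities.

Each trial: gaze resets to centre (the fixation cross), the stimulus
appears, the model saccades among features until the first click threshold,
responds, then views stimulus plus a peripheral correct-answer button while
learning runs, until the second threshold.  Transfer trials skip feedback
and learning.  A 30 s guard truncates runaway trials (never observed at the
shipped constants).

Raw output is a per-trial table plus a gaze stream `(t, x, y, phase,
in_saccade)`; the analysis pipeline — dispersion-based (I-DT) fixation
detection (threshold 5 units = the foveal width, minimum duration 60 ms;
saccade samples and phase boundaries break windows), nearest-AOI labelling
(radius = half the minimum inter-feature distance), binned trial measures,
within-trial probability timelines (each trial resampled to 100 points, five
bins, off-AOI samples excluded so feature probabilities sum to one) — is the
same code one would run on human eye-tracking exports in this format.

What the simulations do **not** emulate: pictorial stimulus content (features
are colour-patch abstractions), eye-tracker noise, dropout and blink
artefacts, human strategy shifts (rule testing, feature neglect — the model
fixates nearly all features early, more than humans do), smooth pursuit or
microsaccades, and manual (mouse-driven) information access.  Passing tests
therefore certify the model's internal behavioural dynamics and the analysis
pipeline, not fidelity to any individual human record.

## Fitting

A subject is summarised by a target vector — 8 elements for the 4-category
task (OLS intercept and slope over 15-trial bins for accuracy, fixation
count, P(fixate irrelevant), fixation duration), 19 for the 5/4 task (16
transfer proportions, learning point, first/last-block mean per-feature
fixation counts).  The objective is a weighted sum of squared
per-component-scaled differences; default scales equalise component
magnitudes (the original per-component weights are not published, so weights
are caller-configurable).  The search evaluates a deterministic Halton
sequence over the three free parameters (bounds = the printed low/high
levels), each point averaged over a configurable number of seeds and cached
on disk keyed by (parameters, structure, seed).  Nested candidate sets make
the best objective monotone in budget.

## Calibration

All fixed constants were set once, in a single calibration pass at the
median free-parameter levels (Learning Rate 1.1e-5, Fixation Impatience 1.7,
Trial Impatience 1.8), against the published behavioural anchors: ~3
saccades/s at no knowledge, first-bin reaction times in the 3–5 s band,
first-bin fixation counts near 7 declining to 3–4, early fixation durations
above 300 ms, a ≥30 ms learned duration decline at high impatience, chance
accuracy at 25% (four categories), and an ending high-minus-low
diagnosticity fixation-count spread near 0.3 in the 5/4 task (measured over
the experiment's closing transfer block, where attention is purely
expectation-driven).  Free parameters were never adjusted to data after
calibration; they remain the three subject-level knobs.

## Numerical and design decisions

- Euler at `dt = 10 ms`; all stochastic terms draw from one seeded
  generator per experiment, making whole datasets bit-reproducible.
- Fixation-duration quantisation: durations are multiples of `dt`; measured
  means therefore carry ±5 ms grid noise.
- Ties: greedy target selection and AOI assignment break ties to the lowest
  index; these are documented contracts, not incidental.
- Inter-trial reset: all neuron banks, fields, and both urgency accumulators
  reset between trials; only `W` persists.  Within a trial, detector working
  memory carries feature values across fixations.
- Saccade execution is instantaneous with a 30 ms flagged interval; no
  ballistic trajectory is modelled, and the initiation neuron resets fully.
- The Hebbian gate ("correct category above threshold") is satisfied by
  feedback-button viewing, or by the model already holding the correct
  category active on a double-click trial; a feedback phase with neither
  leaves `W` unchanged.
- Degenerate inputs: an all-rest motor field still returns an argmax
  (noise decides where rest-state saccades land); empty gaze streams yield
  empty fixation tables; transfer stimuli without training labels carry NaN
  accuracy.
- Visual search runs detectors and categories in a transient regime
  (self-excitation 2): classification must track the currently fixated item,
  and a fixated distractor match must not press the response button — only
  target evidence and trial impatience can end a search trial.
- The acceptance script scales the 5/4 replication to 6 seeds; all other
  problem sizes match the source protocols (360 trials; 189-trial cap).

## Known limitations

- Feature neglect is absent: early in learning the model inspects nearly
  every feature, so its P(fixate irrelevant) starts near 1, above human
  values — the corresponding published fits show the same bias.
- Accuracy plateaus near 0.7–0.9 depending on seed, with visible
  non-monotonic churn late in training: once most weights saturate, the
  interplay of Hebbian, homeostatic, and anti-Hebbian terms keeps the
  matrix wandering, and per-seed attention allocation becomes
  idiosyncratic.  The linear associator also cannot fully separate the 5/4
  structure (nor can humans, typically ~0.8).
- In the 5/4 task the model reliably over-attends the two high-diagnosticity
  features, but it does not separate the medium- from the low-diagnosticity
  feature: the medium feature often receives the least attention, so the
  full high > medium > low ordering of the transfer-phase fixation
  proportions holds only on its high-versus-rest leg.  The corresponding
  acceptance test is left failing deliberately.
- Between-subject variability is underdispersed relative to humans; noise
  amplitudes were kept small for targeting reliability.
- Only linearly separable (prototype-plus-exception) association is
  possible; there is no rule module and no reward-modulated plasticity.
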