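# Methods

## Problem setting

Patients with COPD on long-term oxygen therapy need different oxygen flows
at different physical-activity intensities, but with a conventional
portable oxygen concentrator (POC) they must adjust the pulse setting by
hand — and mostly do not. `oxiflow` models the software stack of an
"intelligent" POC that closes this loop without touching oximetry: a
chest-worn IMU classifies each 3-s window into sedentary / light /
moderate intensity, a safety finite-state machine rate-limits intensity
changes, and a physician-chosen lookup table maps the delivered intensity
level to a pulse setting.

## Signal chain

**Sampling and windowing.** Six channels (3-axis accelerometer in g,
3-axis gyroscope in deg/s) at 25 Hz, cut into non-overlapping 3-s windows
(75 samples). Mixed-activity windows take the majority activity's
intensity; ties break toward the *lower* intensity, a deliberately
conservative choice for dosing on ambiguous windows. Trailing partial
windows are dropped.

**DC removal.** Gravity and slow drift are removed by subtracting a
first-order low-pass IIR (y[n] = αx[n] + (1−α)y[n−1], α = Δt/(RC+Δt),
RC = 1/(2π·0.15 Hz)) from the raw signal — the minimal filter a
microcontroller would run. The filter state is initialised to the first
sample to suppress the startup transient, and the continuous trace is
filtered once before windowing so window boundaries carry no filter
transients. Note the discrete one-pole deviates from the continuous-time
gain r/√(1+r²) at passband edge: at 2 Hz the exact discrete gain is
≈0.976 rather than ≈0.997. Tests assert the exact discrete closed form.

**Features.** 98 time-domain features per window (see
`oxiflow.features`): per-channel RMS / SD / absolute mean, derivative
mean, simplified energy, skewness / kurtosis / median, min / max / range,
IQR; within-sensor pairwise Pearson correlations; signal-magnitude-vector
statistics and signal magnitude area per sensor. Conventions that the
source material leaves open, fixed here and enforced against a naive
loop-based oracle:

* *Simplified energy* = mean of squares (no FFT; "simplified" read as
  avoiding spectral computation).
* The six correlations are the within-sensor pairs (3 accelerometer +
  3 gyroscope); cross-sensor pairs would give 15 candidates.
* Skewness is bias-uncorrected g₁; kurtosis is non-excess Pearson
  m₄/m₂²; SD uses n−1; IQR uses linear interpolation.
* The derivative mean is scaled by the sampling rate (units/s).
* Zero-variance channels define correlation, skewness and kurtosis as 0
  so constant (noise-free) postures stay finite.

## Feature selection

Wrapper selection by best-first forward search: subsets are scored by the
stratified 5-fold CV accuracy of the wrapped node classifier itself (fold
assignment fixed by a seed, so the search is deterministic); the open list
ranks all evaluated-but-unexpanded subsets so the search can backtrack;
the search stops after 5 consecutive non-improving expansions (an absolute
improvement below 1e-5 counts as no improvement, to avoid float-noise
loops). Equal-scoring subsets tie-break toward the smaller subset, then
lexicographic indices. When the incumbent reaches CV accuracy 1.0 the
search stops immediately, since no subset can improve on it.

## Classifiers

The hierarchy has two internal nodes: ϕ₁ (sedentary vs active) consulted
first, ϕ₂ (light vs moderate) only on active predictions, each with its
own wrapper-selected feature subset (ψ₁, ψ₂). Defaults are a decision
tree for ϕ₁ and LDA for ϕ₂ — the pairing that best trades accuracy
against microcontroller cost. ϕ₂ trains only on light/moderate instances,
with instance weights w_i = N/(K·n_class) equalising the per-class weight
sums (light activity heavily outnumbers stair climbing).

* **Tree**: univariate threshold splits chosen by gain ratio among splits
  with at least average information gain (the C4.5 heuristic that stops
  gain ratio favouring degenerate splits), minimum leaf weight 2,
  pessimistic-error pruning with confidence factor 0.25. Scores are
  Laplace-smoothed leaf frequencies, so ROC thresholds exist.
* **LDA**: weighted class means, pooled weighted covariance, weighted
  priors; a ridge of 1e-6·trace/d is added (and logged) only if inversion
  fails. Scores are posterior probabilities.
* **Logistic**: weighted IRLS with an L2 stabiliser of 1e-6.

SVM / RBF / MLP nodes are not implemented; the node contract
(`train_node` / `predict_node`) accepts plug-ins should they be needed.

## Evaluation

Leave-one-subject-out CV: each fold holds out *all* windows of one
subject and re-runs selection and training from scratch on the rest, so
nothing about the held-out subject leaks into model or subset choice.
Pooled predictions give per-class one-vs-rest confusion matrices (all
sharing one total), precision / recall / specificity / accuracy / F1 and
G = √(Se·Sp); reported percentages round half-up to one decimal to match
how such tables are printed. ROC curves are computed per internal node
(where graded binary scores exist) — no multiclass ROC aggregation is
attempted; the trapezoid AUC equals the Mann–Whitney pair statistic with
ties counted ½, which the tests verify exhaustively.

## Flow control

The Mealy FSM moves the delivered intensity at most one level per window
toward the observed class, so a sedentary→moderate misclassification (or
real transition) passes through the light setting; convergence to any
sustained class takes at most 2 windows. An optional debounce parameter
requires k consecutive identical observations before moving (default
k = 1). The therapy lookup table holds the seven personalisation rows
(sedentary/light/moderate → pulse setting 0–5, non-decreasing).

Pulse dosing at reference conditions (20 °C, sea level): 180 mL/min per
setting level split evenly across breaths, bolus = 180·setting/bpm mL
(12 mL per level at 15 bpm; 900 mL/min at the maximum setting). No
environmental correction is applied.

SpO₂ summaries are reporting utilities only (the controller never uses
oximetry as a process variable): CTxx = percentage of samples below xx%;
a desaturation event is a maximal episode below 90% lasting ≥ 10 s, with
episodes separated by < 10 s of recovery merged — the event rule is
configurable because no standard definition exists at this granularity.

## Synthetic cohorts

No patient recordings are available, so `oxiflow.synthetic_data`
generates labelled cohorts that emulate the study conditions: 18 subjects
by default, each performing 3 min seated rest, a 12-min circuit of six
120-s laps (45 s walk, 9 s stairs up, 39 s walk, 9 s stairs down, 18 s
walk), and 3 min seated rest; seated stops of 20–40 s are inserted after
a lap with probability 0.3. This yields per-subject window counts
(~120 sedentary, ~200 light, ~35 moderate) in the same proportions as the
study's 2160/3115/550 instances.

The signal model is gravity + two gait harmonics + white noise: upright
postures put gravity on −Y (chest unit, Y toward head, Z along walking
direction; −X when lying, with small per-posture tilts); walking adds a
dominant harmonic at the subject's cadence and a weaker one at twice the
cadence on Y/Z plus per-step gyro oscillation; stairs scale the walking
amplitudes by a per-subject factor, slow the cadence by 0.8, and add a
slow (0.2 Hz) torso-pitch modulation on the pitch gyro (sign flipping for
descent). Per-subject parameters are drawn once per cohort seed: cadence
1.4–2.2 Hz, walking amplitude 0.28–0.42 g, stair amplification 1.5–1.9,
gyro amplitude 25–60 deg/s, noise 0.02–0.05 g / 0.8–2.0 deg/s. The
amplitude and noise ranges are design choices (no published amplitude
statistics exist to calibrate against), picked for biomechanical
plausibility: stair climbing roughly 1.5–2× the vertical oscillation of
level walking, and slower.

What the generator does *not* emulate: biomechanically realistic gait
(asymmetry, turning, double support), sensor drift and saturation,
inter-day variability, or any coupling between activity and SpO₂. A
passing pipeline test therefore shows that the chain recovers the class
structure the generator encodes — it says nothing about accuracy on real
patients, whose stair/walk separation is far harder (published results
show exactly that weakness at the light/moderate boundary).

## Problem sizes and numerics

The end-to-end pipeline test runs LOSO over the default 18-subject cohort
(~6 500 windows, ~6 200 training windows per fold) with wrapper selection
re-run in all 18 folds; on one CPU this takes ~10 minutes, dominated by
tree-wrapped subset evaluations. Smaller structural tests use a
compressed circuit (30 s + 120 s + 30 s). Determinism: every stochastic
step (cohort draws, CV folds) derives from explicit integer seeds;
per-subject seeds come from `SeedSequence([cohort_seed, index])` so
cohorts are reproducible subject by subject. Degenerate inputs
(zero-variance features, single-class folds, 0/0 metric divisions) are
defined conventionally rather than raised, and logged where they signal a
modelling problem.

## Known limitations

* Generator separability is a modelling choice; headline patient-level
  accuracies cannot be reproduced without the original recordings.
* The FSM transition diagram is a declared interpretation (one level per
  window toward the observation); the deployed device's exact state table
  and any debounce constants are not recoverable from the source text.
* Only tree / LDA / logistic nodes are built-in.
* The bolus model is the reference-condition lookup; altitude and
  temperature effects are out of scope.
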