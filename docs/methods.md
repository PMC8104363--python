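# Methods

## Problem setting

Sleep staging assigns each fixed-length epoch of a night's EEG one of five
AASM stages (W, N1, N2, N3, REM). The staging pipeline here has three parts:
preprocessing of the raw signal, multiscale wavelet sub-band features, and a
linear transfer SVM that adapts a classifier trained on a well-labeled
*source* cohort to a *target* recording with few scored epochs. Because
clinical polysomnography (SHHS/NSRR) is access-restricted, the package also
defines a synthetic generator that serves as the test bed for every stage of
the pipeline; real EDF recordings can be substituted wherever the generator
is used.

## Synthetic polysomnography

**Hypnogram.** A night is modeled as `n_cycles` sleep cycles (default 5,
within the normal 4–6 range), each visiting stages in the order
W → N1 → N2 → N3 → N2 → REM. Total per-stage epoch counts are one
multinomial draw at the requested proportions — defaults 5% N1, 20% N2,
50% N3, 25% REM, the textbook normal-adult sleep-time composition — then
spread as evenly as possible over cycles (remainders to the earliest
cycles; each cycle's N2 share split between its descending and re-ascending
block). The multinomial draw makes realized fractions converge to the
request (sd ≈ 0.5 percentage points at 10,000 epochs) while keeping every
output reachable from a single integer seed. A Markov-chain hypnogram was
considered and rejected: the cycle-skeleton construction guarantees the
stage order by construction and leaves the marginal proportions exactly
controllable.

**EEG.** Each stage is a sum of narrow-band sinusoids on white Gaussian
noise: alpha 9–11 Hz (30 μV) in W, theta 5–7 Hz (40 μV) in N1, sigma
12–14 Hz (35 μV) over a theta background in N2 — plus amplitude-modulated
12–14 Hz spindle bursts (0.5–2 s, Hann envelope, 90% of epochs) — and
0.75–3 Hz delta at 75 μV in N3. REM has no distinctive single-channel EEG
rhythm; it is synthesized as low-amplitude (25 μV) mixed theta, a stand-in
choice and not a physiological claim. Per-epoch log-normal gains
(`amplitude_cv = 0.5`, unit mean; one gain for the rhythms, an independent
one for the noise floor) model the waxing and waning of rhythm amplitude
across epochs of one stage; without them the stage clusters in feature
space are separated by many standard deviations and every classifier is at
ceiling, which would make classifier comparisons vacuous. Background noise
sds (25–35 μV) are of the same order as the rhythm amplitudes, as in real
scalp EEG.

**What the generator does not emulate:** 1/f background spectra,
K-complexes and vertex waves, EOG/EMG channels, inter-subject variability
beyond the explicit domain shift, stage-transition ambiguity. Passing tests
on this generator therefore demonstrate the pipeline's mechanics (band
separation, transfer behavior, protocol correctness), not clinical-grade
staging accuracy.

**Domain shift.** A source/target pair differs by an amplitude rescaling of
all rhythms and noise (`amplitude_scale`), independent additive noise
(`extra_noise_sd`, μV) and an upward shift of every rhythm band
(`frequency_jitter`, Hz). The identity shift leaves the generator
untouched, and matched seeds make the amplitude shift an exact sample-wise
proportionality — both properties are load-bearing in the tests. The
benchmark shift (×1.5 amplitude, +10 μV noise) is a moderate cross-cohort
discrepancy: large enough that a source classifier degrades without
adaptation, small enough that transfer remains sensible.

## Preprocessing

Zero-phase FIR band-pass, default 0.3–35 Hz: the low edge removes baseline
drift and DC, the high edge removes high-frequency noise while keeping
every band used by the features. Taps are `3.3·fs/width` (width = the
high-pass edge), applied forward-backward, so the passband gain is ~1 and
features are not shifted in time; an optional 50/60 Hz mains notch uses a
zero-phase IIR notch (Q = 30), since an FIR notch that narrow would need
impractically many taps at 125 Hz. Epochs whose peak amplitude exceeds
±250 μV (default) are rejected outright and their indices reported —
whether to reject or correct artifacts is an open choice; rejection with an
audit trail is the conservative one.

## Features

4-level db4 DWT with **periodized extension**, so level-k coefficient
counts are exactly `L/2^k` and coefficient energy equals signal energy
(Parseval), which the tests exploit. A 25-s epoch at 125 Hz is 3125
samples, not divisible by 16; epochs are **zero-padded to 3136** before the
transform (truncation to 3120 available). Per band (A4, D4, D3, D2) the
mean and **population** standard deviation (divide by n) of the absolute
coefficients are computed; D1 is discarded as carrying no EEG content below
the 35 Hz low-pass. The 80/140/200-s timescales are centered sliding-window
means over 3/6/8 epochs (windows rounded from the non-integer ratios
80/25, 140/25, 200/25), truncated at recording edges; they *augment* rather
than replace the base features, giving 32 features per epoch ordered
`(A4, D4, D3, D2) × (mean, sd) × (25, 80, 140, 200 s)`. Whether the longer
timescales replace or augment the base scale was ambiguous; augmenting is
the information-preserving reading and is configurable.

## Transfer SVM

Objective, dual and weight recovery as in the README. Numerical choices:

* **Solver.** SMO-style maximal-violating-pair working-set method on the
  dual Gram matrix; training sets here are tens of epochs, so the O(n²)
  memory is irrelevant. Stopping rule: maximal KKT violation ≤ 1e-10
  (`qp_tolerance`); the gradient is recomputed from scratch every 4096
  updates to shed round-off. The dual objective is reported *including* the
  constant `−μ‖w_s‖²/(2μ+1)`, so the printed minimum is exactly the
  negative of the optimal primal value (used by the strong-duality test).
* **Bias.** Averaged over *all* margin support vectors (β in the open box,
  interior margin `ε = 1e-6·C_t`) rather than one arbitrary component —
  identical in exact arithmetic, more stable in floating point. If no
  multiplier is interior (e.g. very large μ driving all β to a bound), the
  bias falls back to the midpoint between the closest opposing projections
  onto `w_t`, with a warning.
* **Ties.** A point exactly on the hyperplane is classified +1; the
  one-vs-rest argmax breaks ties toward the canonical stage order
  (W, N1, N2, N3, REM); μ-grid ties break toward the smaller μ (weaker
  transfer).
* **Standardization.** Features are z-scored with source-domain statistics
  applied to both domains — without a shared affine frame, transferring
  `w_s` is meaningless.
* **Linear kernel only.** The transfer term couples `w_s` with the data in
  input space; a kernelized counterpart is not well-defined for this
  formulation and is deliberately not guessed at.
* **Degenerate inputs.** Single-class training data is an error; empty
  validation halves during μ selection fall back to the smallest grid
  value.

A note on dual identifiability: when the number of training points far
exceeds the feature dimension, the optimal multipliers can lie on a face of
the feasible polytope that is flat to below float64 resolution (the primal
weights remain unique). Solver-vs-oracle comparisons of β are therefore run
on instances with dimension comparable to the sample count; objective
values agree regardless.

## Experiment protocol

Recordings are split into training and held-out sets **by recording, never
by epoch**, to avoid within-recording leakage. The pooled training
recordings fit the standardizer and per-class source SVMs (one-vs-rest,
μ = 0). On each held-out recording, up to `n_labeled_per_class = 10` epochs
per stage (always leaving at least one epoch for evaluation) are treated as
scored; the shared transfer weight μ is selected on a stratified held-out
half of those labels and the final model refit on all of them; remaining
epochs are scored. Metrics follow the standard one-vs-rest ratios
TPR = TP/(TP+FN), TNR = TN/(TN+FP), precision = TP/(TP+FP), reported per
class (pooled over test recordings and per recording) plus macro means. A
zero denominator yields an *undefined* metric, reported as null and
excluded from macro averages — never silently 0 or 1. Since the positive
class of a single summary number is inherently ambiguous in a five-class
problem, the per-class table subsumes any binary choice.

Problem sizes used by the shipped experiments and tests — source recordings
of 150 epochs, targets of 120 epochs, 30-seed benchmarks, 10,000-epoch
hypnograms for proportion checks — were chosen as the smallest sizes at
which the compared quantities are stable, and are parameters everywhere.

## Known limitations

* The synthetic REM signature is a stand-in; REM vs N1 separation rests on
  amplitude statistics only.
* The bias fallback can place the hyperplane suboptimally on degenerate
  one-vs-rest subproblems with very few positives (it is logged).
* Preliminary-stage smoothing/correction of the predicted hypnogram is out
  of scope; predictions are per-epoch.
* The EDF writer covers the plain 16-bit EDF subset used here (1-s records,
  integer sampling rates, no EDF+ annotations).
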