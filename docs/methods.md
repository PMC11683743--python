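# Methods

`patchsleep` reconstructs, end to end, a sleep–wake classification pipeline
for a duty-cycled torso patch that records tri-axial acceleration (ACC) and
single-lead ECG in 14-second blocks within every 20-second interval, with
polysomnography (PSG) as ground truth. Because the clinical recordings such a
device produces are not publicly available, the package pairs the pipeline
with a synthetic cohort generator whose defaults emulate the documented
regime of such a study: 60 participants (35 with a serious mental illness
diagnosis, 25 healthy volunteers), overnight lab sessions, roughly 73% of
ECG and 98% of ACC blocks usable, and about 84% of analysis windows labeled
sleep.

## Synthetic cohort generator

**Hypnogram.** Sleep structure is a first-order Markov chain over the five
PSG stages {W, N1, N2, N3, R} at 30-s epoch resolution, started in wake.
This is the simplest generator with controllable stage dwell times. The
default transition matrix was hand-tuned once so that, with the 5-of-10
majority rule below, ~84% of 5-minute windows are labeled sleep (the
aggregate over 20 nights falls in [0.78, 0.88]) and nights show a realistic
onset latency and brief awakenings. Stationary stage fractions of the
default matrix: W 0.14, N1 0.04, N2 0.40, N3 0.25, R 0.17.

**ACC stream.** Blocks start at t = 0, 20, 40, … s and hold 14 s of samples
at 32 Hz (typical patch hardware; configurable). The signal is a
piecewise-constant gravity orientation (posture), with shift events drawn
from a Poisson process at 2/h, plus movement bursts: 2-s oscillations at the
step cadence (1.8 Hz, 0.25 g) along the gravity axis, at 3/min during wake
versus 0.15/min during sleep, plus white noise (0.02 g). Two percent of ACC
blocks are dropped at random, emulating occasional transmission loss.

**ECG stream.** Each block carries a train of Gaussian-shaped R-peaks
(σ = 12 ms, 1 mV) at 256 Hz whose R-R interval is drawn around
60/HR for the current binary state (wake 72 bpm, sleep 58 bpm, between-block
SD 3 bpm, 2% within-block jitter). A two-state contact-quality chain runs at
block resolution (stay-good 0.97, bad→good 0.09; stationary good ≈ 0.75) and
switches the additive noise between 0.03 mV (clean) and 0.6 mV (degraded);
degraded blocks are intended to fail the downstream quality gate, which
reproduces the ~73% ECG usability regime. No full PQRST morphology is
simulated — the R-peak train is sufficient to exercise the detector.

**Seeding.** One master seed; per-(participant, night, stream) sub-seeds are
derived through `numpy.random.SeedSequence(entropy=seed, spawn_key=...)`, so
any single night can be regenerated bit-for-bit in isolation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real QRS morphology and arrhythmias, apnea or
periodic limb movement phenotypes, gradual electrode drying (contact quality
is a clean two-state switch), non-stationary HR trends within a stage, and
scorer disagreement in the PSG labels. Recovery results on this cohort
demonstrate that the pipeline's machinery is correct and well-posed, not
that it attains any particular accuracy on clinical recordings.

## Preprocessing

ECG blocks pass through a zero-phase 0.5–40 Hz band-pass plus a 60 Hz notch
(Q = 30); cutoffs follow common wearable practice. R-peaks are detected
Pan–Tompkins style: 5–18 Hz QRS emphasis, derivative, squaring, 150-ms
moving-window integration, a threshold at 25% of the window maximum, and a
0.25-s refractory rule, with each candidate refined to the local maximum of
the band-limited signal.

Block validity has two gates:

- **Quality**: median R-peak prominence divided by the raw-signal MAD must
  reach 8. The statistic has a scale-invariant noise-only floor — the
  extremes of band-passed Gaussian noise sit roughly 4 MADs above baseline,
  so a noise-dominated block scores ~3.5–4.5 regardless of amplitude, while
  clean contact scores in the tens. The default of 8 sits between the two
  modes; it is configurable.
- **Plausibility**: mean HR (60 / mean R-R) must lie in the closed interval
  [30, 200] bpm; exactly 30 or 200 is retained. Blocks with fewer than two
  peaks fail both gates.

ACC features per block: step count (peaks of the 0.5–5 Hz band-passed
acceleration magnitude above 0.1 g, at spacings of 0.25–2 s, isolated spikes
discarded), body angle (angle between the low-passed gravity vector and the
device z axis — recumbency for a torso patch; a vanishing gravity vector is
flagged and reported as 0°), and per-axis means. Per-axis SDs and magnitude
mean/SD are computed for the optional extended catalog.

## Windowing

Windows are anchored at PSG epoch 0 and tile the night in 300-s steps; a
trailing window with fewer than ten epochs is dropped. Stages collapse to
binary (W → wake; N1, N2, N3, R → sleep) and a window is **wake iff at least
five of its ten epochs are wake**. Within a window the first ACC block of
each minute is kept (≤ 5) and the first valid ECG block is kept (≤ 1);
validity requires ≥ 3 ACC blocks and an ECG block. A night is usable iff it
has ≥ 60 minutes of valid windows (inclusive at exactly 60). Windows are
anchored to recording start, consistent with defining sleep-onset latency
from the start of measurement.

## Features

Base catalog (15): total step count; mean, sample SD (n−1) and range of the
blockwise body angle and per-axis means; window mean HR; and the HR z-score
against the participant's own HR mean/SD. The extended catalog (30) adds the
same aggregations of within-block SDs and magnitude statistics behind a
config switch; the catalog composition is recorded in run metadata. HR
statistics are computed over the kept ECG blocks of all of a participant's
usable nights — a deliberate, documented leakage-by-design that mirrors
per-participant normalization in deployment, where a person's own baseline
is always available. Participants with fewer than two such blocks (or zero
spread) are excluded with a log message.

Difference features add f(w) − f(w−k) for lags k = 1…5 per night, with 0
substituted when the earlier window is missing (equivalent to assuming it
held the current value). They are generated for whatever base subset enters
the model — after selection when selection is enabled.

## Models

All back-ends standardize features with training-set statistics and emit
per-window P(sleep); labels follow from P(sleep) ≥ τ.

- **GBM** (LightGBM, 200 trees, learning rate 0.05, 31 leaves,
  deterministic, single-threaded): window-independent; temporal context
  enters only through the lag differences.
- **CRF**: binary linear-chain model with real-valued node features plus
  intercept and a 2×2 transition matrix, trained by L2-penalized maximum
  conditional likelihood (L-BFGS, penalty 1.0/n); marginals via log-space
  forward–backward, verified against exhaustive sequence enumeration to
  1e-8. Nights split into separate chains wherever more than one
  consecutive window is missing.
- **LSTM**: one recurrent layer (32 units) with a shared sigmoid readout,
  written directly in numpy; full-batch backpropagation-through-time with
  Adam (learning rate 0.05 — full-batch gradients tolerate a large step;
  0.01 left the model underfit within the epoch budget), gradient-norm
  clipping at 5, ≤ 50 epochs, early stopping (patience 8) on a held-out
  20% participant split of the training set. Variable-length nights are
  zero-padded under a mask. Deterministic given the seed on one thread.

**Backward greedy selection** starts from the full catalog; each round
scores every single-feature removal by participant-grouped 5-fold CV F1
(sleep class) with a small LightGBM, removes the best-scoring one, and
repeats. Elimination continues while the best removal costs no more than
5e-3 F1 — a tolerance sized to the fold-level noise of the estimate
(F1 resolution ≈ 1/(2 × windows per fold)) so that redundant features are
stripped on plateaus — and stops when every removal costs more, or one
feature remains. Ties break toward the lowest feature index. Selection sees
only training participants.

## Evaluation

Splits are by participant (train fraction 0.7, |train| = round(0.7·N));
all of a participant's nights follow the participant. Metrics are pooled
over test windows: sensitivity (sleep recall), specificity (wake recall),
F1 for the sleep class, and rank-based AUC (ties count ½). Threshold sweeps
use a 0.05-step τ grid; sensitivity is non-increasing and specificity
non-decreasing in τ by construction.

Night-level sleep parameters from the 5-minute label sequence:
TST = 5·(#sleep), SOL = 5·(index of first sleep window),
WASO = 5·(#wake after onset), Eff = TST/(5·#windows). Sleep onset defaults
to the first sleep-labeled window; a stricter first-of-two-consecutive rule
sits behind a config flag. Nights with no sleep-labeled window have SOL and
WASO undefined and are excluded from those aggregations with a logged count.

Device-vs-PSG agreement per parameter: mean bias (device − PSG), the paired
two-sided t test, the paired Hedges g, and the R² of regressing device on
PSG values (proportional bias) — all computed with pingouin
(`ttest(paired=True)`, `compute_effsize(paired=True, eftype="hedges")`,
`linear_regression`). Note pingouin's paired Hedges g standardizes by the
average of the two variances, not by the SD of the differences. Degenerate
cases (zero variance of differences) are flagged rather than reported as
numbers. Ten-fold cross-validation re-randomizes participants into ten
folds, each participant validating exactly once, and summarizes per-fold
metrics as mean, SD and IQR.

## Problem sizes and numerical choices

The default synthetic study runs 60 participants × 2 nights × 480 minutes —
the cohort size of the emulated regime at a desk-scale night count — which
the acceptance script processes end to end, measuring ECG usability
exhaustively on a six-night subsample (≈ 8,600 blocks; the binomial SE at
that count is under half a percentage point). Examples and unit tests use
shorter nights and smaller cohorts; all results in the README were printed
by the committed code. Other numerics: sample SD (n−1) for all blockwise
aggregation; standardization guards zero-variance columns; CRF L-BFGS runs
to ftol 1e-10 / gtol 1e-7 with a 200-iteration cap; probabilities are exact
marginals, never clipped.

## Known limitations

The CRF and LSTM assume regular 5-minute spacing within a chain and ignore
the absolute clock; circadian covariates are out of scope. The generator's
contact process is memoryless at block scale, so usability estimates on it
cannot capture slow electrode degradation. Multi-class stage prediction,
HRV features beyond mean HR, and epoch-level (30-s) scoring are explicit
non-goals. Equivalence with any proprietary R-peak detector cannot be
claimed — only functional parity on synthetic trains is tested.
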