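# Methods

`compslide` analyzes continuous self-reported speech comprehension: a
participant listens to (possibly time-compressed) speech and continuously
adjusts a physical slider whose 8-bit position (0–255) is streamed at a
nominal 250 Hz with paired device- and host-clock timestamps.  This note
documents the models and procedures the package implements, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Device logs and traces

**Clock drift.** The microcontroller's clock runs at a slightly different
rate than the host's (the host clock is aligned with audio playback and is
the reference).  The drift is modeled as a pure linear rate offset: elapsed
device time is regressed on elapsed host time by least squares, giving a
`rate_ratio` (device rate in host units; 400 ppm of drift appears as
1.0004) and an offset.  Device timestamps are mapped to the host scale as
`(device − offset) / rate_ratio`.  For drift up to 500 ppm (0.05%, the
measured worst case over a trial) the corrected residual is far below one
sample period (4 ms), so drift is behaviorally negligible once corrected —
the point of performing the correction is to verify that this is so.

**Resampling.** Raw logs are resampled onto a uniform grid by zero-order
hold: the slider reports a held physical position, not samples of a
band-limited signal, so the last reported position persists until the next
report.  Linear interpolation is available as an option.  Gaps longer than
five sample periods are filled by the hold and flagged in the trace's
quality metadata.

**Normalization.** Values are divided by 255 (the device maximum), so a
participant who never reaches the top of the scale is not inflated.
Per-trial min-max normalization is available as an option for visualization.

**Sample counts.** Expected trial lengths use half-up rounding of
`duration × fs`; this convention is pinned by the per-rate counts
7250/3638/2733/1820/1453 that follow from the mean segment durations
29/14.55/10.93/7.28/5.81 s at 250 Hz (three of which are exact .5 cases).

**Trial summaries.** The single comprehension score for a trial is the
median of its trace.  Before time-course analyses the initial travel from
the 0 origin is cropped using per-rate cutoffs (5/4/2.5/2/1.5 s for
speed-up factors 1–5; configurable per experiment).  Pentile statistics
split a trace (or a transcript's words) into five contiguous bins whose
sizes differ by at most one, remainder to the earliest bins; the bins
partition the input exactly.

**Attention screening.** The movement statistic for the ±3.5 SD outlier
check is each participant's mean total absolute trace displacement per
trial.  The underlying distributional statistic is not uniquely determined
by the screening rule alone; total displacement was chosen because it is
scale-free across trial durations and sensitive to both frozen and erratic
sliders.

## Summary scoring

Three scores compare a written summary with the heard segment:

* `written_summary_score` — for every summary word, the maximum cosine to
  any segment word, **summed** over summary words.  Length-sensitive by
  construction: a single verbatim match cannot dominate, and it is exactly
  additive — appending a word adds that word's best cosine.  Duplicating a
  summary word changes it.
* `heard_segment_score` — for every segment word, the maximum cosine to any
  summary word, **averaged**.  Normalizes by segment length and is invariant
  to duplicated summary words.  The asymmetry between the two scores is
  intentional and tested.
* `contextual_score` — cosine of two single-vector text encodings.  Any
  deterministic text-to-vector callable satisfies the encoder contract; the
  packaged encoder mean-pools word vectors.  Pretrained sentence encoders
  can be plugged in unchanged.

Out-of-vocabulary words are skipped and counted, never replaced by zero
vectors (a zero vector would silently corrupt a max-cosine).  Stop words are
retained by default; scores operate on the text as written.  Word vectors
load from the word2vec text format; tests use small deterministic random
tables, so absolute score values in the test suite are not comparable to
scores produced with real distributional embeddings — only the oracle
identities and orderings are.

## Comprehension-decline models

Median slider score `y` as a function of speed-up factor `x` is fit by

    linear:   y = b0 + b1 x
    sigmoid:  y = b0 / (1 + exp(-b1 (x − b2)))

where `b0` is the intercept (maximum asymptote), `b1` the slope (growth
rate; negative for a decline) and `b2` the center of the sigmoid, where the
main drop occurs.  The sigmoid is fit by bounded nonlinear least squares
with initialization `(max(y), −1, median(x))`, bounds `b0 ∈ (0, 1.5]`,
`b2 ∈ [min(x), max(x)]`, `|b1| ≤ 50`, and up to ten seeded random restarts
within the bounds on non-convergence.

Model comparison uses speech-rate-stratified k-fold cross-validation
(default k = 5): within each rate, trial indices are shuffled and dealt
round-robin, so every fold holds an equal number of trials of each rate
(remainder round-robin).  Each model is scored by the Pearson correlation
and MSE between predicted and observed held-out medians; per-subject mean
correlations feed a one-sided Wilcoxon signed-rank test of the directional
hypothesis r_sigmoid > r_linear (exact null distribution up to 25 non-zero
differences, zero differences dropped).

Covariate handling: the package builds the long-format per-trial analysis
table (all variables rescaled to 0–1: ratings /10, rates min-max over the
design, digit span over its 3–9 range, digit-in-noise /100, semantic scores
min-max over observed trials, missing summaries stay missing) and exposes
the mixed-model formula descriptor; fitting mixed-effects models is routine
statistics left to the user's preferred package.

## Temporal response functions

The TRF predicts the continuous slider trace from six annotation channels —
low-surprisal passage onsets, high-surprisal passage onsets, word-by-word
surprisal impulses, segment onset, and x1 / x2.5 rate-condition onsets —
via time-lagged ridge regression over lags −0.2…+5 s (1301 lags per feature
at 250 Hz).  The negative-lag band is retained as an artifact detector: a
true response cannot precede its stimulus, and `negative_lag_mass` flags
kernels with substantial acausal mass.  Peak latency is the lag of the
maximum absolute coefficient within [0, tmax]; ties resolve to the earlier
lag, and an all-zero kernel raises instead of returning 0.

**Solver.** Ridge with identity penalty, α = 1.0 by default.  Both the
response and every design column are centered before solving; the intercept
is `ȳ − x̄ᵀβ` and is never penalized.  Column centering matters: with an
uncentered design the constant offset of the response is not exactly
representable by impulse columns, and the resulting compromise visibly
biases every kernel.  The normal equations are solved by a
positive-definite factorization.

**Cross-validation.** Folds are contiguous blocks aligned to story
boundaries — never shuffled samples, which would leak through the strong
autocorrelation of slider traces.  Accuracy is Spearman's ρ (average ranks
on ties) between predicted and observed held-out samples.  "Not enough
variation within a fold" is operationalized as a constant held-out trace or
an annotation channel that varies overall but is constant within a training
fold; when this occurs under k = 3 the model falls back to k = 2, and fully
degenerate data raise.

**Ablation.** The surprisal contribution is measured by zeroing the three
surprisal channels, re-running the same cross-validation, and testing the
per-subject Δρ (full − reduced) against zero with a one-sample t-test.

## The synthetic-data generator

The generator is first-class, tested code; it defines the conditions under
which every downstream claim is checked.

**Participants.** Each simulated participant has a declining sigmoid
comprehension profile (asymptote 0.7–1.0, slope 1.5–3, center at rates
2.5–3.5), a gamma-density motor delay kernel (shape 2.5–4.5, scale
0.25–0.45 s, i.e. delays peaking around 0.4–1.6 s, discretized to sum to
one so convolution preserves levels), motor noise (sd 0.05 in slider
units), and a device clock drift of 50–500 ppm.  Digit-span and
digit-in-noise covariates are drawn but do not influence the latent traces.

**Trials.** The latent target starts at 0, steps to the latent
comprehension at stimulus onset, and (when word events are supplied) is
pushed down in proportion to the local surprisal excess over the stimulus
mean.  The target is convolved with the delay kernel, perturbed by motor
noise, clipped to [0, 1], quantized to 8 bits and timestamped on the
drifting device clock.  Post hoc measures map from the median latent trace:
the 10-point rating as `round(10·median)` (a modeling choice — the mapping
from latent comprehension to the rating is not empirically constrained) and
multiple-choice accuracy as `0.25 + 0.75·median` (chance mixing, keeping
accuracy above the 25% line even when comprehension collapses).  Summaries
sample `⌈comprehension·n⌉` segment words without replacement with inclusion
weights `1 + recency_bias·pentile` (default bias 1.0), emulating the
recency bias of written recall.

**Stories.** Alternating low/high-surprisal passages of ~30 words; per-word
surprisal is normal around the passage mean (4.91 / 5.90, sd 0.5) truncated
at zero; surprisal is treated as dimensionless language-model surprisal,
since only internal consistency matters here.  Inter-word intervals are
jittered lognormally around the x1 mean (≈0.31 s, i.e. ≈196 wpm) and scale
exactly with the speed-up factor.

**TRF subjects.** For kernel-recovery and ablation checks, traces are
generated *through the estimator's own lagged design*: every true feature
kernel is the participant's gamma delay shape scaled by a feature
amplitude, the clean trace is design × kernels, and noise brings the
signal-to-noise variance ratio to 5.  The noise is half white and half a
slow AR(1) wander (time constant 10 s) standing in for endogenous slider
drift.  Three structural choices make the simulation identifiable, all
fixed while validating the generator against its own noise-free oracle:
(1) the segment-onset channel is exactly the sum of the two rate-onset
channels (every story onset is a rate onset), so only the minimum-norm
decomposition of the onset response is identifiable, and the ground-truth
amplitudes are stated in that form (segment amplitude = sum of rate
amplitudes); (2) story lead-ins are longer than the lag window, so the
story-onset response cannot alias into passage-onset kernels; and
(3) passage lengths, starting levels and inter-passage gaps are jittered so
the design is not periodic.  Each simulated subject hears 32 stories
(half at each rate) — more than a realistic session, chosen so the sparse
rate-onset channels (one impulse per story) accumulate enough events for
stable per-feature recovery; the ablation checks, which do not need
per-feature stability, use 8 stories.  Simulations run at 20 Hz (105 lags
per feature); the estimator itself is rate-agnostic and the full 250-Hz
window is exercised separately in shape tests.

**What the generator does not emulate.** Real slider data contain
re-reading artifacts, hand switches, end-stop dwell, nonstationary motor
noise, and semantic structure in summaries beyond word identity; the toy
embeddings carry no distributional semantics.  Passing tests therefore
demonstrate that the *pipeline* is correct under known ground truth — not
that real data satisfy the generative assumptions.

## A known property of the rank-based ablation metric

Under a null generator (surprisal channels carried by the annotations but
ignored by the trace), the mean Δρ of the surprisal ablation is *not* zero:
it is reliably ≈ −0.10 to −0.13.  The cause is mechanical, not a defect of
the fits: between onset events the reduced model's design rows are exactly
zero, so its held-out predictions are exact constants there and form one
large rank tie-block, which shrinks its rank variance and concentrates ρ on
the informative events; the full model's dense word-surprisal columns carry
small fitted-noise wiggles that un-tie every sample and dilute its ρ.  The
effect is independent of the amount of data and *grows* as noise shrinks
(smaller wiggles still break ties), and it disappears entirely under a
Pearson metric (Δr ≈ 0.003 on the same data).  Because the deficit is
negative, it is conservative with respect to the positive ablation claim
(a genuine surprisal contribution must overcome it), but rank-based Δρ
values should not be read as unbiased effect sizes when the reduced model
predicts long constant stretches.

## Problem sizes and tolerances

Simulation scales used by the validation suite and `scripts/acceptance.py`:
50 cohorts of 125 trials for sigmoid recovery (median parameter errors
≤ 0.05); 50 replicate cohorts of 22 subjects for model selection (sigmoid
preferred in ≥ 90% of replicates; both models r > 0); 20 TRF subjects at
SNR 5 for kernel recovery (per-feature mean correlation ≥ 0.9, group ρ > 0
at p < .001, peak-latency error ≤ 0.1 s); 25 subjects per condition for the
ablation.  Nonlinear fits are considered converged at the optimizer's
defaults; numerical identities are asserted at 1e-6…1e-10 depending on the
conditioning of the quantity.
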