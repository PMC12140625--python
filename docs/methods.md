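# Methods

This note documents the models, estimators, and numerical choices behind
`selhist`, in the order data flows through the package: the task and its
generative model, history labeling, tachometric estimation, cross-subject
alignment, and the conditional-independence interaction benchmark. It
closes with what the synthetic generator does and does not emulate, and
the known limitations.

## Task model and trial table

The data model is one row per *completed* trial of an urgent
four-alternative singleton search: a go signal, a gap of 0–225 ms before
the color cue appears, a response deadline of 450 ms after the go signal,
four possible target locations (right/up/left/down, chance 0.25) and two
target colors (red/green). The processing time PT = RT − gap is the time
the cue could have informed the choice; it may be negative (the saccade
began before the cue). Validation enforces 0 < RT ≤ 450 ms, gap ∈
[0, 225] ms, PT ≡ RT − gap, and outcome ≡ (choice = target location); rows
violating timing are rejected by default (an explicit `drop_invalid`
filter exists, with a logged count, because silently dropping trials hides
data problems). Rigs that record continuous target angles can be reduced
to the four quadrant labels with `quadrantize`, which assigns each axis
and the following (counterclockwise) open quadrant to one label.

Aborted/incomplete trials are outside the data model; all history
definitions below therefore run over consecutive *completed* trials, and
never across session boundaries.

## Synthetic generator

The generator is the minimal mechanism that produces every qualitative
history effect the pipeline is designed to detect. Per trial, in order:

1. gap ~ discrete uniform on [0, 225] ms; target color uniform on 2;
   target location uniform on 4 (all independent across trials, so the
   color-repeat prior is 0.5 and the location-repeat prior 0.25);
2. RT ~ Normal(μ_RT = 250 ms, σ_RT = 60 ms) truncated to (0, 450];
   PT = RT − gap;
3. the trial is *informed* with probability Φ((PT − μ_ramp)/σ_ramp)
   (defaults μ_ramp = 125 ms, σ_ramp = 25 ms), otherwise a *guess*;
4. a guess draws its location from softmax(w_loc) over the four
   location-bias accumulators; an informed choice hits the target with
   probability σ(logit(q₀) + w_col[target color]) (default base ceiling
   q₀ = 0.70) and otherwise lands on a uniformly random distracter;
5. learning: the accumulators of the *target's* location and color are
   incremented by η·g(outcome), with η_loc = 0.6, η_col = 1.0, and
   g(correct) = +1, g(error) = −0.5; then every weight decays
   geometrically (λ_loc = 0.8, λ_col = 0.5). Sessions reset all weights.

Rationale for the defaults:

- **Two channels, two expressions.** Location bias lives in the guess
  policy (it moves the floor and is invisible at long PT); color priming
  lives in the informed policy (it moves the ceiling and cannot affect
  guesses). This is the dissociation the tachometric analysis exploits.
- **Outcome gating with weaker devaluation.** Reward reinforces repetition
  of the just-rewarded color/location; errors devalue it. With
  |g(error)| < g(correct), repetition still helps *on average* when
  outcomes are not conditioned on, while outcome-conditioned contrasts
  (1SC vs 1SE) swing by tens of percentage points. With symmetric gains
  (g(error) = −g(correct)) the unconditioned repetition effect nearly
  cancels — and in fact slightly inverts, because the update variance it
  adds is penalized by the concavity of the sigmoid — which is not the
  phenomenology being emulated.
- **Distinct timescales.** λ_col = 0.5 extinguishes a single color event
  within about 5 trials; λ_loc = 0.8 keeps a single location event
  measurable out to roughly 9 trials (0.8⁹ ≈ 0.13). These give the two
  channels clearly separable decay rates for the time-course analysis.
- **RT independent of bias by default.** History effects on RT are
  idiosyncratic across subjects; a hook (`rt_bias_gain_ms`) that shortens
  RT with the motor bias at the chosen location exists but ships off.

Two named presets exist. `GeneratorParams.unbiased()` zeroes both gains
(accuracy depends on PT only; with q₀ = 0.25 every PT is at chance).
`GeneratorParams.independent_channels()` removes outcome gating
(g(error) = g(correct) = +1), so each accumulator is a deterministic
function of its *own* target sequence and the two history variables
influence outcome through fully decoupled channels — the appropriate
ground truth for testing slope-recovery of the interaction benchmark —
and raises η_col to 2.0 so the ceiling-accuracy spread across sequences
has the tens-of-percentage-points scale seen in trained subjects rather
than a few points.

Randomness is a single PCG64 stream consumed in a fixed order (per-session
vector draws, then per-trial choice draws), so output is bit-reproducible
per seed.

## History labeling

Color and location conditions are *relative* to the current trial: an S
step means the trial in question had the same color (or location) as the
current trial, a D step means a different one ("different" location is any
of the other three). Outcome conditions are *absolute*: C/E mean the
preceding trial was correct/error. Run conditions (`NS`, `ND`, `NC`, `NE`)
use "at least N" semantics exactly as defined verbally — the 2S set is a
subset of the 1S set — so reporting functions always state N. Lagged
single-event conditions (`1Skx`) constrain only the trial k+1 positions
back, leaving the k intervening trials fully unconstrained. Joint
conditions are conjunctions of same-depth components; fully specified
per-step patterns (e.g. color SD with location DS) partition the eligible
trials (those with ≥ H same-session predecessors) at each depth H, which
the test suite verifies exhaustively against a literal string-matching
oracle on small tables.

## Tachometric estimation

The tachometric curve is the fraction correct in a rectangular sliding PT
window, default 50 ms wide stepping every 1 ms, on an integer-ms grid of
centers. Bins are half-open, [c − w/2, c + w/2) — the convention is stated
because nothing in the verbal definition fixes edge handling. Empty bins
are *undefined* (NaN, n = 0), never zero, and are excluded from downstream
fits.

Floor and ceiling accuracies are plain proportions over PT < 100 ms and
PT > 150 ms respectively — independent of any binning by construction.
The ceiling threshold is configurable (subjects with later ramps need
~200 ms). All binomial CIs are 95% Agresti–Coull intervals with the exact
normal quantile (not z = 2), clipped to [0, 1]; the implementation is the
closed form and is cross-checked against `statsmodels` in the tests, with
simulated coverage at p = 0.25, n = 200 within 1% of nominal. RT summaries
(mean, SD, SEM) pool correct and incorrect trials at all PTs. A percentile
bootstrap (default 10⁴ replicates) is provided for significance testing of
derived quantities; it is labeled as a percentile method because the
resampling scheme behind published significance calls of this kind is
typically under-specified.

## Cross-subject alignment

To pool two subjects, the second subject's curve y₂ is registered onto the
first's via z(j) = g·(y₂(j + δ) + b) and the mean absolute deviation
|y₁ − z| over mutually defined bins is minimized. δ is searched on an
integer-ms grid (default −100…100): the curves live on a 1-ms grid and a
discrete search is exactly reproducible, whereas a nested continuous
optimizer buys nothing but non-determinism. The inner 2-parameter L1
problem is solved by iteratively reweighted least squares on the
reparameterization z = a·y₂ + c (a = g, c = g·b), with weight floor 1e−10,
parameter tolerance 1e−12, and a 200-iteration cap. The objective is
*normalized* (mean, not sum) so candidate δ with different overlap sizes
compare fairly; the sum-form value is reported alongside. Ties break
toward smaller |δ|, then smaller δ. A constant y₂ makes the gain
unidentifiable and is flagged rather than fit. Only δ is ever applied to
data (subtracted from the second subject's RTs, hence PTs); g and b are
reported for inspection only. Bins can optionally be weighted by trial
count (`weight_by_n`); the default is unweighted.

## Interaction benchmark

Under conditional independence of two history variables A and B given the
outcome C, Bayes' theorem reduces the jointly conditioned accuracy to

    P(C=1|A,B) = (p_A p_B / π) / (p_A p_B / π + (1−p_A)(1−p_B)/(1−π)),

where p_A = P(C=1|A), p_B = P(C=1|B), and π = P(C=1) is the prior. The
prior is always the ceiling-window overall accuracy of the analyzed table,
recomputed per dataset. Marginal accuracies of exactly 0 or 1 (possible at
small n) are clamped to [1e−9, 1−1e−9] with a log message; a degenerate
prior is an error.

A scan enumerates every fully specified joint sequence at depth H over a
variable pair — (color, location), (color, outcome), (location, outcome),
or the outcome-augmented pairing in which P(C=1|color-pattern + outcome-
pattern) and P(C=1|location-pattern + outcome-pattern) predict the full
three-variable sequence — measures the informed-window accuracy of each
joint condition, and predicts it from the two marginals. Points whose
*measured* CI spans ≥ 15 percentage points are flagged unreliable and
excluded from the summary regression (the measured accuracy is the
regressor, so its noise is what matters; the predicted value's CI,
propagated from the marginal CIs by a first-order delta method, is for
display only). The summary slope β₂ comes from OLS of predicted on
measured over the reliable points, with an intercept (a no-intercept
option exists) and a t-based 95% CI.

Two caveats are worth stating. First, because the regressor is itself
estimated, β₂ is attenuated toward 0 by errors-in-variables; the effect is
negligible when the accuracy spread across sequences is large relative to
per-point sampling error (the regime of interest, and of the recovery
tests at H = 2) but becomes visible for deep scans of weak effects — a
slope slightly below 1 at large H is not, by itself, evidence of
interaction. Second, the reliability rule could alternatively inspect the
predicted CI or both; the measured span is used because it is the noisier,
regression-relevant quantity, and the threshold is configurable.

`ci_oracle_check` closes the loop on the formula itself: it samples an
explicit 2×2×2 joint P(A,B,C), compares empirical joint accuracies with
predictions built from empirical marginals, and returns the worst-cell
discrepancy — < 0.01 at 10⁶ samples when the joint satisfies conditional
independence exactly, and bounded away from zero (> 0.1) for an XOR-like
construction where the marginals are uninformative.

## Problem sizes and test design

The test suite exercises the estimators at sizes where their sampling
error is small relative to the effects under test: 10⁵ trials for priors
and floor checks, 5×10⁴ per seed (20 seeds) for slope recovery at H = 2,
2.5×10⁴ per subject for alignment recovery (δ within ±5 ms of an injected
30 ms shift; noiseless transforms recover (g, b, δ) to ≤ 1e−6), and
4×10⁵ trials for the single-event time courses, whose lag-5 contrasts are
only a few percentage points. Slope recovery is asserted at H = 2 — the
canonical 16-sequence depth — because deeper scans enter the
attenuation regime described above.

## What the generator does not emulate

The synthetic data contain no aborted trials, no lapses, no RT dependence
on bias (by default), no session-to-session drift in ramp position or
asymptote, no eccentricity/orientation variation of the stimulus array,
and gap values are exactly uniform. Effective history effects are
first-order (exponential-decay accumulators): real subjects may show
longer-tailed kernels, asymmetries between repeat and switch beyond the
outcome gating modeled here, and cross-channel couplings other than
reward. Passing the recovery tests therefore certifies the *estimators*
— that the pipeline measures what it claims on data whose ground truth is
known — not that this generative model is an adequate description of any
particular subject.

## Known limitations

- The L1 alignment assumes the two curves differ by gain/baseline/shift
  only; genuinely different curve *shapes* produce a well-defined but
  hard-to-interpret δ.
- β₂ attenuation at deep H (see above); an errors-in-variables or Deming
  regression would remove it at the cost of an extra variance-ratio
  assumption, and is not implemented.
- The reliability filter and the 15-point threshold are conventions; very
  small datasets can end with < 2 reliable points, in which case the slope
  is flagged undefined rather than extrapolated.
- History labels condition on the *target's* color/location, not the
  chosen location; choice-conditioned histories are out of scope.
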