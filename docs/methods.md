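# Methods

This note documents the models, conventions and defaults the package
implements, the choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## Task model

A probabilistic inference task is four binary cues predicting one of two
options. Validities lie strictly in (.5, 1) — a validity of .5 carries no
information, 1 would be certainty — and are stored in descending order;
equally valid cues keep their input order. Cue values are coded +1/−1
rather than 1/0 so the sign of a cue–option link in the network follows
directly from the cue value. Option labels A and B are fixed content
labels; screen-position randomization is presentation-only and not
modeled. The task generator rejection-samples uniform validities (rounded
to two decimals, the precision at which validities are displayed to
participants) and uniform ±1 cue patterns, discarding dominated items,
duplicates (on rounded validities plus pattern) and naive-Bayes ties, so
that the rational benchmark is defined for every generated task. The
sampling distribution of validities is not dictated by the task format;
uniform over a configurable range (default .60–.94, the span of the
printed example tasks) is the package's choice.

## PCS network

Nodes: one driver (clamped at 1), four cue nodes, two option nodes; all
other activations start at 0 and are bounded in [a_min, a_max] = [−1, 1].
Weights are symmetric: driver→cue `w_vᵢ = (vᵢ − .5)^P`, cue→option
±.01 (sign = cue value), option↔option −.2. The constants (decay .05,
bounds ±1, link magnitudes, driver activation 1) are the published values
of the interactive-activation model family this network belongs to; all
are configurable through `PCSConstants`.

Updating is synchronous ("parallel"): every non-driver node receives
`input = Σ weight × neighbour activation` and moves by
`a(1−d) + input·(a_max − a)` for non-negative input, else
`a(1−d) + input·(a − a_min)`. After each step activations are clipped
into [a_min, a_max]: at small `P` the driver→cue weights approach 1 and
the raw step can transiently overshoot the ceiling (input can reach 1.02
at activation 0), so the clip makes the boundedness invariant hold by
construction. Two implementation details keep the dynamics exactly
symmetric under relabeling of the options: the two option contributions to
a cue node are combined as `w_v + (term_A + term_B)`, which is invariant
under swapping A and B in IEEE arithmetic, whereas a fused BLAS dot or a
different association order is not. Mirrored tasks therefore produce
bit-identical activations with the options swapped.

Convergence: the largest per-node absolute change must stay below 1e−6
for 10 consecutive iterations; the run aborts at 3000 iterations with a
non-convergence flag (surfaced, never silently ignored). The reported
iteration count is the first iteration of the stable window; the
window-end convention is available via configuration. With default
constants every generated task converges within ~90–250 iterations for
P ∈ [0, 5].

Predictions: choice = option with the higher settled activation (an exact
tie predicts "random"), confidence = |a_A − a_B|, time = iterations to
convergence. `PCS_fix` uses P = 1.9 with deterministic choices; for
`PCS_fitted` the probability of choosing the preferred option is the
logistic `1/(1 + e^{−λΔa})`, so λ = 0 is guessing and large λ is nearly
deterministic.

## Heuristics and the Bayesian benchmark

TTB scans cues in validity order and decides by the first discriminating
cue; its confidence is that cue's validity, and with no discriminating cue
it predicts random choice at chance confidence (.5). EQW compares
unweighted cue sums (confidence = |difference|, an even integer in
{0,…,8}); WADD_c compares sums weighted by `vᵢ − .5`. Time predictions
are elementary-information-process (EIP) counts: 3 per examined cue for
TTB (2 reads + 1 comparison, stopping at discrimination), constants 15 and
23 for EQW and WADD_c. The literature names the EIP construct but not a
unique count; because predictions enter classification only through the
contrast transform (below), any strictly monotone recount yields identical
TTB contrasts up to affine equivalence and identical all-zero contrasts
for the constant-time strategies, so classification is insensitive to the
bookkeeping.

The naive Bayesian solution accumulates posterior log-odds
`Σ dᵢ ln(vᵢ/(1−vᵢ))` with `dᵢ = +1/0/−1` for cues favoring A, neither,
or B, under cue independence and equal priors. Exact ties are reported as
"tie", never silently resolved; the generator excludes tie tasks so
performance scoring is well defined.

## Contrast transform

Raw time and confidence predictions live on arbitrary, strategy-specific
scales. They are mapped to contrast weights `(x − mean)/(max − min)` —
zero-sum, unit-range — per task set; a constant input maps to the all-zero
vector. Classification is thereby invariant to affine rescaling of any
strategy's raw predictions, and a strategy that predicts no variation on a
measure (EQW/WADD_c times) contributes an intercept-only model for it.

## MM-ML likelihood and classification

Per strategy and participant the log-likelihood sums three components:

* **Choices.** Deterministic strategies: Bernoulli with constant error
  ε ∈ [0, .5], estimated as the error proportion over trials with a
  determinate prediction (capped at .5); random-prediction trials
  contribute probability .5 and are excluded from the ε denominator.
  `PCS_fitted`: the logistic rule with λ.
* **Times.** Gaussian on preprocessed ln-RT with mean
  `μ_T + β_T·time_contrast`.
* **Confidence.** Gaussian with mean `μ_C + β_C·confidence_contrast` on
  the 50–100 slider scale.

Slopes are estimated by least squares and clamped at zero (refitting the
intercept) so a strategy cannot profit from predicting the *reverse* of
the observed ordering — the directional logic of the method. σ is the ML
estimate (divide by n), floored at 1e−6 so noise-free data keeps a finite
likelihood; the floor is far below any realistic residual scale and only
matters for exact fits.

Model selection is by `BIC = −2 logL + k ln(n)` with `n` the number of
scalar observations entering the likelihood (60 choices + 60 confidences +
kept decision times under the full method). Parameter counts are fixed,
documented conventions, configurable per strategy: k = 7 for deterministic
strategies (ε plus intercept/slope/σ twice) and k = 9 for `PCS_fitted`
(the fitted P and λ replace ε and add grid parameters). BIC ties break
toward fewer parameters, then alphabetically. With choice-only
classification (available for comparison) the defaults become 1 and 3.

`PCS_fitted` is fitted by exhaustive grid search over P ∈ [0, 5] and
λ ∈ [0, 5] in steps of .1 (51 × 51 combinations); likelihood ties break
toward the smallest P, then the smallest λ. The network is λ-free, so runs
are cached per (task set, P): one batched sweep of 51 × 60 network
settlements serves every participant on the same task set, and the
per-participant fit is a vectorized evaluation over the grid. The
restricted range P ∈ [1, 2] (a stricter a-priori convention some analysts
prefer) is available
through the same configuration and reproduces the corner-solution pile-up
expected when the generating P lies outside the range.

The saturated-model check compares the winner's choice component against a
model with one free choice probability per distinct cue pattern by the
likelihood-ratio statistic G² with df = (patterns − choice parameters),
flagging significant misfit at α = .05. A participant whose winning
strategy misfits should not be interpreted as classified.

## Cross-validation

Tasks are partitioned into six seeded folds of ten. Per fold, every
strategy parameter — ε or (P, λ), and the Gaussian parts — is re-estimated
on the other 50 tasks' trials and the held-out trials are scored under
those fixed parameters; the winner maximizes the summed out-of-sample
log-likelihood. No BIC penalty applies out of sample, since no parameter
is fitted to the held-out fold; selection by held-out BIC would double-
penalize and is deliberately not the default. Contrast vectors are
computed once on the full task set (predictions are data-independent, so
this leaks nothing). For held-out scoring ε is floored at 1e−6: an ε of
exactly 0 would assign probability zero to an unseen error, and the floor
guards that impossible event without distorting deterministic fits — a
noise-free agent still outranks every competitor.

## Preprocessing and exclusions

Participants below 55% agreement with the naive Bayesian solution are
excluded. Decision times above 60 s, or more than 3 SD from the grand mean
across all kept participants, are flagged and leave all time analyses
(choices and confidence keep the trial). The 3-SD screen runs on the ln
scale by default, consistent with the downstream ln analysis; the raw
scale is a documented option since the choice is not dictated by the
analysis logic. ln-RTs are then detrended per participant — linear
regression on trial index, residuals plus the participant mean — to
partial out order effects such as practice speed-up; per-participant
(rather than pooled) detrending is the default because order effects are
idiosyncratic.

Adherence is the proportion of choices matching a strategy's determinate
predictions (random-prediction trials leave that strategy's denominator);
`PCS_fitted` adherence uses each participant's fitted P. Individual-level
Pearson correlations between observed measures and contrast predictions
are averaged via Fisher z (atanh — mean — tanh); zero-variance contrasts
have undefined correlations and are reported as 0. Condition differences
in the classification distribution use a 2 × strategies chi-square without
continuity correction (never-assigned strategies dropped); the fitted-P
comparison uses a two-sided Mann–Whitney U.

## Synthetic-data generator

The generator is the package's test bed: agents with a known strategy
produce (choice, RT, confidence) streams with exactly the statistical
structure the likelihood assumes — choices flipped with probability ε (or
sampled through the logistic rule for PCS agents; fair coins on
random-prediction trials), ln-RT Gaussian in the time contrast, confidence
Gaussian in the confidence contrast and clipped to [50, 100] the way a
slider censors. Trial order is randomized per participant, with an
optional linear ln-RT drift for order-effect testing. Ground-truth labels
travel in a sidecar structure, never inside the trial data.

Study-level defaults emulate the reference design: 67 intuition + 61
deliberation participants, 60 tasks, strategy mixture .30/.29/.28/.07/.06
for PCS_fitted/PCS_fix/WADD_c/EQW/TTB (PCS variants .59 combined), PCS
sensitivity 1.70 (intuition) vs 1.97 (deliberation). Deliberation shifts
ln-RT by ln(9241/5583) ≈ .504 — reproducing the observed mean-time ratio —
and multiplies the error rate by .75 (dividing λ by the same factor).
The noise defaults (ε = .12, λ = 2.7, multiplier .75) were calibrated once
so that the default study's condition performance means land on the
reference values (.87 intuition, .91 deliberation) at the full design
size; they are conventions for simulation, not estimates of any
individual.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: within-participant strategy switching or
mixtures (each agent is one strategy throughout), heavy-tailed or skewed
residuals beyond lognormal RTs, sequential dependencies other than a
linear drift, slider response styles (end-preference, coarse rounding),
attention lapses, and any questionnaire or self-report structure.
Recovery rates measured on generator output are upper bounds for real
data, where the likelihood is misspecified to an unknown degree.

## Numerical conventions and degenerate inputs

σ floor 1e−6; held-out ε floor 1e−6; `0·ln 0 = 0` throughout; exact
activation ties predict "random" (probability .5 in likelihoods, excluded
from adherence); constant observed measures give zero-variance Gaussian
fits at the floor; fewer than 3 usable trials per measure is an error, as
is a trial stream referencing unknown task ids. All stochastic components
take explicit seeds; per-participant seeds derive from a study master
seed, so datasets regenerate bit-identically.

## Problem sizes in the test suite and acceptance script

The recovery benchmark uses 20 agents per strategy (5 strategies, 60
tasks) at low noise (ε = .05; logistic determinism 4; residual sd .1 on
standardized scales), with probabilistic-PCS agents generated at P = 3.0 —
away from the fixed variant's 1.9, since an agent at P ≈ 1.9 is
observationally near-equivalent to `PCS_fix` and the two labels would not
be distinct models. The choice-only comparison instead uses the
compensatory regime (P = 1.0), where PCS and WADD_c choice predictions
coincide on nearly every task and only times and confidence separate the
processes. Parameter recovery uses 20 seeds per (P, λ) setting; the
chi-square calibration uses 200 replicate null studies of 15 + 15
participants with identical generating conditions in both groups. These
sizes are the package's chosen simulation designs and are large enough
that the reported rates are stable to a few percentage points.

## Known limitations

The network constants are conventions of the model family; fitted P values
are interpretable only relative to those constants. The grid's .1
resolution bounds parameter-recovery precision. BIC parameter counts are
conventions (documented, configurable), not derived quantities; competing
conventions shift BIC by a constant per strategy and can flip
classifications near ties. The saturated test has low power for cue
patterns seen once. Cross-validation selects by held-out likelihood;
alternatives (held-out BIC) are not implemented beyond the penalty-free
default. The pipeline replaces mixed-model analyses with per-participant
correlation summaries; data can be exported for external mixed-model
fitting.
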