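# Methods

## Task model

A session is a sequence of uncued blocks over a fixed offer set
{5, 10, 20, 40, 80 μL}.  The first block is mixed; thereafter high and low
blocks alternate with a mixed block between each.  A block ends after
`block_length_completed` (default 40) completed trials; premature fixation
breaks (violations) do not count and force the next trial to repeat the same
offer.  Offers are drawn uniformly from the block's set; a fraction
`catch_prob` of completed trials withhold the reward; delays are exponential
with mean `mean_delay` (default 2.5 s) and catch-trial waits are censored at
the 100-s timeout.  Female-rat scaling maps the physical volumes to
{4, 8, 16, 32, 64 μL} but stores the canonical labels, matching how such data
are analyzed.  Each session consumes one RNG stream with a fixed draw order
(block coin; then per trial: violation flag, catch flag, offer, delay,
behavioral noise), so a seed pins the entire table.

Defaults that the task description leaves open: `n_blocks = 9` (~450-trial
sessions, a typical day), `catch_prob = 0.20` (the steady-state range is
15–25%; the 15% value is the introductory setting), `violation_prob = 0.20`
(typical premature-break rates; exposed in config).

## Hidden-state inference

The ideal observer runs a discrete Bayes filter over blocks (low, mixed,
high).  The likelihood of an offer is uniform over the current block's set
(1/3 or 1/5); only the low-block column of the likelihood and transition
structure is canonical, the rest follows from symmetry: the transition
(hazard) matrix has low column (1−H₀, H₀, 0) for previous (low, mixed,
high), the high column mirrors it, and rows normalize, giving
h[mixed][mixed] = 1−2H₀ and a doubly stochastic matrix.  H₀ = 1/40 encodes
the block length and is a constant, never fitted.  The posterior initializes
one-hot on mixed because sessions always start in a mixed block (a flat
start is available).  MAP ties break toward mixed, then low — mixed is the
marginal modal state and the rule must be deterministic.  The λ model blends
the propagated prior with a flat prior before the likelihood update;
λ = 1 is the ideal observer, λ = 0 keeps only the current likelihood.
By default the filter updates on every offered reward, including the
repeated offers of violation trials (a skip-violations switch exists);
repeated offers are genuine evidence under the task's offer distribution, so
updating is the conservative default.

## Value models

κ (μL/s) is the opportunity cost of time.  The inferential model takes the
fixed κ of the MAP block; the belief-state model the posterior-weighted
average.  The retrospective model is a TD learner over offered rewards,
`κ_{t+1} = κ_t + α_t (r_t − κ_t)`, with dynamic learning rate
`α_t = G_t α₀` where `G_t = 1/(1 − |Δ p_mixed|)` tracks how fast the
ideal-observer posterior is moving (capped at 1000, since the expression
diverges as |Δp| → 1; α_eff additionally clamps at 1).  Static (G = 1) and
|RPE| gain variants are implemented for contrast.  The retrospective update
skips violation trials by default (only completed-trial offers feed the
running average); a switch codes violation/catch rewards as 0 to mirror the
regression convention.

Rewards entering the TD update are divided by `reward_timescale` (seconds)
so κ shares units with the other models.  The nominal convention is 1 s.
For *generating* wait times from a retrospective agent the default
timescale is 10 s: with a 1-s timescale the running average sits near the
mean offer (~31 μL/s), κτ then exceeds every offer and the wait-time
equation is clamped everywhere — a degenerate generator.  At 10 s, κ ranges
over ~(0.5, 8) μL/s and generated wait times are seconds-scale.  The
timescale is a fixed model constant shared between generation and fitting,
never a free parameter.

Per-trial timing conventions: the wait-time κ on trial t uses the posterior
*including* the trial-t offer (the offer is cued before the wait), while the
initiation-time κ is the pre-offer value (the propagated prior's MAP, or the
TD κ before its trial-t update), since the animal initiates before hearing
the tone.

## Behavioral read-outs and noise

`WT = Dτ ln(C/(1−C) · (R−κτ)/(κτ))` with natural log (the derivation from
the exponential delay hazard is in nats; D absorbs any base change).  The
expression is undefined for R ≤ κτ; such predictions, and any prediction
below it, are floored at 0.001 s.  C = 1 − catch probability is a known
task constant.  `TI = D_ti/κ`; the default D_ti = 25 μL gives median
initiation times of a few seconds to ~20 s at the default κ range, matching
the seconds-to-tens-of-seconds latencies typical of self-paced rodent tasks.

Observation noise is log-normal with *constant variance on the linear
scale*: σ² = ln(1 + v/m²), μ = ln m − σ²/2, so the distribution's mean is
the model prediction and its variance is v (8 s² wait, 4 s² initiation).
This is the only reading that keeps both "log-normal" and "constant
variance" literal; the alternative (constant variance on the log scale) can
be swapped in through `lognormal_params` alone.  Synthetic agents opt out
iff the realized delay exceeds a noisy willingness-to-wait drawn from this
distribution around the predicted wait time — the minimal generative rule
consistent with the wait-time model; catch trials always end in opt-out.

## Fitting

The likelihood uses catch-trial wait times only: opt-outs on rewarded-delay
trials are censored observations and a full censoring likelihood is out of
scope.  Fitting is multi-start L-BFGS-B within bounds, each start polished
with Nelder-Mead (the clamp boundary makes the NLL kinked and creates flat
plateaus where every prediction is clamped), followed by per-parameter
1-D log-grid scans around the incumbent, which escape those zero-gradient
plateaus.  Starts are log-uniform for scale-like parameters; half the
κ-triple starts are sorted low ≤ mixed ≤ high.  Convergence: ftol 1e-10 on
the NLL.  `n_starts = 20` is the desk-scale default; 100 is available by
argument.  Cross-validation folds are contiguous blocks of whole sessions,
respecting the sequential state of the value models.  Free parameters:
(κ_low, κ_mixed, κ_high, D) for the inferential/belief-state models, plus λ
for the λ model; (κ_init, α₀, D) for the retrospective model.  H₀, C, τ and
the noise variances are constants.

Standard errors come from the inverse finite-difference Hessian and are
reported as missing when an estimate sits on a bound or a clamp plateau
(where the likelihood is locally flat and the Hessian uninformative).

## Analyses

Filter order: the session-local 2-SD trim exists only inside the session
inclusion criterion; analyses apply the pooled per-rat 1-SD wait filter,
the 99th-percentile initiation filter, then per-session detrending
(OLS of TI on z-scored trial number; residuals keep the session mean).
"Significantly positive" in the inclusion rule is read literally: the
session itself must be significantly positive (one-sided p < 0.05) and the
*next* session's slope merely positive.

Transition curves z-score wait times per (rat, volume) on catch trials and
initiation times per rat after detrending; offset 0 is the first trial of
the new block, violations occupy offsets but contribute only observed
values; per-rat curves use a 10-point centered moving average (shrinking at
the edges) before averaging over rats.  The overshoot metric is the maximum
post-transition value minus the value 20 trials in.  Logistic fits
(y = A + (D−A)/(1+exp(−C(x−x₀)))) are least squares with A ≤ D enforced by
parametrizing D − A ≥ 0, from a deterministic start grid.  The shuffle test
permutes rat labels, refits the group-average logistics and reports, per
parameter, the one-tailed upper p = (1 + #{null ≥ observed})/(n+1)
(exchangeable-exact) together with the null CDF at the observed difference;
the default is 500 shuffles.

History regressions use mixed blocks only, log2 offers, an intercept, and
listwise deletion of rows whose lag window crosses a block boundary.  The
wait regression includes the current offer and uses offered volumes on every
trial, violations included; the initiation regression uses the previous 9
offers only, with violation and catch trials entering as regressor value 0
(log2 of the received "reward" of 1 would be ill-defined at 0 μL; 0 is the
no-reward coding).  After OLS, the first coefficient whose 95% CI (OLS,
homoskedastic) covers 0 and all later ones are set to exactly 0, and
y = D·exp(−x/τ) is fit to the previous-trial kernel with x = 0 at the
one-back lag; an all-zero kernel reports τ = 0.  Rank-sum tests use the
exact distribution for n ≤ 20 and the continuity-corrected normal
approximation otherwise.

Learning dynamics pair consecutive sessions for the ratio measures, regress
each session's catch-trial waits on (current reward, block code 1/2/3) and
initiation times on the previous reward, smooth coefficients with a
5-session centered moving average, and blank outliers more than 3 scaled
MADs from a 5-point moving median.  Misinference flags are mixed-block
trials whose MAP block is not mixed, labeled by the misinferred side.

## What the simulator does and does not establish

The generator produces behavior *from the fitted models' own generative
assumptions* (log-normal noise, stationary parameters, the stated opt-out
rule).  Green tests therefore establish internal consistency — filters match
brute-force enumeration, fitting recovers generative parameters, model
comparison identifies the generator, the analysis statistics show the
predicted signatures — not that rats obey these models.  Real initiation
times are heavy-tailed, multi-process and satiety-modulated; the simulator
reproduces none of that beyond a linear drift the detrending step removes.
Cohort-level effect sizes from real animals are likewise out of reach of the
synthetic world and are not asserted anywhere.

## Known limitations

- No censored-likelihood treatment of non-catch opt-outs.
- No learning of the hazard rate, no step-function or blurred hazards, and
  no infinite-horizon steady-state value model.
- Belief-state and inferential models are near-identical whenever the
  posterior is concentrated, so the identifiability matrix is run over the
  inferential/retrospective pair only.
- Initiation-time models are never fit to data (the read-out is used for
  qualitative predictions); the TI scale parameter appears only in the
  synthetic recovery harness.
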