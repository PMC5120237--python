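# Methods

`perspect` models the selection of motivational smoking-cessation messages
as an explicit-feedback recommendation problem, simulates a two-arm
randomized messaging trial around it, and implements the trial's
statistical analysis. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish.

## Rating model

Ratings are 1–5 Likert responses to "this message influences me to quit".
The deployed predictor is Bayesian probabilistic matrix factorization
(BPMF): with the training mean μ removed,

    r_ij − μ ~ N(uᵢ·vⱼ, 1/α),
    uᵢ ~ N(μ_U, Λ_U⁻¹),   vⱼ ~ N(μ_V, Λ_V⁻¹),
    (μ_U, Λ_U), (μ_V, Λ_V) ~ Normal–Wishart(μ₀, β₀, W₀, ν₀).

Inference is by Gibbs sampling: each sweep draws both Normal–Wishart
hyperparameter pairs from their conjugate conditionals, then every user
factor from its conditional Gaussian given the item factors and that
user's ratings, then item factors symmetrically. Predictions are the
posterior mean of μ + uᵢ·vⱼ over retained samples, clipped to [1, 5].
Ratings are treated as real-valued throughout (the trial analysis averages
them); no ordinal likelihood is used.

Defaults: D = 10 latent dimensions, observation precision α = 2,
μ₀ = 0, β₀ = 2, W₀ = I, ν₀ = D, 50 burn-in sweeps, 200 retained samples —
the conventional settings for this model family on 1–5 scales; all
overridable. Mean-centering before factorization keeps the global offset
out of the factors, which is what makes the mean baselines a meaningful
floor. Test and simulation configurations use smaller samplers (D = 2,
25–75 samples) matched to the two-factor synthetic generator; those sizes
are stated where used.

**Cold start.** A user absent from training is handled by freezing all
non-user parameters: for each retained sample, the new user's factor is
the conditional Gaussian posterior mean given that sample's item factors,
hyperparameters, and the user's observed ratings — a ridge solve with
prior precision Λ_U^(s). With no observed ratings the factor falls back to
the prior mean (zero), so every prediction equals the training mean.

**Comparators.** MAP PMF is fitted by alternating ridge least squares
(deterministic; objective provably non-increasing; stop at relative change
< 1e-6 or 500 alternations; regularization λ = 0.5 per factor entry).
User-based K-NN uses Pearson similarity over co-rated items (minimum
overlap 3), the K = 20 most similar raters of the target message, and a
mean-centred weighted average, falling back to the message mean and then
the global mean; equal similarities resolve toward the lower user row
index for reproducibility. Global/message/user mean baselines complete the
bake-off floor.

## Strong-generalization protocol

Algorithm selection uses strong generalization: test users are entirely
absent from training. Users are split into 5 random folds (sizes differing
by at most one); per test fold, 3 train/validation repeats refit each
algorithm with a distinct derived seed; each test user's 20 ratings are
split into 5 folds of exactly 4 test ratings, and observed subsets of 5,
10, and 16 ratings are drawn from the complement (16 is the full
complement), so observed and test sets are disjoint by construction.
Metrics per (algorithm × fold × repeat × budget) cell: RMSE (pooled over
the cell's predictions), Kendall tau-b, and NDCG averaged over the
per-user 4-item lists, skipping lists where the statistic is undefined
(e.g. all-tied ratings).

NDCG uses exponential gain (2^rel − 1) with log2(rank+1) discount — the
dominant convention — at full list depth; ties in predicted scores are
broken pessimistically (lowest relevance first), so reported NDCG never
benefits from ties. Kendall tau-b applies the standard tie correction and
is reported as undefined when either vector is constant.

Hyperparameter grids are searched exhaustively on validation RMSE; if a
selected value sits at an endpoint of its range, the range is extended one
step in that direction and the search repeats (bounded number of rounds,
with a recorded warning if the boundary persists). Paired comparisons
against a reference algorithm use two-sided paired t tests over matched
cells with Bonferroni correction by the number of competitors;
zero-variance nonzero-mean differences are flagged as degenerate rather
than assigned a t value.

## Synthetic data

The generator emulates the shape of the bootstrap corpus and the trial:

* **Library**: 261 messages; 102 carry `MOTIVATIONAL_CONTENT` and 139
  `BEHAVIORAL_TREATMENT` (tag counts are exact by construction); each
  message gets one uniform primary readiness stage plus each further stage
  with probability 0.3; half the messages are expert-written (the true
  expert/peer split is not published).
* **Pilot ratings**: 846 users × 20 ratings over the 261 messages
  (16,920 ratings). Latent user and item vectors are i.i.d. N(0, 0.8²)
  per coordinate with D = 2; the continuous score is
  3.0 + u·v + N(0, 0.5²); the ordinal rating is the score rounded and
  clipped to {1..5} (simple, monotone, standard). The realized rating SD
  is ≈ 0.98, a realistic Likert spread. True factors are returned with
  every dataset so recovery tests never re-simulate.
* **Cohort**: 120 participants block-randomized in registration order
  with a (7 intervention : 3 comparison) composition per block of 10 —
  the published trial's realized 74:46 split is not reproducible by any
  fixed composition of 10 at a 2:1 target, so the composition is a
  parameter rather than a hard-coded split. Baseline readiness stages
  follow a configurable distribution concentrated on "thinking of
  quitting"; demographics follow the trial's marginal rates.
* **Arm effect**: each participant carries a scalar rating-propensity
  bias, N(0, 0.2²) plus `arm_effect` for the intervention arm. A mean
  shift of the latent preference *vector* would not move expected ratings
  (item factors are zero-mean), so the additive arm shift lives in this
  scalar component of the preference record. Follow-up outcome
  probabilities (one-day quit, moving up the readiness ladder, the seven
  influence questions) are logistic in `arm_effect` around comparison-arm
  base rates taken from the published trial (32% quit, 30% moved up,
  38–81% per-question agreement).
* **Preference heterogeneity**: cohort users' preference vectors default
  to N(0, 0.3²) per coordinate — deliberately smaller than the pilot's
  0.8. `arm_effect` is the simulator's controlled effect size: with it at
  zero the two arms' daily-rating distributions must be exchangeable for
  the trial analysis to be calibration-valid, yet the recommender must
  still have preference signal to exploit. At 0.3 the policy's selection
  advantage is reliably positive on true latent scores (the policy-value
  check) while moving daily means by only ~0.2 — well below the distance
  from the baseline mean (≈3.0) to the agree threshold (4.0) — so null
  trials do not reject. With the pilot's 0.8 the selection effect alone
  crosses the threshold and every null trial would "detect" an arm
  difference, conflating policy value with the randomized effect.

Consequences worth stating plainly: simulated comparison-arm daily means
sit near 3.0 and essentially never reach the agree threshold, unlike the
published trial where the comparison arm agreed on 44% of days; passing
the end-to-end checks therefore shows that the machinery detects a
controlled arm effect and stays calibrated under the null, not that the
simulator reproduces the published trial's operating point. The generator
also omits real-data features: rater attrition within the 30 days,
day-of-week and novelty effects, repeated-exposure drift, and any
dependence of ratings on demographics.

## Scheduler

Both arms draw from the same library and the same stage filter (the
five-level readiness ladder; the original rule-based system's tailoring
granularity is not published, so the ladder is used uniformly). The
recommender arm ranks stage-matched unsent messages by predicted rating —
re-inferring the user's factors from all of their ratings so far after
every rating (full re-inference is cheap at D ≤ 10 and 30 ratings) — and
breaks predicted-rating ties toward the lowest message id. The comparator
draws a seeded-uniform unsent stage-matched message and ignores ratings;
how the original system chose among stage-matched messages is not
published, and this neutral, reproducible draw is the central comparator
assumption. When the stage-matched pool is exhausted the filter relaxes
to adjacent ladder levels outward, then to all unsent messages. No message
is ever sent twice; "day" is the message ordinal, not calendar time.

## Trial analysis

The primary endpoint is the daily rating: the mean of the ratings all of
an arm's participants gave at each message ordinal 1..30. A day "agrees"
when its daily mean is ≥ 4. Arms are compared by Pearson chi-square on
the agreed/not-agreed day counts — df = 1, **no continuity correction**,
which exactly reproduces the published p-values (.02/.07/.09/.70/.60)
from the published counts, whereas Yates-corrected values do not. Three
published influence rows (.35/.96/.42) are *not* reproduced by Pearson
chi-square on their printed counts; they are excluded from the checks and
the discrepancy is simply recorded. Day windows are compared by
two-sample Student t tests on the daily means, with days missing in either
arm excluded pairwise and the effective n reported. Influence responses
are dichotomized at ≤3 vs ≥4; readiness movement is a strictly greater
ladder level at follow-up. Displayed percentages round half away from
zero, matching the published presentation.

## Problem sizes and determinism

The bundled tests and the acceptance script run everything at sizes chosen
to exercise the full design while staying quick on one CPU: the
recommender benchmark uses 300 users × 100 messages × 20 ratings with a
75-sample/40-burn-in sampler; trial simulations use a 200-user pilot and a
30-sample model. Every stochastic component takes an explicit seed; a
pipeline run fans one base seed out to per-stage seeds by fixed offsets,
writes its resolved configuration and a config-hash manifest next to its
outputs, and reruns byte-identically.

## Known limitations

* The recommender benchmark's held-out RMSE cannot approach the Gaussian
  noise SD alone: rounding continuous scores to integer ratings adds
  ≈ 1/12 variance, so the attainable floor is ≈ √(0.25 + 1/12) ≈ 0.577
  before any estimation error, and 5–16 observed ratings with D = 2 leave
  cells at ≈ 0.60–0.69. Comparisons against the mean baselines, which
  face the same floor, are the meaningful yardstick.
* Implicit feedback (e-mail return visits) and message-metadata regression
  are out of scope; the engine uses explicit ratings only.
* The comparator's within-stage selection rule is an assumption (seeded
  uniform), not a published fact.
* Only the active user's parameters update during a session; the item
  factors and other users' factors stay frozen at their pilot posterior.
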