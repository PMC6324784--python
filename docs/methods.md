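# Methods

## The experiment being modelled

A stated-preference survey in which each respondent completes five choice
tasks; each task presents two hypothetical community-based health insurance
(CBHI) benefit packages alongside the current (status-quo) scheme, and the
respondent ranks the three from most to least preferred (1, 2, 3). A
package is a profile over seven attributes; the monthly premium is the only
pecuniary attribute and its LAK amount depends on the household-size bracket
{1, 2–4, 5–7, 8+}:

| design level | 1 member | 2–4 | 5–7 | 8+ |
|---|---|---|---|---|
| p1 (−2,000) | 10,000 | 18,000 | 23,000 | 26,000 |
| p2 (current) | 12,000 | 20,000 | 25,000 | 28,000 |
| p3 (+2,000) | 14,000 | 22,000 | 27,000 | 30,000 |
| p4 (+4,000) | 16,000 | 24,000 | 29,000 | 32,000 |

The six non-pecuniary attributes (reference level = status quo, in
italics): medical consultations (No / *Yes*), hospitalizations (No / *Yes*),
traffic accidents (*No* / Yes), pharmaceuticals (*Partly* / Fully),
transportation (*No* / One way / Round trip), prepaid discount
(*No* / 5% / 10%). The level sets give 576 profiles, 575 excluding the
status quo.

## Design generation

- **Pair universe.** Unordered pairs of distinct non-status-quo profiles,
  C(575, 2) = 165,025, sampled uniformly without replacement. 575 pairs are
  chunked sequentially into 115 choice sets of five tasks; the sampling
  order is already exchangeable, so sequential chunking is equivalent to any
  random blocking.
- **Display conventions.** The left/right position of the two hypothetical
  alternatives is randomized per task; the status quo is always shown last
  (its role is fixed, so is its position). Each respondent receives one
  uniformly random attribute display order, constant across their five
  tasks and deterministic in (seed, respondent id).
- **Seeding.** One master seed drives tagged `numpy.random.SeedSequence`
  substreams (pair sampling, attribute orders, population draw, choice
  noise), so each stage is independently reproducible and re-running a
  pipeline with the same configuration is byte-identical.

## Synthetic respondents

No respondent-level data are distributed with the package; a generator
stands in for the survey so that every estimator can be checked against
analytic truth. Choices follow a rational random-utility process additive
in money:

    U_i(profile) = base_value_i + Σ part-worths of non-reference levels
                   − realized premium + ε,   ε ~ N(0, noise_scale²) i.i.d.
                   per (respondent, task, alternative).

The implied WTP of respondent *i* for a profile over the status quo is the
part-worth sum plus the current premium; the generator writes it per row
(`true_wtp`) so recovery tests have closed-form targets. Monotonicity in
money holds by construction; continuity holds because part-worths are
continuous draws.

Default study conditions (all LAK/household/month; overridable via
`PopulationModel`):

- 580 respondents, assigned round-robin to the 115 choice sets (≈5 per
  set); 5 tasks × 2 alternatives each → 5,800 estimator rows.
- Household-bracket shares (0.05, 0.30, 0.45, 0.20) over {1, 2–4, 5–7, 8+}.
  The target population's true shares are unknown here; these are a
  plausible rural-household stand-in and the WTP bound exposes them as an
  explicit, overridable input.
- Part-worth means: consultations No −15,000; hospitalizations No −20,000;
  traffic accidents Yes +8,000; pharmaceuticals Fully +5,000; transportation
  One way +4,000 / Round trip +9,000; prepaid discount 5% +1,000 / 10%
  +2,000. Chosen once on substantive grounds: losing either core coverage
  hurts more than any single add-on helps, transport coverage is the most
  valuable add-on (transport costs are a known enrollment barrier in rural
  settings), and discounts are worth roughly their cash value at these
  premiums. Heterogeneity is independent normal per level with SDs of
  roughly 40% of the mean magnitude; normality is a convenience, not an
  assumption of the estimators, which are nonparametric.
- Choice noise scale 3,000: comparable to the 2,000-LAK premium spacing, so
  choice probabilities stay well inside (0, 1).
- `noise_scale=0` is a first-class mode in which every choice is an exact
  utility comparison (used by the oracle tests); exact utility ties are
  broken by a seeded uniform jitter of amplitude 1e−9 LAK, far below any
  meaningful utility difference.

What the generator does **not** emulate: item non-response, interviewer or
ordering effects (the independence assumption holds by construction),
fatigue across tasks, non-additive preferences, or correlation between
part-worths and household size. Passing recovery tests therefore show that
the estimators are correct under the model's own assumptions — not that
those assumptions hold in any particular field sample.

## Estimation

- **AMCE.** Linear probability model of the binary outcome on one indicator
  per non-reference level plus an intercept (11 indicators for the default
  table), fit by OLS (statsmodels). Status-quo rows are never regression
  rows; they only define the external outcome. Covariance is the
  cluster-robust sandwich with respondents as clusters and CR1 scaling
  G/(G−1)·(N−1)/(N−K) (the common applied default; `correction="CR0"`
  switches it off). Confidence intervals are normal-approximation
  ±1.96·SE; no multiple-testing adjustment. `diff_in_means` implements the
  one-cell nonparametric estimator and serves as the independent oracle: on
  balanced factorial data the two agree to numerical precision.
- **WTP distribution.** F̂(pₖ) = 1 − mean(Y_external | premium level k) on
  the boundary-filtered subsample (consultations = Yes and hospitalizations
  = Yes, ≈¼ of a randomized design — the other attributes' baselines
  already equal the status quo). Conditioning uses the design level 1..4,
  not the realized LAK amount, so brackets pool within a level. Interval
  masses are successive differences and telescope to 1 exactly; SEs come
  from the same cluster-robust covariance via linear contrasts.
- **Negative masses.** Raw estimates may be locally non-monotone; they are
  reported raw. An optional isotonic (pool-adjacent-violators) projection
  (`isotonic=True`) restores monotonicity; it is off by default because the
  identification itself does not require it. Cumulative approval rates clip
  negative masses to zero by default so a noisy dip cannot raise approval
  above an earlier threshold.
- **Lower-bound mean.** μ̲ values each interval at its lower endpoint (zero
  below p₁) and weights premium amounts by bracket shares; with a single
  bracket this reduces to the scalar inner product Σ cⱼ·massⱼ₊₁. Bracket
  shares default to the empirical shares of the respondents in the data and
  are overridable for sensitivity analysis.

## Recovery studies and their truth

The replication study (200 surveys at full scale: fresh design, population
and noise each time) compares each fitted AMCE to analytic truth within two
cluster-robust SEs. With noise scale *s*, a respondent prefers a profile to
the status quo with probability Φ((WTP − premium)/(s·√2)). Two oracles are
provided:

- `analytic_external_amce`: the population AMCE, marginal over the uniform
  randomization distribution of the other attributes.
- `design_conditional_amce`: the least-squares projection of the known
  per-row choice probabilities onto the realized design matrix.

Coverage is assessed against the **design-conditional** target. A single
realized design contributes only 1,150 profile draws shared by all
respondents, so the uniform-marginal truth differs from the regression's
estimand by the design's own finite-sample wobble — a component
cluster-robust SEs (which condition on the realized randomization, as is
standard in conjoint analysis) do not claim to cover. Against the
conditional target, coverage is mildly conservative (≈99%), because the
cluster sandwich also absorbs between-respondent heterogeneity.

Other validation problem sizes, chosen to make Monte-Carlo error small
relative to the tolerances while keeping the default test run fast: the
uniform-WTP CDF recovery uses 2,000 single-bracket respondents (binomial SE
≤ 0.011 per threshold against a closed-form uniform CDF); balanced-factorial
oracle-equivalence fixtures use 4 × 576 rows; frequency checks on orders and
bracket draws use 10,000 and 100,000 draws against 99% multinomial bands.

## Known limitations

- The WTP bound is a lower bound only; no upper bound is identified without
  assumptions on the right tail, and none is attempted.
- The boundary filter discards ≈¾ of the data, so WTP quantities have
  noticeably wider intervals than the AMCEs.
- Interval masses are valued at lower endpoints; μ̲ is therefore sensitive
  to the bracket shares and to how much mass sits in the open top interval.
- The pair universe is the package's own convention (unordered pairs of
  distinct non-status-quo profiles); other conventions would change nothing
  materially, but exact pair counts differ between formulations.
- `fit_amce` presumes the design matrix is full rank; heavily filtered or
  degenerate designs raise an estimation error naming the collinear
  columns rather than silently dropping them.
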