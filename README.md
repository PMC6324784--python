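# cbhi-conjoint

Design, simulation and analysis of a **fully randomized conjoint experiment**
on community-based health insurance (CBHI) benefit packages, with
nonparametric identification of the **willingness-to-pay (WTP) distribution**
and a lower bound on its mean.

The package is for health economists and survey methodologists who run
discrete choice experiments on insurance demand: it generates the randomized
choice tasks, simulates ranked responses from a rational random-utility
population (so every estimator can be validated against known truth),
estimates causal attribute effects on enrollment probabilities, and bounds
the mean WTP — all with respondent-clustered uncertainty.

## The design and the estimands

A hypothetical CBHI scheme is a profile over seven attributes: a monthly
premium (four levels per household-size bracket, in Lao kip, LAK) and six
benefit-package components (coverage for medical consultations,
hospitalizations, traffic accidents, pharmaceuticals, transportation, and a
one-year prepaid discount). The level sets give 4·2·2·2·2·3·3 = 576 profiles;
dropping the status-quo profile leaves 575. The design samples 575 unordered
pairs of distinct profiles uniformly and chunks them into 115 choice sets of
five tasks; each task asks a respondent to rank the two hypothetical schemes
and the status quo (580 respondents × 5 tasks × 2 alternatives = 5,800
estimator rows).

Because all levels are randomized independently, the **average marginal
component effect** (AMCE) of moving attribute *l* from level *a₀* to *a₁* is
identified by a difference in conditional means of the binary choice
outcome,

&nbsp;&nbsp;&nbsp;&nbsp;π̂ˡ(a₁, a₀) = Ȳ | Aₗ = a₁ − Ȳ | Aₗ = a₀,

and estimated jointly for all levels by the linear probability model
E[Y] = β₀ + β_c·I_c + Σₗ βₗ·Iₗ with the status-quo levels as reference
categories and CR1 cluster-robust standard errors (clusters = respondents).
Two outcomes are supported: *external* (preferred to the status quo) and
*internal* (preferred to the other hypothetical alternative).

With utility monotone in money, the external outcome also identifies the
marginal WTP distribution at the four premium thresholds p₁ < p₂ < p₃ < p₄:

&nbsp;&nbsp;&nbsp;&nbsp;F̂(c) = 1 − Ȳ | C = c,

whose successive differences are the masses of the five intervals [0, p₁],
(p₁, p₂], (p₂, p₃], (p₃, p₄], (p₄, ∞). Valuing each interval at its lower
endpoint (zero below p₁) and weighting premium amounts by household-size
bracket shares s_b gives the lower bound on mean WTP

&nbsp;&nbsp;&nbsp;&nbsp;μ̲ = Σ_b s_b Σⱼ premium(pⱼ, b) · mass(interval j+1).

Identification requires the boundary assumption (WTP ≥ 0), so the analysis
subsample keeps only rows whose consultation and hospitalization coverage
are at the status-quo level.

## Worked example

```python
import numpy as np
import cbhi_conjoint as cc

specs, schedule = cc.default_attributes(), cc.default_schedule()
plan = cc.randomize_design(specs, n_pairs=575, tasks_per_set=5, seed=1)
respondents, obs = cc.simulate_survey(plan, cc.PopulationModel(), schedule, seed=1)
print(f"{plan.n_sets} choice sets, {len(obs)} hypothetical-alternative observations")

amce = cc.fit_amce(obs, outcome="external")
top = amce.summary_.query("~is_reference").sort_values("estimate")
print(top[["attribute", "level", "estimate", "se"]].round(3).to_string(index=False))

west = cc.WtpEstimator().fit(obs)
print("interval masses:", np.round(west.interval_masses_, 3))
print(f"mu_lower = {west.mu_lower_:,.0f} LAK/month on n = {west.n_obs_} boundary-filtered rows")
cmp = west.compare_levels("transportation", "No", "Round trip")
print(f"round-trip transport raises top-bin approval by "
      f"{100*cmp.diff[3]:.1f} pp (SE {100*cmp.diff_se[3]:.1f})")
```

prints

```
115 choice sets, 5800 hypothetical-alternative observations
        attribute      level  estimate    se
 hospitalizations         No    -0.492 0.012
    consultations         No    -0.370 0.011
          premium         p4    -0.082 0.013
          premium         p3    -0.062 0.012
          premium         p1     0.043 0.013
 prepaid_discount        10%     0.046 0.011
 prepaid_discount         5%     0.047 0.011
   transportation    One way     0.093 0.011
  pharmaceuticals      Fully     0.095 0.009
traffic_accidents        Yes     0.161 0.011
   transportation Round trip     0.186 0.013
interval masses: [ 0.038  0.016  0.127 -0.036  0.855]
mu_lower = 25,718 LAK/month on n = 1454 boundary-filtered rows
round-trip transport raises top-bin approval by 23.1 pp (SE 4.5)
```

Reading the output: removing hospitalization coverage cuts the probability
of choosing a scheme over the status quo by 49 percentage points, while the
+4,000-LAK premium level (p4) cuts it by 8 points; the raw interval masses
telescope to one (a slightly negative mass is ordinary sampling noise and is
reported raw — `WtpEstimator(isotonic=True)` projects it away); and for this
synthetic population the mean WTP for an improved scheme is at least
≈25,700 LAK/household/month.

A command-line interface mirrors the stages:

```
cbhi-conjoint design --pairs 575 --tasks-per-set 5 --seed 1 --out plan.csv
cbhi-conjoint simulate --plan plan.csv --seed 1 --out responses.csv
cbhi-conjoint amce --data responses.csv --outcome external --out amce.csv
cbhi-conjoint wtp --data responses.csv --out wtp.csv
cbhi-conjoint run            # full pipeline with figures
cbhi-conjoint validate --data responses.csv
```

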