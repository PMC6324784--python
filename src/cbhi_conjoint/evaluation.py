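"""Estimator-recovery studies against analytic truth.

The simulator knows every respondent's part-worths, so the estimands have
closed forms: with normal choice noise of scale ``s`` per alternative, the
probability that a respondent prefers a profile to the status quo is
``Phi((WTP - premium) / (s * sqrt(2)))`` (the difference of two independent
noise draws has scale ``s * sqrt(2)``); at zero noise it is the indicator.
Averaging those probabilities over the profile universe — uniformly over the
other attributes' levels, exactly as the randomization distributes them —
gives the true AMCE of each level.  These enumeration oracles never touch
the regression code they are used to check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .amce import AmceEstimator
from .attributes import (
    AttributeSpec,
    CURRENT_PREMIUM_LEVEL,
    PremiumSchedule,
    default_attributes,
    default_schedule,
    premium_spec,
)
from .design import randomize_design
from .simulate import (
    PopulationModel,
    Respondent,
    _nonreference_keys,
    _premium_level,
    simulate_survey,
)
from .design import enumerate_hypothetical_profiles


def analytic_external_amce(
    respondents: Sequence[Respondent],
    specs: Sequence[AttributeSpec] | None = None,
    schedule: PremiumSchedule | None = None,
    noise_scale: float = 0.0,
) -> pd.Series:
    """True external-choice AMCE per non-reference level for a given
    population, by enumerating the 575 hypothetical profiles."""
    specs = tuple(specs) if specs is not None else default_attributes()
    schedule = schedule if schedule is not None else default_schedule()
    profiles = enumerate_hypothetical_profiles(specs)
    keys = _nonreference_keys(specs)

    D = np.zeros((len(profiles), len(keys)))
    plevels = np.zeros(len(profiles), dtype=int)
    for i, prof in enumerate(profiles):
        plevels[i] = _premium_level(prof, specs)
        for s, level in zip(specs, prof.levels):
            if not s.pecuniary and level != s.reference_level:
                D[i, keys.index((s.name, level))] = 1.0

    PW = np.array([[r.part_worths[k] for k in keys] for r in respondents])
    bidx = np.array([schedule.bracket_index(r.size_bracket) for r in respondents])
    current = schedule.as_array[CURRENT_PREMIUM_LEVEL - 1][bidx]
    wtp = PW @ D.T + current[:, None]                    # (n, P)
    premium = schedule.as_array[plevels - 1][:, :][:, bidx].T
    if noise_scale > 0:
        probs = stats.norm.cdf((wtp - premium) / (noise_scale * np.sqrt(2.0)))
    else:
        probs = (wtp > premium).astype(float)
    mean_by_profile = probs.mean(axis=0)                 # (P,)

    ps = premium_spec(specs)
    truth = {}
    for s in specs:
        if s.pecuniary:
            ref_mask = plevels == (ps.levels.index(s.reference_level) + 1)
            for level in s.nonreference_levels:
                mask = plevels == (s.levels.index(level) + 1)
                truth[f"{s.name}[{level}]"] = (
                    mean_by_profile[mask].mean() - mean_by_profile[ref_mask].mean())
        else:
            for level in s.nonreference_levels:
                j = keys.index((s.name, level))
                mask = D[:, j] == 1.0
                # reference mask: none of this attribute's non-ref dummies set
                own = [keys.index((s.name, l)) for l in s.nonreference_levels]
                ref_mask = D[:, own].sum(axis=1) == 0.0
                truth[f"{s.name}[{level}]"] = (
                    mean_by_profile[mask].mean() - mean_by_profile[ref_mask].mean())
    return pd.Series(truth)


def design_conditional_amce(
    observations: pd.DataFrame,
    specs: Sequence[AttributeSpec] | None = None,
    noise_scale: float = 0.0,
) -> pd.Series:
    """The estimand of the AMCE regression conditional on the realized
    design and population: the least-squares projection of the known
    per-row choice probabilities Phi((WTP - premium)/(s*sqrt(2))) onto the
    dummy design matrix.

    Cluster-robust SEs estimate the sampling variance around exactly this
    conditional target (inference in conjoint analysis is conditional on the
    realized randomization), so recovery checks compare against it rather
    than the uniform-marginal truth, which differs by the design's own
    finite-sample wobble.
    """
    from .amce import encode_dummies

    specs = tuple(specs) if specs is not None else default_attributes()
    X = encode_dummies(observations, specs).to_numpy()
    z = (observations["true_wtp"] - observations["realized_premium"]).to_numpy()
    if noise_scale > 0:
        p = stats.norm.cdf(z / (noise_scale * np.sqrt(2.0)))
    else:
        p = (z > 0).astype(float)
    beta, *_ = np.linalg.lstsq(X, p, rcond=None)
    names = encode_dummies(observations.head(1), specs).columns[1:]
    return pd.Series(beta[1:], index=list(names))


@dataclass
class RecoveryStudy:
    """Per-(replication, level) recovery results and coverage summaries."""

    records: pd.DataFrame  # columns: rep, level, estimate, se, truth, covered

    @property
    def coverage_by_level(self) -> pd.Series:
        return self.records.groupby("level", sort=False)["covered"].mean()

    @property
    def min_coverage(self) -> float:
        return float(self.coverage_by_level.min())

    @property
    def mean_coverage(self) -> float:
        return float(self.records["covered"].mean())


def uniform_wtp_cdf_study(seed: int = 0, n_respondents: int = 2000,
                          wtp_high: float = 32_000.0):
    """Simulate a single-bracket (2-4 members) survey whose WTP is exactly
    Uniform(0, wtp_high) and estimate the marginal CDF.

    Returns ``(distribution, expected)`` where ``expected[k-1]`` is the
    closed-form CDF value p_k / wtp_high at the bracket's four thresholds.
    The uniform draw enters through a single part-worth (traffic-accident
    coverage, fixed to "Yes" in every alternative) so choices still run
    through the full ranking machinery at zero noise.
    """
    from .design import ChoiceTask, DesignPlan, status_quo_profile
    from .simulate import Respondent, build_observations, rank_task
    from .wtp import boundary_filter, marginal_cdf

    specs = default_attributes()
    schedule = default_schedule()
    bracket = "2-4"
    current = schedule.current(bracket)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 5)))

    def prof(premium_label):
        levels = {s.name: s.reference_level for s in specs}
        levels.update(premium=premium_label, traffic_accidents="Yes")
        from .design import Profile

        return Profile(tuple(levels[s.name] for s in specs))

    tasks = [
        ChoiceTask(0, 0, prof("p1"), prof("p2"), status_quo_profile(specs)),
        ChoiceTask(1, 0, prof("p3"), prof("p4"), status_quo_profile(specs)),
    ]
    plan = DesignPlan(specs=specs, choice_sets=[tasks], seed=seed)
    zero_pw = {
        ("consultations", "No"): 0.0, ("hospitalizations", "No"): 0.0,
        ("traffic_accidents", "Yes"): 0.0, ("pharmaceuticals", "Fully"): 0.0,
        ("transportation", "One way"): 0.0, ("transportation", "Round trip"): 0.0,
        ("prepaid_discount", "5%"): 0.0, ("prepaid_discount", "10%"): 0.0,
    }
    respondents, rankings = [], []
    for i in range(n_respondents):
        pw = dict(zero_pw)
        pw[("traffic_accidents", "Yes")] = float(rng.uniform(-current, wtp_high - current))
        r = Respondent(id=i, size_bracket=bracket, base_value=0.0,
                       part_worths=pw, noise_scale=0.0)
        respondents.append(r)
        for task in tasks:
            rankings.append(rank_task(r, task, specs, schedule, rng=rng))
    obs = build_observations(rankings, plan, respondents, schedule)
    dist = marginal_cdf(boundary_filter(obs, specs))
    thresholds = np.array([schedule.amount(k, bracket) for k in (1, 2, 3, 4)])
    return dist, thresholds / wtp_high


def amce_recovery_study(
    n_reps: int = 200,
    seed: int = 0,
    model: PopulationModel | None = None,
    n_pairs: int = 575,
    tasks_per_set: int = 5,
) -> RecoveryStudy:
    """Replicate the full survey ``n_reps`` times (fresh design, population
    and noise each time), fit the external AMCE, and check each estimate
    against the analytic truth of its replication's population within two
    cluster-robust SEs."""
    model = model if model is not None else PopulationModel()
    specs = default_attributes()
    schedule = default_schedule()
    rep_seeds = (
        np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32)
        % np.uint32(2**31)
    )
    rows = []
    for rep, s in enumerate(int(x) for x in rep_seeds):
        plan = randomize_design(specs, n_pairs, tasks_per_set, seed=s)
        respondents, obs = simulate_survey(plan, model, schedule, seed=s)
        est = AmceEstimator(outcome="external", specs=specs).fit(obs)
        truth = design_conditional_amce(obs, specs, noise_scale=model.noise_scale)
        for level in est.coef_.index:
            b, se, t = est.coef_[level], est.se_[level], truth[level]
            rows.append({"rep": rep, "level": level, "estimate": b, "se": se,
                         "truth": t, "covered": abs(b - t) <= 2.0 * se})
    return RecoveryStudy(records=pd.DataFrame(rows))
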