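"""Synthetic respondents and ranked choice outcomes.

The generator emulates the stated-preference survey the estimators were built
for: 580 household heads, each assigned to one choice set of five tasks, each
task ranking two hypothetical benefit packages against the status-quo scheme.
Choices follow a rational random-utility process that is additive in money:

    U_i(profile) = base_value_i + sum of part-worths of the profile's
                   non-reference levels - realized premium + noise,

with all quantities in LAK/household/month.  Because the premium enters with
coefficient -1, utility is monotone decreasing in money by construction, and
the respondent's willingness to pay (WTP) for a profile over the status quo
has the closed form

    WTP_i(profile) = sum of part-worths + current premium,

which the generator exposes per observation (column ``true_wtp``) so that
estimator-recovery tests can compare against analytic truth.

Part-worths are drawn from independent normals per level (heterogeneity
across respondents); noise is i.i.d. normal per (respondent, task,
alternative).  A zero-noise mode (``noise_scale=0``) makes every choice an
exact utility comparison for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .attributes import (
    AttributeSpec,
    PremiumSchedule,
    BRACKETS,
    CURRENT_PREMIUM_LEVEL,
    premium_spec,
    validate_attributes,
)
from .design import ChoiceTask, DesignPlan, Profile, STATUS_QUO_ID
from .errors import DataError, ModelError

_POPULATION_STREAM = 3
_NOISE_STREAM = 4

#: Amplitude of the uniform jitter used only to break exact utility ties.
_TIE_JITTER = 1e-9


@dataclass
class Respondent:
    """One synthetic household head.

    ``part_worths`` maps (attribute, level) to the LAK increment of that
    non-reference level over the attribute's status-quo level; reference
    levels implicitly contribute zero.  ``base_value`` is the valuation of
    the status-quo benefit package; it cancels from every within-task
    comparison but anchors the utility scale.
    """

    id: int
    size_bracket: str
    base_value: float
    part_worths: dict[tuple[str, str], float]
    noise_scale: float = 0.0


@dataclass
class PopulationModel:
    """Sampling distribution of synthetic respondents.

    Defaults are the package's standard survey conditions: 580 respondents,
    bracket shares (0.05, 0.30, 0.45, 0.20) over household sizes
    {1, 2-4, 5-7, 8+}, normal part-worth heterogeneity around means chosen so
    that removing consultation or hospitalization coverage hurts more than
    any single hypothetical add-on helps, transport coverage is the most
    valuable add-on, and discounts are worth roughly their cash value.
    Noise of 3,000 LAK gives choice probabilities well inside (0, 1) at the
    2,000-LAK premium spacing.
    """

    n_respondents: int = 580
    bracket_shares: dict[str, float] = field(
        default_factory=lambda: {"1": 0.05, "2-4": 0.30, "5-7": 0.45, "8+": 0.20}
    )
    part_worth_means: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("consultations", "No"): -15_000.0,
            ("hospitalizations", "No"): -20_000.0,
            ("traffic_accidents", "Yes"): 8_000.0,
            ("pharmaceuticals", "Fully"): 5_000.0,
            ("transportation", "One way"): 4_000.0,
            ("transportation", "Round trip"): 9_000.0,
            ("prepaid_discount", "5%"): 1_000.0,
            ("prepaid_discount", "10%"): 2_000.0,
        }
    )
    part_worth_sds: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("consultations", "No"): 6_000.0,
            ("hospitalizations", "No"): 8_000.0,
            ("traffic_accidents", "Yes"): 3_200.0,
            ("pharmaceuticals", "Fully"): 2_000.0,
            ("transportation", "One way"): 1_600.0,
            ("transportation", "Round trip"): 3_600.0,
            ("prepaid_discount", "5%"): 400.0,
            ("prepaid_discount", "10%"): 800.0,
        }
    )
    base_value_mean: float = 30_000.0
    base_value_sd: float = 10_000.0
    noise_scale: float = 3_000.0

    def validate(self) -> "PopulationModel":
        if self.n_respondents < 1:
            raise ModelError("n_respondents must be positive")
        shares = np.array(list(self.bracket_shares.values()), dtype=float)
        if (shares < 0).any() or not np.isclose(shares.sum(), 1.0):
            raise ModelError(f"bracket shares must be nonnegative and sum to 1, got {self.bracket_shares}")
        for key, sd in self.part_worth_sds.items():
            if sd < 0:
                raise ModelError(f"negative part-worth sd for {key}")
        if self.base_value_sd < 0 or self.noise_scale < 0:
            raise ModelError("scales must be nonnegative")
        return self


def default_population_model(**overrides) -> PopulationModel:
    return replace(PopulationModel(), **overrides).validate()


# ---------------------------------------------------------------------------
# config round trip (YAML-friendly: part-worth keys nested attribute -> level)

def population_model_to_config(model: PopulationModel) -> dict:
    def nest(d: Mapping[tuple[str, str], float]) -> dict:
        out: dict[str, dict[str, float]] = {}
        for (attr, level), v in d.items():
            out.setdefault(attr, {})[level] = float(v)
        return out

    return {
        "n_respondents": model.n_respondents,
        "bracket_shares": dict(model.bracket_shares),
        "part_worth_means": nest(model.part_worth_means),
        "part_worth_sds": nest(model.part_worth_sds),
        "base_value_mean": model.base_value_mean,
        "base_value_sd": model.base_value_sd,
        "noise_scale": model.noise_scale,
    }


def population_model_from_config(cfg: dict) -> PopulationModel:
    def flatten(d: Mapping[str, Mapping[str, float]]) -> dict[tuple[str, str], float]:
        return {(a, l): float(v) for a, levels in d.items() for l, v in levels.items()}

    model = PopulationModel(
        n_respondents=int(cfg["n_respondents"]),
        bracket_shares={str(k): float(v) for k, v in cfg["bracket_shares"].items()},
        part_worth_means=flatten(cfg["part_worth_means"]),
        part_worth_sds=flatten(cfg["part_worth_sds"]),
        base_value_mean=float(cfg["base_value_mean"]),
        base_value_sd=float(cfg["base_value_sd"]),
        noise_scale=float(cfg["noise_scale"]),
    )
    return model.validate()


def save_population_model(path, model: PopulationModel) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(population_model_to_config(model), fh, sort_keys=False)


def load_population_model(path) -> PopulationModel:
    with open(path) as fh:
        return population_model_from_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# population and utilities

def draw_population(model: PopulationModel, seed: int = 0) -> list[Respondent]:
    """Draw ``model.n_respondents`` respondents, reproducibly in ``seed``."""
    model.validate()
    rng = np.random.default_rng(np.random.SeedSequence((seed, _POPULATION_STREAM)))
    brackets = list(model.bracket_shares)
    shares = np.array([model.bracket_shares[b] for b in brackets], dtype=float)
    bracket_idx = rng.choice(len(brackets), size=model.n_respondents, p=shares)
    base = rng.normal(model.base_value_mean, model.base_value_sd, model.n_respondents)
    keys = list(model.part_worth_means)
    means = np.array([model.part_worth_means[k] for k in keys])
    sds = np.array([model.part_worth_sds.get(k, 0.0) for k in keys])
    pw = rng.normal(means, sds, size=(model.n_respondents, len(keys)))
    return [
        Respondent(
            id=i,
            size_bracket=brackets[bracket_idx[i]],
            base_value=float(base[i]),
            part_worths={k: float(pw[i, j]) for j, k in enumerate(keys)},
            noise_scale=model.noise_scale,
        )
        for i in range(model.n_respondents)
    ]


def _premium_level(profile: Profile, specs: Sequence[AttributeSpec]) -> int:
    ps = premium_spec(specs)
    if ps is None:
        raise DataError("attribute vocabulary has no pecuniary (premium) attribute")
    return ps.levels.index(profile.level_of(specs, ps.name)) + 1


def valuation(respondent: Respondent, profile: Profile, specs: Sequence[AttributeSpec]) -> float:
    """base_value plus the part-worths of the profile's non-reference,
    non-pecuniary levels."""
    total = respondent.base_value
    for s, level in zip(specs, profile.levels):
        if s.pecuniary or level == s.reference_level:
            continue
        try:
            total += respondent.part_worths[(s.name, level)]
        except KeyError:
            raise ModelError(
                f"respondent {respondent.id} has no part-worth for "
                f"({s.name!r}, {level!r})"
            ) from None
    return total


def utility(
    respondent: Respondent,
    profile: Profile,
    specs: Sequence[AttributeSpec],
    schedule: PremiumSchedule,
    noise: float = 0.0,
) -> float:
    """LAK-net utility: valuation - realized premium + noise.

    For a status-quo-equivalent profile this reduces to
    base_value - current premium (+ noise).
    """
    level = _premium_level(profile, specs)
    premium = schedule.amount(level, respondent.size_bracket)
    return valuation(respondent, profile, specs) - premium + noise


def true_wtp(
    respondent: Respondent,
    profile: Profile,
    specs: Sequence[AttributeSpec],
    schedule: PremiumSchedule,
) -> float:
    """The maximum premium at which ``respondent`` still prefers ``profile``
    to the status quo: part-worth sum plus the current premium."""
    delta = valuation(respondent, profile, specs) - respondent.base_value
    return delta + schedule.current(respondent.size_bracket)


# ---------------------------------------------------------------------------
# ranking

@dataclass(frozen=True)
class RankingRecord:
    """Ranks 1 (most preferred) .. 3 over (alt A, alt B, status quo)."""

    respondent_id: int
    task_id: int
    ranks: dict[str, int]  # keys "A", "B", "SQ"

    def __post_init__(self) -> None:
        if sorted(self.ranks.values()) != [1, 2, 3] or set(self.ranks) != {"A", "B", STATUS_QUO_ID}:
            raise DataError(f"ranks must be a bijection of {{A, B, SQ}} onto {{1,2,3}}, got {self.ranks}")


def rank_task(
    respondent: Respondent,
    task: ChoiceTask,
    specs: Sequence[AttributeSpec],
    schedule: PremiumSchedule,
    rng: np.random.Generator | None = None,
) -> RankingRecord:
    """Rank the three alternatives by descending utility.

    Noise (scale ``respondent.noise_scale``) is drawn i.i.d. per alternative;
    exact utility ties are broken by a seeded uniform jitter.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    labels = ("A", "B", STATUS_QUO_ID)
    profiles = (task.alt_a, task.alt_b, task.status_quo)
    noise = (
        rng.normal(0.0, respondent.noise_scale, 3)
        if respondent.noise_scale > 0
        else np.zeros(3)
    )
    u = np.array(
        [utility(respondent, p, specs, schedule, noise=noise[i]) for i, p in enumerate(profiles)]
    )
    u = u + rng.random(3) * _TIE_JITTER
    order = np.argsort(-u, kind="stable")
    ranks = {labels[alt]: int(pos) + 1 for pos, alt in enumerate(order)}
    return RankingRecord(respondent_id=respondent.id, task_id=task.task_id, ranks=ranks)


# ---------------------------------------------------------------------------
# observations

#: Column dictionary of the long-format observation table (one row per
#: hypothetical alternative): see docs/methods.md.
OBSERVATION_COLUMNS = [
    "respondent_id", "size_bracket", "set_id", "task_id", "alternative_id",
    "premium", "consultations", "hospitalizations", "traffic_accidents",
    "pharmaceuticals", "transportation", "prepaid_discount",
    "premium_level", "realized_premium", "rank", "Y_internal", "Y_external",
    "true_wtp",
]


def build_observations(
    rankings: Sequence[RankingRecord],
    plan: DesignPlan,
    respondents: Sequence[Respondent],
    schedule: PremiumSchedule,
) -> pd.DataFrame:
    """Expand ranking records into estimator rows: two per task, one per
    hypothetical alternative.

    ``Y_external`` = 1 iff the alternative outranks the status quo;
    ``Y_internal`` = 1 iff it outranks the other hypothetical alternative.
    """
    specs = plan.specs
    task_by_id = {t.task_id: t for t in plan.tasks()}
    resp_by_id = {r.id: r for r in respondents}
    names = [s.name for s in specs]
    rows = []
    for rec in rankings:
        if rec.task_id not in task_by_id:
            raise DataError(f"ranking refers to unknown task {rec.task_id}")
        task = task_by_id[rec.task_id]
        try:
            resp = resp_by_id[rec.respondent_id]
        except KeyError:
            raise DataError(f"unknown respondent {rec.respondent_id}") from None
        for alt_id, other_id, prof in (("A", "B", task.alt_a), ("B", "A", task.alt_b)):
            level = _premium_level(prof, specs)
            rows.append({
                "respondent_id": rec.respondent_id,
                "size_bracket": resp.size_bracket,
                "set_id": task.set_id,
                "task_id": task.task_id,
                "alternative_id": alt_id,
                **dict(zip(names, prof.levels)),
                "premium_level": level,
                "realized_premium": schedule.amount(level, resp.size_bracket),
                "rank": rec.ranks[alt_id],
                "Y_internal": int(rec.ranks[alt_id] < rec.ranks[other_id]),
                "Y_external": int(rec.ranks[alt_id] < rec.ranks[STATUS_QUO_ID]),
                "true_wtp": true_wtp(resp, prof, specs, schedule),
            })
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def _nonreference_keys(specs: Sequence[AttributeSpec]) -> list[tuple[str, str]]:
    return [(s.name, l) for s in specs if not s.pecuniary for l in s.nonreference_levels]


def simulate_survey(
    plan: DesignPlan,
    model: PopulationModel,
    schedule: PremiumSchedule,
    seed: int = 0,
) -> tuple[list[Respondent], pd.DataFrame]:
    """Draw a population, assign respondents to choice sets round-robin,
    rank every task, and return (respondents, observation table).

    Vectorized over respondents and tasks; identical in distribution to the
    per-task :func:`rank_task` path (and identical row-for-row at zero
    noise, where choices are deterministic).
    """
    specs = plan.specs
    respondents = draw_population(model, seed=seed)
    n = len(respondents)
    n_sets = plan.n_sets
    if n_sets == 0:
        raise DataError("design plan has no choice sets")

    keys = _nonreference_keys(specs)
    missing = [k for k in keys if k not in model.part_worth_means]
    if missing:
        raise ModelError(f"population model lacks part-worths for levels {missing}")

    # profile -> (part-worth dummy row, premium level)
    profile_index: dict[Profile, int] = {}
    dummies: list[np.ndarray] = []
    prem_levels: list[int] = []

    def intern(profile: Profile) -> int:
        if profile not in profile_index:
            row = np.zeros(len(keys))
            for s, level in zip(specs, profile.levels):
                if not s.pecuniary and level != s.reference_level:
                    row[keys.index((s.name, level))] = 1.0
            profile_index[profile] = len(dummies)
            dummies.append(row)
            prem_levels.append(_premium_level(profile, specs))
        return profile_index[profile]

    tasks = list(plan.tasks())
    a_of_task = np.array([intern(t.alt_a) for t in tasks])
    b_of_task = np.array([intern(t.alt_b) for t in tasks])
    sq = intern(tasks[0].status_quo)
    D = np.vstack(dummies)                      # (n_profiles, n_keys)
    plevels = np.array(prem_levels)             # design level 1..4 per profile

    PW = np.array([[r.part_worths[k] for k in keys] for r in respondents])
    bidx = np.array([schedule.bracket_index(r.size_bracket) for r in respondents])
    delta_value = PW @ D.T                      # (n, n_profiles): valuation - base
    prem_amt = schedule.as_array[plevels - 1][:, :]  # (n_profiles, n_brackets)
    premium = prem_amt[:, bidx].T               # (n, n_profiles)
    current = schedule.as_array[CURRENT_PREMIUM_LEVEL - 1][bidx]  # (n,)

    # respondent r -> choice set r % n_sets; tasks stacked per respondent
    tasks_by_set: dict[int, list[int]] = {}
    for j, t in enumerate(tasks):
        tasks_by_set.setdefault(t.set_id, []).append(j)
    set_ids = sorted(tasks_by_set)
    tps = plan.tasks_per_set
    task_rows = np.array([tasks_by_set[set_ids[r % n_sets]] for r in range(n)])  # (n, tps)

    rng = np.random.default_rng(np.random.SeedSequence((seed, _NOISE_STREAM)))
    noise = (
        rng.normal(0.0, model.noise_scale, (n, tps, 3))
        if model.noise_scale > 0
        else np.zeros((n, tps, 3))
    )
    jitter = rng.random((n, tps, 3)) * _TIE_JITTER

    rr = np.arange(n)[:, None]
    ai = a_of_task[task_rows]                   # (n, tps) profile indices
    bi = b_of_task[task_rows]
    u = np.stack(
        [
            delta_value[rr, ai] - premium[rr, ai] + noise[:, :, 0],
            delta_value[rr, bi] - premium[rr, bi] + noise[:, :, 1],
            delta_value[:, sq][:, None] - current[:, None] + noise[:, :, 2],
        ],
        axis=-1,
    ) + jitter
    # rank = 1 + number of alternatives with strictly higher (jittered) utility
    ranks = 1 + (u[:, :, None, :] > u[:, :, :, None]).sum(axis=-1)  # (n, tps, 3)

    names = [s.name for s in specs]
    index_profiles = {v: k for k, v in profile_index.items()}
    level_table = np.array(
        [[index_profiles[i].levels[j] for j in range(len(specs))] for i in range(len(dummies))],
        dtype=object,
    )

    alt_profile = np.empty((n, tps, 2), dtype=int)
    alt_profile[:, :, 0] = ai
    alt_profile[:, :, 1] = bi
    flat_prof = alt_profile.reshape(-1)
    resp_col = np.repeat(np.arange(n), tps * 2)
    task_col = np.repeat(task_rows.reshape(-1), 2)
    task_ids = np.array([t.task_id for t in tasks])
    set_col = np.array([tasks[j].set_id for j in task_col])
    alt_lab = np.tile(np.array(["A", "B"]), n * tps)
    rank_self = ranks[:, :, :2].reshape(-1)
    rank_other = ranks[:, :, [1, 0]].reshape(-1)
    rank_sq = np.repeat(ranks[:, :, 2].reshape(-1), 2)

    frame = pd.DataFrame({
        "respondent_id": resp_col,
        "size_bracket": np.array([respondents[i].size_bracket for i in resp_col], dtype=object),
        "set_id": set_col,
        "task_id": task_ids[task_col],
        "alternative_id": alt_lab,
    })
    for j, name in enumerate(names):
        frame[name] = level_table[flat_prof, j]
    frame["premium_level"] = plevels[flat_prof]
    frame["realized_premium"] = schedule.as_array[plevels[flat_prof] - 1, bidx[resp_col]]
    frame["rank"] = rank_self
    frame["Y_internal"] = (rank_self < rank_other).astype(int)
    frame["Y_external"] = (rank_self < rank_sq).astype(int)
    frame["true_wtp"] = delta_value[resp_col, flat_prof] + current[resp_col]
    assert len(frame) == n * tps * 2
    return respondents, frame[OBSERVATION_COLUMNS]
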