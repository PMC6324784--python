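"""Fully randomized conjoint designs over the benefit-package profile universe.

The design protocol: enumerate every profile (the Cartesian product of
attribute levels), drop the status-quo profile, sample unordered pairs of
distinct profiles uniformly without replacement, and chunk the pairs into
choice sets of five three-alternative tasks (two hypothetical alternatives
plus the status quo).  Each respondent additionally receives one uniformly
random attribute display order, held fixed across their five tasks.

Full randomization is what makes the difference-in-means estimator causal:
every attribute level is statistically independent of every other level and
of respondent characteristics, so conditional means identify average marginal
component effects without functional-form assumptions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .attributes import (
    AttributeSpec,
    PremiumSchedule,
    attributes_from_config,
    attributes_to_config,
    validate_attributes,
)
from .errors import DataError, DesignError

# Substream tags so design sampling, attribute orders and simulation draw
# from independent, individually reproducible streams of one master seed.
_PAIR_STREAM = 1
_ORDER_STREAM = 2

STATUS_QUO_ID = "SQ"


@dataclass(frozen=True)
class Profile:
    """One hypothetical scheme: a tuple of level labels, one per attribute."""

    levels: tuple[str, ...]

    def as_dict(self, specs: Sequence[AttributeSpec]) -> dict[str, str]:
        return {s.name: l for s, l in zip(specs, self.levels)}

    def level_of(self, specs: Sequence[AttributeSpec], attribute: str) -> str:
        for s, l in zip(specs, self.levels):
            if s.name == attribute:
                return l
        raise DataError(f"unknown attribute {attribute!r}")


@dataclass(frozen=True)
class ChoiceTask:
    """A three-alternative task: two hypothetical profiles plus the status quo."""

    task_id: int
    set_id: int
    alt_a: Profile
    alt_b: Profile
    status_quo: Profile

    def __post_init__(self) -> None:
        if self.alt_a == self.alt_b:
            raise DesignError(f"task {self.task_id}: alternatives must be distinct")


@dataclass
class DesignPlan:
    """A randomized design: choice sets of tasks plus the randomization seed."""

    specs: tuple[AttributeSpec, ...]
    choice_sets: list[list[ChoiceTask]]
    seed: int
    attribute_order_policy: str = "per-respondent-uniform"

    @property
    def n_sets(self) -> int:
        return len(self.choice_sets)

    @property
    def tasks_per_set(self) -> int:
        return len(self.choice_sets[0]) if self.choice_sets else 0

    def tasks(self) -> Iterator[ChoiceTask]:
        for cs in self.choice_sets:
            yield from cs

    @property
    def n_tasks(self) -> int:
        return sum(len(cs) for cs in self.choice_sets)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per task-alternative, incl. the status quo."""
        names = [s.name for s in self.specs]
        rows = []
        for task in self.tasks():
            for alt_id, prof in (("A", task.alt_a), ("B", task.alt_b), (STATUS_QUO_ID, task.status_quo)):
                rows.append(
                    {"set_id": task.set_id, "task_id": task.task_id, "alt_id": alt_id,
                     **dict(zip(names, prof.levels))}
                )
        return pd.DataFrame(rows, columns=["set_id", "task_id", "alt_id", *names])

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        specs: Sequence[AttributeSpec],
        seed: int,
        attribute_order_policy: str = "per-respondent-uniform",
    ) -> "DesignPlan":
        specs = validate_attributes(specs)
        names = [s.name for s in specs]
        missing = set(names) - set(frame.columns)
        if missing:
            raise DataError(f"design frame lacks attribute columns {sorted(missing)}")
        sets: dict[int, list[ChoiceTask]] = {}
        for (set_id, task_id), grp in frame.groupby(["set_id", "task_id"], sort=True):
            alts = {row.alt_id: Profile(tuple(getattr(row, n) for n in names))
                    for row in grp.itertuples(index=False)}
            if set(alts) != {"A", "B", STATUS_QUO_ID}:
                raise DataError(f"task {task_id}: expected alternatives A, B, {STATUS_QUO_ID}")
            task = ChoiceTask(int(task_id), int(set_id), alts["A"], alts["B"], alts[STATUS_QUO_ID])
            sets.setdefault(int(set_id), []).append(task)
        choice_sets = [sets[k] for k in sorted(sets)]
        return cls(specs=specs, choice_sets=choice_sets, seed=seed,
                   attribute_order_policy=attribute_order_policy)

    def save(self, csv_path) -> None:
        """Write the plan CSV plus a JSON sidecar with seed and order policy."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = {
            "seed": self.seed,
            "attribute_order_policy": self.attribute_order_policy,
            **attributes_to_config(self.specs),
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, csv_path) -> "DesignPlan":
        csv_path = Path(csv_path)
        sidecar = json.loads(csv_path.with_suffix(".json").read_text())
        specs, _ = attributes_from_config(sidecar)
        frame = pd.read_csv(csv_path, dtype={"set_id": int, "task_id": int, "alt_id": str})
        # Levels like "5%" or "10,000" must stay strings even if numeric-looking
        for s in specs:
            frame[s.name] = frame[s.name].astype(str)
        return cls.from_frame(frame, specs, seed=int(sidecar["seed"]),
                              attribute_order_policy=sidecar["attribute_order_policy"])


def status_quo_profile(specs: Sequence[AttributeSpec]) -> Profile:
    """The profile whose every level is its attribute's reference level."""
    return Profile(tuple(s.reference_level for s in validate_attributes(specs)))


def enumerate_profiles(specs: Sequence[AttributeSpec]) -> list[Profile]:
    """All profiles: the Cartesian product of the attributes' level sets."""
    specs = validate_attributes(specs)
    return [Profile(combo) for combo in itertools.product(*(s.levels for s in specs))]


def enumerate_hypothetical_profiles(specs: Sequence[AttributeSpec]) -> list[Profile]:
    """All profiles except the status quo (the pairing universe)."""
    sq = status_quo_profile(specs)
    return [p for p in enumerate_profiles(specs) if p != sq]


def randomize_design(
    specs: Sequence[AttributeSpec],
    n_pairs: int = 575,
    tasks_per_set: int = 5,
    seed: int = 0,
) -> DesignPlan:
    """Sample ``n_pairs`` unordered pairs of distinct non-status-quo profiles
    uniformly without replacement and chunk them into choice sets.

    The left/right position of the two hypothetical alternatives is
    randomized per task; the status quo is always displayed last.
    """
    specs = validate_attributes(specs)
    if tasks_per_set < 1 or n_pairs < 1:
        raise DesignError("n_pairs and tasks_per_set must be positive")
    if n_pairs % tasks_per_set != 0:
        raise DesignError(
            f"n_pairs={n_pairs} is not divisible by tasks_per_set={tasks_per_set}"
        )
    universe = enumerate_hypothetical_profiles(specs)
    m = len(universe)
    n_unordered = m * (m - 1) // 2
    if n_pairs > n_unordered:
        raise DesignError(
            f"requested {n_pairs} pairs but only {n_unordered} unordered pairs "
            f"of {m} distinct profiles exist"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, _PAIR_STREAM)))
    left, right = np.triu_indices(m, k=1)
    chosen = rng.choice(n_unordered, size=n_pairs, replace=False)
    # randomize which member of the unordered pair is displayed on the left
    flip = rng.random(n_pairs) < 0.5
    a_idx = np.where(flip, right[chosen], left[chosen])
    b_idx = np.where(flip, left[chosen], right[chosen])

    sq = status_quo_profile(specs)
    choice_sets: list[list[ChoiceTask]] = []
    for set_id in range(n_pairs // tasks_per_set):
        tasks = []
        for j in range(tasks_per_set):
            t = set_id * tasks_per_set + j
            tasks.append(
                ChoiceTask(task_id=t, set_id=set_id,
                           alt_a=universe[a_idx[t]], alt_b=universe[b_idx[t]],
                           status_quo=sq)
            )
        choice_sets.append(tasks)
    return DesignPlan(specs=specs, choice_sets=choice_sets, seed=seed)


def assign_attribute_order(
    respondent_id: int, specs: Sequence[AttributeSpec], seed: int
) -> tuple[str, ...]:
    """A uniformly random attribute display order, deterministic in
    ``(seed, respondent_id)`` and therefore constant across a respondent's
    five tasks."""
    specs = validate_attributes(specs)
    rng = np.random.default_rng(
        np.random.SeedSequence((seed, _ORDER_STREAM, int(respondent_id)))
    )
    names = [s.name for s in specs]
    return tuple(names[i] for i in rng.permutation(len(names)))


def realize_premium(premium_level: int, bracket: str, schedule: PremiumSchedule) -> float:
    """LAK amount of a premium design level for a household-size bracket."""
    return schedule.amount(premium_level, bracket)
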