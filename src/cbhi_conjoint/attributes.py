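"""Attribute and premium vocabulary for the CBHI benefit-package experiment.

A hypothetical community-based health insurance (CBHI) scheme is described by
seven attributes: a monthly premium (the only pecuniary attribute, with four
design levels whose amounts in Lao kip, LAK, depend on household size) and six
non-pecuniary benefit-package components (coverage for medical consultations,
hospitalizations, traffic accidents, pharmaceuticals, transportation, and a
one-year prepaid discount).  The *reference* level of each attribute is the
level of the currently implemented status-quo scheme; the status-quo profile
is the profile that takes the reference level of every attribute.

The default vocabulary (:func:`default_attributes`) and the default rural
premium schedule (:func:`default_schedule`) encode the experiment's standard
benefit-package table: 4 x 2 x 2 x 2 x 2 x 3 x 3 = 576 distinct profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import DataError, SpecificationError

#: Household-size brackets, in the order used by the premium schedule.
BRACKETS: tuple[str, ...] = ("1", "2-4", "5-7", "8+")

#: Premium design levels are labelled p1..p4; p2 is the current premium.
PREMIUM_LEVELS: tuple[str, ...] = ("p1", "p2", "p3", "p4")

#: Design level (1..4) whose amounts equal the current (status quo) premium.
CURRENT_PREMIUM_LEVEL: int = 2


@dataclass(frozen=True)
class AttributeSpec:
    """One attribute of the choice experiment.

    Parameters
    ----------
    name
        Attribute identifier, unique within a vocabulary.
    levels
        Ordered level labels, unique within the attribute.
    reference_level
        The status-quo level; must be one of ``levels``.
    pecuniary
        True only for the premium attribute, whose levels map to LAK
        amounts through a :class:`PremiumSchedule`.
    """

    name: str
    levels: tuple[str, ...]
    reference_level: str
    pecuniary: bool = False

    def __post_init__(self) -> None:
        if not self.levels:
            raise SpecificationError(f"attribute {self.name!r} has no levels")
        if len(set(self.levels)) != len(self.levels):
            raise SpecificationError(f"attribute {self.name!r} has duplicate levels")
        if self.reference_level not in self.levels:
            raise SpecificationError(
                f"reference level {self.reference_level!r} not among levels of "
                f"attribute {self.name!r}"
            )
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference_level)


@dataclass(frozen=True)
class PremiumSchedule:
    """Monthly premium amounts (LAK/household) by design level and bracket.

    ``amounts[i, j]`` is the premium at design level ``i + 1`` for household
    size bracket ``brackets[j]``.  Amounts must be strictly increasing in the
    design level within each bracket, so that utility monotone decreasing in
    money implies monotone choice behaviour across levels.
    """

    amounts: tuple[tuple[int, ...], ...]
    brackets: tuple[str, ...] = BRACKETS

    def __post_init__(self) -> None:
        arr = np.asarray(self.amounts, dtype=float)
        if arr.shape != (len(PREMIUM_LEVELS), len(self.brackets)):
            raise SpecificationError(
                f"premium schedule must be {len(PREMIUM_LEVELS)} levels x "
                f"{len(self.brackets)} brackets, got shape {arr.shape}"
            )
        if not (np.diff(arr, axis=0) > 0).all():
            raise SpecificationError(
                "premium amounts must be strictly increasing across levels "
                "within each bracket"
            )

    @property
    def as_array(self) -> np.ndarray:
        return np.asarray(self.amounts, dtype=float)

    def bracket_index(self, bracket: str) -> int:
        try:
            return self.brackets.index(bracket)
        except ValueError:
            raise DataError(
                f"unknown household-size bracket {bracket!r}; "
                f"expected one of {self.brackets}"
            ) from None

    def amount(self, premium_level: int, bracket: str) -> float:
        """Premium in LAK for design level 1..4 and a size bracket."""
        if not 1 <= premium_level <= len(PREMIUM_LEVELS):
            raise DataError(f"premium level must be 1..{len(PREMIUM_LEVELS)}, got {premium_level}")
        return float(self.as_array[premium_level - 1, self.bracket_index(bracket)])

    def current(self, bracket: str) -> float:
        """The status-quo (current) premium for a bracket (design level 2)."""
        return self.amount(CURRENT_PREMIUM_LEVEL, bracket)


def default_schedule() -> PremiumSchedule:
    """The rural premium schedule: current premium +/- 2,000-LAK steps."""
    return PremiumSchedule(
        amounts=(
            (10_000, 18_000, 23_000, 26_000),  # p1: 2,000 below current
            (12_000, 20_000, 25_000, 28_000),  # p2: current premium
            (14_000, 22_000, 27_000, 30_000),  # p3: 2,000 above current
            (16_000, 24_000, 29_000, 32_000),  # p4: 4,000 above current
        )
    )


def default_attributes() -> tuple[AttributeSpec, ...]:
    """The seven-attribute benefit-package vocabulary (reference = status quo)."""
    return (
        AttributeSpec("premium", PREMIUM_LEVELS, "p2", pecuniary=True),
        AttributeSpec("consultations", ("No", "Yes"), "Yes"),
        AttributeSpec("hospitalizations", ("No", "Yes"), "Yes"),
        AttributeSpec("traffic_accidents", ("No", "Yes"), "No"),
        AttributeSpec("pharmaceuticals", ("Partly", "Fully"), "Partly"),
        AttributeSpec("transportation", ("No", "One way", "Round trip"), "No"),
        AttributeSpec("prepaid_discount", ("No", "5%", "10%"), "No"),
    )


def validate_attributes(specs: Sequence[AttributeSpec]) -> tuple[AttributeSpec, ...]:
    """Check cross-attribute invariants and return the specs as a tuple."""
    specs = tuple(specs)
    if not specs:
        raise SpecificationError("attribute list is empty")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SpecificationError(f"duplicate attribute names in {names}")
    n_pecuniary = sum(s.pecuniary for s in specs)
    if n_pecuniary > 1:
        raise SpecificationError("at most one attribute may be pecuniary (the premium)")
    return specs


def premium_spec(specs: Sequence[AttributeSpec]) -> AttributeSpec | None:
    """Return the pecuniary (premium) attribute, or None if there is none."""
    for s in specs:
        if s.pecuniary:
            return s
    return None


def attributes_to_config(
    specs: Sequence[AttributeSpec], schedule: PremiumSchedule | None = None
) -> dict:
    cfg: dict = {
        "attributes": [
            {
                "name": s.name,
                "levels": list(s.levels),
                "reference_level": s.reference_level,
                "pecuniary": bool(s.pecuniary),
            }
            for s in specs
        ]
    }
    if schedule is not None:
        cfg["premium_schedule"] = {
            "brackets": list(schedule.brackets),
            "amounts": [list(row) for row in schedule.amounts],
        }
    return cfg


def attributes_from_config(cfg: dict) -> tuple[tuple[AttributeSpec, ...], PremiumSchedule | None]:
    specs = validate_attributes(
        AttributeSpec(
            name=a["name"],
            levels=tuple(a["levels"]),
            reference_level=a["reference_level"],
            pecuniary=bool(a.get("pecuniary", False)),
        )
        for a in cfg["attributes"]
    )
    schedule = None
    if "premium_schedule" in cfg:
        ps = cfg["premium_schedule"]
        schedule = PremiumSchedule(
            amounts=tuple(tuple(row) for row in ps["amounts"]),
            brackets=tuple(ps["brackets"]),
        )
    return specs, schedule


def save_attributes(path, specs: Sequence[AttributeSpec], schedule: PremiumSchedule | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(attributes_to_config(specs, schedule), fh, sort_keys=False)


def load_attributes(path) -> tuple[tuple[AttributeSpec, ...], PremiumSchedule | None]:
    with open(path) as fh:
        return attributes_from_config(yaml.safe_load(fh))
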