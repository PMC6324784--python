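"""Structural validation of long-format choice observation tables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .attributes import AttributeSpec, BRACKETS, default_attributes, validate_attributes
from .simulate import OBSERVATION_COLUMNS


@dataclass(frozen=True)
class Issue:
    code: str
    message: str
    rows: tuple[int, ...] = ()

    def as_dict(self) -> dict:
        return {"code": self.code, "message": self.message, "rows": list(self.rows)}


def validate_observations(
    observations: pd.DataFrame, specs: Sequence[AttributeSpec] | None = None
) -> list[Issue]:
    """Check the column dictionary, level domains, rank integrity and
    Y-consistency of an observation table; returns a machine-readable list
    of issues (empty for a well-formed table)."""
    specs = validate_attributes(specs if specs is not None else default_attributes())
    issues: list[Issue] = []

    required = [c for c in OBSERVATION_COLUMNS if c != "true_wtp"]
    missing = [c for c in required if c not in observations.columns]
    if missing:
        issues.append(Issue("missing-columns", f"missing required columns: {missing}"))
        return issues

    for s in specs:
        if s.pecuniary:
            continue
        col = observations[s.name].astype(str)
        bad = ~col.isin(s.levels)
        if bad.any():
            issues.append(Issue(
                "level-domain",
                f"attribute {s.name!r} has values outside {s.levels}",
                tuple(observations.index[bad][:20]),
            ))

    plevel = pd.to_numeric(observations["premium_level"], errors="coerce")
    bad = ~plevel.isin([1, 2, 3, 4])
    if bad.any():
        issues.append(Issue("level-domain", "premium_level outside 1..4",
                            tuple(observations.index[bad][:20])))

    bad = ~observations["size_bracket"].astype(str).isin(BRACKETS)
    if bad.any():
        issues.append(Issue("bracket-domain", f"size_bracket outside {BRACKETS}",
                            tuple(observations.index[bad][:20])))

    for ycol in ("Y_internal", "Y_external"):
        yv = pd.to_numeric(observations[ycol], errors="coerce")
        bad = ~yv.isin([0, 1])
        if bad.any():
            issues.append(Issue("y-domain", f"{ycol} not binary",
                                tuple(observations.index[bad][:20])))

    # per-(respondent, task) integrity: two alternatives, distinct ranks in
    # 1..3, and internal Ys summing to exactly 1 (strict ranking forces a
    # unique internal winner)
    grouped = observations.groupby(["respondent_id", "task_id"], sort=False)
    for (rid, tid), grp in grouped:
        if len(grp) != 2:
            issues.append(Issue("task-shape",
                                f"respondent {rid} task {tid}: expected 2 rows, got {len(grp)}",
                                tuple(grp.index)))
            continue
        ranks = sorted(pd.to_numeric(grp["rank"], errors="coerce"))
        if not (len(set(ranks)) == 2 and all(r in (1, 2, 3) for r in ranks)):
            issues.append(Issue("rank-integrity",
                                f"respondent {rid} task {tid}: alternative ranks {ranks} "
                                "are not two distinct values in 1..3",
                                tuple(grp.index)))
        ysum = pd.to_numeric(grp["Y_internal"], errors="coerce").sum()
        if ysum != 1:
            issues.append(Issue("y-consistency",
                                f"respondent {rid} task {tid}: internal Ys sum to {ysum}, "
                                "expected exactly 1",
                                tuple(grp.index)))
    return issues
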