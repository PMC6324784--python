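"""Average marginal component effects (AMCE) on choice probabilities.

Under full randomization, the AMCE of moving attribute ``l`` from level
``a0`` to ``a1`` is identified by a difference in conditional means of the
binary choice outcome, and is estimated jointly for all levels by a linear
probability model

    E[Y] = b0 + sum over non-reference levels of b_level * 1{level present},

with the status-quo level of every attribute as the reference category.
Uncertainty uses a cluster-robust sandwich with respondents as clusters
(each respondent contributes ten correlated rows: five tasks x two
alternatives).  The small-sample scaling is CR1,
G/(G-1) * (N-1)/(N-K); confidence intervals are normal-approximation
estimate +/- z_{0.975} * SE.

Two outcomes are supported: ``external`` (alternative preferred to the
status quo) and ``internal`` (preferred to the other hypothetical
alternative in the same task).  :func:`diff_in_means` is the nonparametric
estimator of the same quantity one cell at a time; on balanced designs it
coincides with the regression coefficients and serves as an independent
oracle in the tests.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .attributes import AttributeSpec, default_attributes, validate_attributes
from .errors import DataError, EstimationError

OUTCOME_COLUMNS = {"external": "Y_external", "internal": "Y_internal"}

_Z975 = float(stats.norm.ppf(0.975))


def _column_name(attribute: str, level: str) -> str:
    return f"{attribute}[{level}]"


def encode_dummies(
    observations: pd.DataFrame, specs: Sequence[AttributeSpec]
) -> pd.DataFrame:
    """Design matrix: an intercept plus one indicator per non-reference level.

    Reference categories are the status-quo levels, so a status-quo-identical
    alternative encodes as the all-zero row (intercept only).
    """
    specs = validate_attributes(specs)
    if observations.empty:
        raise DataError("no observations to encode")
    X = pd.DataFrame(index=observations.index)
    X["intercept"] = 1.0
    for s in specs:
        col = observations[s.name].astype(str)
        bad = set(col.unique()) - set(s.levels)
        if bad:
            raise DataError(f"unknown level(s) {sorted(bad)} for attribute {s.name!r}")
        for level in s.nonreference_levels:
            X[_column_name(s.name, level)] = (col == level).astype(float)
    return X


class AmceEstimator(BaseEstimator):
    """Linear-probability AMCE estimator with cluster-robust inference.

    Parameters
    ----------
    outcome : {"external", "internal"}
        Which binary choice outcome to model.
    specs : sequence of AttributeSpec, optional
        Attribute vocabulary; defaults to the standard seven-attribute
        benefit-package table.
    cluster_col : str
        Column identifying clusters (respondents).
    correction : {"CR1", "CR0"}
        Small-sample scaling of the sandwich covariance.
    alpha : float
        Two-sided CI level is ``1 - alpha``.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : pd.Series          estimates per non-reference level (probability scale)
    se_ : pd.Series            cluster-robust standard errors
    intercept_ : float         baseline choice probability (all-reference profile)
    summary_ : pd.DataFrame    tidy table (attribute, level, estimate, se, ci_lo, ci_hi)
    n_obs_, n_clusters_ : int
    """

    def __init__(
        self,
        outcome: str = "external",
        specs: Sequence[AttributeSpec] | None = None,
        cluster_col: str = "respondent_id",
        correction: str = "CR1",
        alpha: float = 0.05,
    ):
        self.outcome = outcome
        self.specs = specs
        self.cluster_col = cluster_col
        self.correction = correction
        self.alpha = alpha

    def _specs(self) -> tuple[AttributeSpec, ...]:
        return validate_attributes(self.specs if self.specs is not None else default_attributes())

    def fit(self, X: pd.DataFrame, y=None) -> "AmceEstimator":
        """Fit on a long-format observation table (one row per hypothetical
        alternative)."""
        if self.outcome not in OUTCOME_COLUMNS:
            raise DataError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
        if self.correction not in ("CR0", "CR1"):
            raise DataError("correction must be 'CR0' or 'CR1'")
        specs = self._specs()
        ycol = OUTCOME_COLUMNS[self.outcome]
        for col in (ycol, self.cluster_col):
            if col not in X.columns:
                raise DataError(f"observations lack required column {col!r}")
        groups = X[self.cluster_col]
        n_clusters = groups.nunique()
        if n_clusters < 2:
            raise EstimationError("cluster-robust estimation needs at least 2 clusters")

        design = encode_dummies(X, specs)
        yvals = X[ycol].astype(float).to_numpy()
        if not np.isin(yvals, (0.0, 1.0)).all():
            raise DataError(f"{ycol} must be binary 0/1")

        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            # name the offending columns for the user
            q, r = np.linalg.qr(design.to_numpy())
            bad = [c for c, d in zip(design.columns, np.abs(np.diag(r))) if d < 1e-8]
            raise EstimationError(
                f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
                f"collinear columns: {bad}"
            )

        model = sm.OLS(yvals, design.to_numpy())
        res = model.fit(
            cov_type="cluster",
            cov_kwds={
                "groups": groups.to_numpy(),
                "use_correction": self.correction == "CR1",
            },
            use_t=False,
        )
        names = list(design.columns)
        params = pd.Series(res.params, index=names)
        bse = pd.Series(res.bse, index=names)
        # constant outcomes leave exact-zero residuals; keep SEs at clean zero
        bse[np.isclose(bse, 0.0, atol=1e-12)] = 0.0

        self.feature_names_ = names[1:]
        self.intercept_ = float(params["intercept"])
        self.intercept_se_ = float(bse["intercept"])
        self.coef_ = params.drop("intercept")
        self.se_ = bse.drop("intercept")
        self.n_obs_ = int(len(X))
        self.n_clusters_ = int(n_clusters)
        self.cov_ = pd.DataFrame(res.cov_params(), index=names, columns=names)
        z = float(stats.norm.ppf(1 - self.alpha / 2))

        rows = []
        for s in specs:
            rows.append({
                "outcome": self.outcome, "attribute": s.name, "level": s.reference_level,
                "is_reference": True, "estimate": 0.0, "se": np.nan,
                "ci_lo": np.nan, "ci_hi": np.nan,
            })
            for level in s.nonreference_levels:
                cname = _column_name(s.name, level)
                est, se = float(params[cname]), float(bse[cname])
                rows.append({
                    "outcome": self.outcome, "attribute": s.name, "level": level,
                    "is_reference": False, "estimate": est, "se": se,
                    "ci_lo": est - z * se, "ci_hi": est + z * se,
                })
        self.summary_ = pd.DataFrame(rows)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted choice probabilities for the rows of an observation table."""
        design = encode_dummies(X, self._specs())
        beta = np.concatenate([[self.intercept_], self.coef_.to_numpy()])
        return design.to_numpy() @ beta


def fit_amce(
    observations: pd.DataFrame,
    outcome: str = "external",
    specs: Sequence[AttributeSpec] | None = None,
    correction: str = "CR1",
) -> AmceEstimator:
    """Functional wrapper over :class:`AmceEstimator`."""
    return AmceEstimator(outcome=outcome, specs=specs, correction=correction).fit(observations)


def diff_in_means(
    observations: pd.DataFrame,
    attribute: str,
    level_a1: str,
    level_a0: str,
    premium_level: int | None = None,
    outcome: str = "external",
) -> float:
    """Nonparametric AMCE estimate for one attribute change:
    mean(Y | A_l = a1) - mean(Y | A_l = a0), optionally conditioning both
    cells on a premium design level."""
    if outcome not in OUTCOME_COLUMNS:
        raise DataError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
    ycol = OUTCOME_COLUMNS[outcome]
    df = observations
    if premium_level is not None:
        df = df[df["premium_level"] == premium_level]
    cells = []
    for lvl in (level_a1, level_a0):
        cell = df[df[attribute].astype(str) == lvl]
        if cell.empty:
            raise EstimationError(
                f"empty cell: {attribute}={lvl!r}"
                + (f" at premium level {premium_level}" if premium_level is not None else "")
            )
        cells.append(cell[ycol].mean())
    return float(cells[0] - cells[1])
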