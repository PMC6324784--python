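"""Nonparametric identification of the willingness-to-pay (WTP) distribution.

With choices generated by utility monotone decreasing in the premium, the
share of respondents whose WTP for an improved scheme is at or below a
premium threshold c is identified by

    F(c) = 1 - mean(Y_external | premium = c),

evaluated at the four design premium levels p1 < p2 < p3 < p4.  Successive
differences of F give the probability mass of the five threshold intervals
[0, p1], (p1, p2], (p2, p3], (p3, p4], (p4, inf); the masses telescope to 1
by construction.  Raw interval masses may be locally negative through
sampling noise; they are reported raw by default, with an optional isotonic
(pool-adjacent-violators) correction.

Identification requires the *boundary assumption*: WTP is bounded below at
zero, which holds only when every non-pecuniary attribute of the alternative
is at least as good as the status quo.  Since consultation and
hospitalization coverage are the only attributes whose status-quo level can
be worsened, the analysis subsample keeps rows with both set to "Yes"
(about one quarter of a fully randomized design).

Valuing each interval at its lower endpoint (and the first at zero) yields a
lower bound on mean WTP.  Because premium amounts depend on the household
size bracket, the bound is a bracket-share-weighted sum:

    mu_lower = sum over brackets b of s_b *
               sum_{j=1..4} premium(level j, b) * mass(interval j+1).

All standard errors are cluster-robust with respondents as clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .attributes import (
    AttributeSpec,
    PremiumSchedule,
    default_attributes,
    default_schedule,
    validate_attributes,
)
from .errors import DataError, EstimationError

_Z975 = float(stats.norm.ppf(0.975))

#: Interval labels, lowest to highest threshold.
INTERVAL_LABELS = ("[0,p1]", "(p1,p2]", "(p2,p3]", "(p3,p4]", "(p4,inf)")

#: Attributes whose status-quo level can be worsened by the randomization;
#: the boundary assumption requires them at the status-quo ("Yes") level.
BOUNDARY_ATTRIBUTES = ("consultations", "hospitalizations")


def boundary_filter(
    observations: pd.DataFrame, specs: Sequence[AttributeSpec] | None = None
) -> pd.DataFrame:
    """Keep rows whose consultation and hospitalization coverage equal the
    status quo ("Yes"), so no attribute is below the status quo and WTP is
    bounded below at zero."""
    specs = validate_attributes(specs if specs is not None else default_attributes())
    by_name = {s.name: s for s in specs}
    mask = pd.Series(True, index=observations.index)
    for name in BOUNDARY_ATTRIBUTES:
        if name not in observations.columns:
            raise DataError(f"observations lack boundary attribute column {name!r}")
        ref = by_name[name].reference_level if name in by_name else "Yes"
        mask &= observations[name].astype(str) == ref
    return observations[mask]


@dataclass
class WtpDistribution:
    """Estimated marginal WTP distribution at the four premium thresholds.

    ``f_hat[k-1]`` is F(p_k); ``interval_masses`` are the five threshold
    interval probabilities; ``approval_rates[k-1] = 1 - F(p_k)`` is the
    share who would enroll at premium level k.
    """

    f_hat: np.ndarray
    f_hat_se: np.ndarray
    interval_masses: np.ndarray
    interval_se: np.ndarray
    approval_rates: np.ndarray
    approval_se: np.ndarray
    n_obs: int
    n_per_level: np.ndarray
    n_clusters: int

    def isotonic(self) -> "WtpDistribution":
        """Pool-adjacent-violators correction: monotone F, nonnegative masses.

        SEs are carried over unchanged (the correction is a projection, not a
        re-estimation)."""
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
        f = iso.fit_transform(np.arange(len(self.f_hat)), self.f_hat)
        masses = np.diff(np.concatenate([[0.0], f, [1.0]]))
        return WtpDistribution(
            f_hat=f, f_hat_se=self.f_hat_se.copy(),
            interval_masses=masses, interval_se=self.interval_se.copy(),
            approval_rates=1.0 - f, approval_se=self.approval_se.copy(),
            n_obs=self.n_obs, n_per_level=self.n_per_level.copy(),
            n_clusters=self.n_clusters,
        )

    def cumulative_approval(self, k: int, clip_negative_masses: bool = True) -> float:
        """Approval rate at premium threshold k (1..4): the share willing to
        pay more than p_k, i.e. 1 - F(p_k).

        With ``clip_negative_masses`` (default), negative interval masses are
        treated as zero before cumulating, so a noisy locally non-monotone F
        cannot raise the approval rate above an earlier threshold.
        """
        if not 1 <= k <= len(self.f_hat):
            raise DataError(f"threshold index must be 1..{len(self.f_hat)}")
        masses = self.interval_masses[:k]
        if clip_negative_masses:
            masses = np.clip(masses, 0.0, None)
        return float(1.0 - masses.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(4):
            rows.append({"quantity": "F_hat", "interval": f"p{k + 1}",
                         "estimate": self.f_hat[k], "se": self.f_hat_se[k],
                         "n": int(self.n_per_level[k])})
            rows.append({"quantity": "approval_rate", "interval": f"p{k + 1}",
                         "estimate": self.approval_rates[k], "se": self.approval_se[k],
                         "n": int(self.n_per_level[k])})
        for j, lab in enumerate(INTERVAL_LABELS):
            rows.append({"quantity": "interval_mass", "interval": lab,
                         "estimate": self.interval_masses[j], "se": self.interval_se[j],
                         "n": self.n_obs})
        df = pd.DataFrame(rows)
        df["ci_lo"] = df["estimate"] - _Z975 * df["se"]
        df["ci_hi"] = df["estimate"] + _Z975 * df["se"]
        return df


def _safe_se(variances: np.ndarray) -> np.ndarray:
    """SEs from a variance vector; exact-zero-residual fits leave tiny
    negative/positive float dust that is flushed to a clean zero."""
    v = np.asarray(variances, dtype=float).copy()
    v[np.abs(v) < 1e-24] = 0.0
    return np.sqrt(np.clip(v, 0.0, None))


def _cell_means_cluster(
    observations: pd.DataFrame, outcome_col: str, cluster_col: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-premium-level means of a binary outcome with the cluster-robust
    covariance of the four means (respondent clusters, CR1)."""
    levels = observations["premium_level"].astype(int)
    counts = np.array([(levels == k).sum() for k in (1, 2, 3, 4)])
    if (counts == 0).any():
        missing = [k + 1 for k in range(4) if counts[k] == 0]
        raise EstimationError(f"no observations at premium level(s) {missing}")
    X = np.column_stack([(levels == k).astype(float) for k in (1, 2, 3, 4)])
    y = observations[outcome_col].astype(float).to_numpy()
    res = sm.OLS(y, X).fit(
        cov_type="cluster",
        cov_kwds={"groups": observations[cluster_col].to_numpy(), "use_correction": True},
        use_t=False,
    )
    cov = np.asarray(res.cov_params())
    return np.asarray(res.params), cov, counts, observations[cluster_col].nunique()


def marginal_cdf(
    observations: pd.DataFrame,
    outcome_col: str = "Y_external",
    cluster_col: str = "respondent_id",
) -> WtpDistribution:
    """Estimate F(p_k) = 1 - mean(Y | premium level k) and the interval
    masses by successive differences.

    The caller is responsible for passing the boundary-filtered subsample
    (see :func:`boundary_filter`); conditioning uses the design premium
    level 1..4 so that households of different sizes pool within a level.
    """
    for col in (outcome_col, cluster_col, "premium_level"):
        if col not in observations.columns:
            raise DataError(f"observations lack required column {col!r}")
    means, cov, counts, n_clusters = _cell_means_cluster(
        observations, outcome_col, cluster_col
    )
    f_hat = 1.0 - means
    f_se = _safe_se(np.diag(cov))

    # masses = L @ means + offset: [1-m1, m1-m2, m2-m3, m3-m4, m4]
    L = np.array([
        [-1.0, 0.0, 0.0, 0.0],
        [1.0, -1.0, 0.0, 0.0],
        [0.0, 1.0, -1.0, 0.0],
        [0.0, 0.0, 1.0, -1.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    masses = L @ means + np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    mass_se = _safe_se(np.diag(L @ cov @ L.T))

    return WtpDistribution(
        f_hat=f_hat, f_hat_se=f_se,
        interval_masses=masses, interval_se=mass_se,
        approval_rates=means, approval_se=f_se.copy(),
        n_obs=int(len(observations)), n_per_level=counts, n_clusters=int(n_clusters),
    )


@dataclass
class LowerBoundWtp:
    """Lower bound on mean WTP (LAK/household/month) with its ingredients."""

    mu_lower: float
    bracket_shares: dict[str, float]
    schedule: PremiumSchedule


def lower_bound_mean(
    dist: WtpDistribution,
    bracket_shares: Mapping[str, float],
    schedule: PremiumSchedule | None = None,
) -> LowerBoundWtp:
    """Value each WTP interval at its lower endpoint (zero below p1) and
    average over household-size brackets:

        mu = sum_b s_b * sum_{j=1..4} premium(j, b) * mass_{j+1}.
    """
    schedule = schedule if schedule is not None else default_schedule()
    shares = {str(k): float(v) for k, v in bracket_shares.items()}
    vals = np.array(list(shares.values()))
    if (vals < 0).any():
        raise DataError(f"bracket shares must be nonnegative, got {shares}")
    if not np.isclose(vals.sum(), 1.0):
        raise DataError(f"bracket shares must sum to 1, got {vals.sum():.6f}")
    upper_masses = dist.interval_masses[1:]  # intervals with lower endpoints p1..p4
    mu = 0.0
    for bracket, share in shares.items():
        endpoints = np.array([schedule.amount(j, bracket) for j in (1, 2, 3, 4)])
        mu += share * float(endpoints @ upper_masses)
    return LowerBoundWtp(mu_lower=float(mu), bracket_shares=shares, schedule=schedule)


@dataclass
class ApprovalComparison:
    """Approval distributions under two levels of one attribute, with
    per-threshold approval differences and cluster-robust SEs."""

    attribute: str
    level_a0: str
    level_a1: str
    dist_a0: WtpDistribution
    dist_a1: WtpDistribution
    diff: np.ndarray      # approval(a1, k) - approval(a0, k), k = 1..4
    diff_se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "attribute": self.attribute, "a0": self.level_a0, "a1": self.level_a1,
            "threshold": f"p{k + 1}", "approval_a0": self.dist_a0.approval_rates[k],
            "approval_a1": self.dist_a1.approval_rates[k],
            "diff": self.diff[k], "se": self.diff_se[k],
            "ci_lo": self.diff[k] - _Z975 * self.diff_se[k],
            "ci_hi": self.diff[k] + _Z975 * self.diff_se[k],
        } for k in range(4)]
        return pd.DataFrame(rows)


def approval_by_attribute(
    observations: pd.DataFrame,
    attribute: str,
    level_a0: str,
    level_a1: str,
    outcome_col: str = "Y_external",
    cluster_col: str = "respondent_id",
) -> ApprovalComparison:
    """Compare the WTP/approval distribution between the ``a0`` and ``a1``
    subsamples of one attribute (a baseline -> new-level change),
    on boundary-filtered data."""
    if attribute not in observations.columns:
        raise DataError(f"observations lack attribute column {attribute!r}")
    if level_a0 == level_a1:  # identical subsets: zero difference by construction
        sub = observations[observations[attribute].astype(str) == level_a0]
        if sub.empty:
            raise EstimationError(f"empty subset: {attribute}={level_a0!r}")
        dist = marginal_cdf(sub, outcome_col, cluster_col)
        return ApprovalComparison(
            attribute=attribute, level_a0=level_a0, level_a1=level_a1,
            dist_a0=dist, dist_a1=dist, diff=np.zeros(4), diff_se=np.zeros(4),
        )
    subsets = {}
    for lvl in (level_a0, level_a1):
        sub = observations[observations[attribute].astype(str) == lvl]
        if sub.empty:
            raise EstimationError(f"empty subset: {attribute}={lvl!r}")
        subsets[lvl] = sub
    dist_a0 = marginal_cdf(subsets[level_a0], outcome_col, cluster_col)
    dist_a1 = marginal_cdf(subsets[level_a1], outcome_col, cluster_col)

    diffs, ses = [], []
    both = observations[observations[attribute].astype(str).isin([level_a0, level_a1])]
    for k in (1, 2, 3, 4):
        cell = both[both["premium_level"].astype(int) == k]
        g = (cell[attribute].astype(str) == level_a1).astype(float).to_numpy()
        X = np.column_stack([np.ones(len(cell)), g])
        res = sm.OLS(cell[outcome_col].astype(float).to_numpy(), X).fit(
            cov_type="cluster",
            cov_kwds={"groups": cell[cluster_col].to_numpy(), "use_correction": True},
            use_t=False,
        )
        diffs.append(float(res.params[1]))
        ses.append(float(res.bse[1]))
    return ApprovalComparison(
        attribute=attribute, level_a0=level_a0, level_a1=level_a1,
        dist_a0=dist_a0, dist_a1=dist_a1,
        diff=np.array(diffs), diff_se=np.array(ses),
    )


def income_share(mu_monthly_lak: float, annual_income_lak: float) -> float:
    """A monthly WTP bound as a percentage of one-twelfth of an annual
    income figure."""
    if annual_income_lak <= 0:
        raise DataError("annual income must be positive")
    return 100.0 * mu_monthly_lak / (annual_income_lak / 12.0)


def empirical_bracket_shares(observations: pd.DataFrame) -> dict[str, float]:
    """Household-size-bracket shares of the distinct respondents in a table."""
    resp = observations.drop_duplicates("respondent_id")
    counts = resp["size_bracket"].astype(str).value_counts()
    return {b: float(c) / float(len(resp)) for b, c in counts.items()}


class WtpEstimator(BaseEstimator):
    """Full WTP analysis as a fit-shaped estimator.

    ``fit`` applies the boundary filter (optional), estimates the marginal
    WTP distribution, and computes the lower-bound mean using the supplied
    bracket shares (default: the empirical shares of the respondents in the
    data).

    Attributes (after :meth:`fit`)
    ------------------------------
    distribution_ : WtpDistribution
    f_hat_, interval_masses_, approval_rates_ : np.ndarray
    mu_lower_ : float            lower bound on mean WTP, LAK/month
    bracket_shares_ : dict
    n_obs_ : int                 rows in the analysis subsample
    """

    def __init__(
        self,
        specs: Sequence[AttributeSpec] | None = None,
        schedule: PremiumSchedule | None = None,
        apply_boundary_filter: bool = True,
        bracket_shares: Mapping[str, float] | None = None,
        isotonic: bool = False,
        cluster_col: str = "respondent_id",
    ):
        self.specs = specs
        self.schedule = schedule
        self.apply_boundary_filter = apply_boundary_filter
        self.bracket_shares = bracket_shares
        self.isotonic = isotonic
        self.cluster_col = cluster_col

    def fit(self, X: pd.DataFrame, y=None) -> "WtpEstimator":
        specs = validate_attributes(self.specs if self.specs is not None else default_attributes())
        schedule = self.schedule if self.schedule is not None else default_schedule()
        data = boundary_filter(X, specs) if self.apply_boundary_filter else X
        if data.empty:
            raise EstimationError("boundary filter left no observations")
        dist = marginal_cdf(data, cluster_col=self.cluster_col)
        if self.isotonic:
            dist = dist.isotonic()
        shares = (
            dict(self.bracket_shares)
            if self.bracket_shares is not None
            else empirical_bracket_shares(data)
        )
        bound = lower_bound_mean(dist, shares, schedule)

        self.filtered_ = data
        self.distribution_ = dist
        self.f_hat_ = dist.f_hat
        self.interval_masses_ = dist.interval_masses
        self.approval_rates_ = dist.approval_rates
        self.mu_lower_ = bound.mu_lower
        self.bracket_shares_ = shares
        self.n_obs_ = dist.n_obs
        return self

    def compare_levels(self, attribute: str, level_a0: str, level_a1: str) -> ApprovalComparison:
        """Baseline -> new-level attribute change on the fitted analysis subsample."""
        return approval_by_attribute(self.filtered_, attribute, level_a0, level_a1,
                                     cluster_col=self.cluster_col)
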