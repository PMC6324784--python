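"""WTP distribution identification, lower-bound mean, approval comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cbhi_conjoint as cc
from cbhi_conjoint.errors import DataError, EstimationError
from cbhi_conjoint.wtp import INTERVAL_LABELS

from conftest import make_respondent, profile_with


def cell_observations(means, n_per=20, n_clusters=5):
    """Observations whose per-premium-level Y_external means are exact."""
    rows = []
    for k, m in enumerate(means, start=1):
        ones = round(m * n_per)
        for i in range(n_per):
            rows.append({"premium_level": k, "Y_external": int(i < ones),
                         "respondent_id": i % n_clusters})
    return pd.DataFrame(rows)


class TestBoundaryFilter:
    def test_drops_below_status_quo_rows(self, specs, survey):
        _, obs = survey
        kept = cc.boundary_filter(obs, specs)
        assert (kept["consultations"] == "Yes").all()
        assert (kept["hospitalizations"] == "Yes").all()
        # two independent binary attributes at 1/2 each -> about a quarter kept
        assert abs(len(kept) / len(obs) - 0.25) < 0.04

    def test_trivial_rows(self, specs):
        df = pd.DataFrame([
            {"consultations": "No", "hospitalizations": "Yes"},
            {"consultations": "Yes", "hospitalizations": "Yes"},
        ])
        kept = cc.boundary_filter(df, specs)
        assert len(kept) == 1 and kept.iloc[0]["consultations"] == "Yes"


class TestMarginalCdf:
    def test_universal_approval(self):
        dist = cc.marginal_cdf(cell_observations([1, 1, 1, 1]))
        assert np.allclose(dist.f_hat, 0.0)
        assert np.allclose(dist.interval_masses, [0, 0, 0, 0, 1])
        assert np.allclose(dist.approval_rates, 1.0)
        assert np.all(dist.interval_se == 0.0)

    def test_interval_mass_arithmetic(self):
        """Means (0.9, 0.8, 0.7, 0.6) across levels give masses
        (0.1, 0.1, 0.1, 0.1, 0.6) by successive differences."""
        dist = cc.marginal_cdf(cell_observations([0.9, 0.8, 0.7, 0.6]))
        assert np.allclose(dist.f_hat, [0.1, 0.2, 0.3, 0.4])
        assert np.allclose(dist.interval_masses, [0.1, 0.1, 0.1, 0.1, 0.6])

    def test_identities_on_survey_data(self, survey):
        """Telescoping: masses sum to 1 exactly; approval(k) + F(p_k) = 1."""
        _, obs = survey
        dist = cc.marginal_cdf(cc.boundary_filter(obs))
        assert dist.interval_masses.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(dist.approval_rates + dist.f_hat, 1.0, atol=1e-12)
        assert dist.n_per_level.sum() == dist.n_obs

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=20), min_size=4, max_size=4))
    def test_identities_for_arbitrary_cell_means(self, ones):
        dist = cc.marginal_cdf(cell_observations([o / 20 for o in ones]))
        assert dist.interval_masses.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(dist.approval_rates + dist.f_hat, 1.0, atol=1e-12)

    def test_empty_premium_cell_rejected(self):
        obs = cell_observations([0.5, 0.5, 0.5, 0.5])
        with pytest.raises(EstimationError, match="premium level"):
            cc.marginal_cdf(obs[obs["premium_level"] != 3])

    def test_uniform_wtp_recovers_closed_form_cdf(self, specs, schedule):
        """WTP ~ Uniform(0, 32,000) in a single 2-4-member bracket: F(p_k)
        estimates threshold/32,000 at thresholds 18k/20k/22k/24k."""
        rng = np.random.default_rng(21)
        n = 2000
        tasks = []
        for t, (la, lb) in enumerate((("p1", "p2"), ("p3", "p4"))):
            tasks.append(cc.ChoiceTask(
                t, 0,
                profile_with(specs, premium=la, traffic_accidents="Yes"),
                profile_with(specs, premium=lb, traffic_accidents="Yes"),
                cc.status_quo_profile(specs)))
        plan = cc.DesignPlan(specs=specs, choice_sets=[tasks], seed=0)
        respondents, rankings = [], []
        for i in range(n):
            r = make_respondent(rid=i, bracket="2-4")
            # WTP = part-worth + current premium (20,000) ~ U(0, 32,000)
            r.part_worths[("traffic_accidents", "Yes")] = float(rng.uniform(-20_000, 12_000))
            respondents.append(r)
            for task in tasks:
                rankings.append(cc.rank_task(r, task, specs, schedule, rng=rng))
        obs = cc.build_observations(rankings, plan, respondents, schedule)
        dist = cc.marginal_cdf(cc.boundary_filter(obs, specs))
        expected = np.array([18, 20, 22, 24]) * 1000 / 32_000
        assert np.all(dist.n_per_level == n)
        assert np.allclose(dist.f_hat, expected, atol=0.03)
        # estimates should also sit within ~3 cluster-robust SEs of truth
        assert np.all(np.abs(dist.f_hat - expected) < 3.5 * dist.f_hat_se + 1e-9)


class TestLowerBoundMean:
    def make_dist(self, masses):
        masses = np.asarray(masses, dtype=float)
        f = np.cumsum(masses[:4])
        z = np.zeros(4)
        return cc.WtpDistribution(
            f_hat=f, f_hat_se=z, interval_masses=masses, interval_se=np.zeros(5),
            approval_rates=1 - f, approval_se=z, n_obs=100,
            n_per_level=np.full(4, 25), n_clusters=10)

    def test_all_mass_above_p4_single_bracket(self, schedule):
        dist = self.make_dist([0, 0, 0, 0, 1])
        shares = {"1": 0.0, "2-4": 1.0, "5-7": 0.0, "8+": 0.0}
        assert cc.lower_bound_mean(dist, shares, schedule).mu_lower == 24_000

    def test_all_mass_below_p1_is_zero(self, schedule):
        dist = self.make_dist([1, 0, 0, 0, 0])
        shares = {"1": 0.25, "2-4": 0.25, "5-7": 0.25, "8+": 0.25}
        assert cc.lower_bound_mean(dist, shares, schedule).mu_lower == 0.0

    def test_hand_computed_inner_product(self, schedule):
        """Masses (0, .1, .2, .3, .4) on bracket 1 (10/12/14/16 thousand):
        mu = .1*10,000 + .2*12,000 + .3*14,000 + .4*16,000 = 14,000."""
        dist = self.make_dist([0.0, 0.1, 0.2, 0.3, 0.4])
        shares = {"1": 1.0, "2-4": 0.0, "5-7": 0.0, "8+": 0.0}
        assert cc.lower_bound_mean(dist, shares, schedule).mu_lower == pytest.approx(14_000)

    def test_single_bracket_equals_scalar_form(self, schedule):
        """With one bracket the weighted form reduces to the scalar
        sum over thresholds c_j * mass_{j+1} — two code paths, one answer."""
        rng = np.random.default_rng(3)
        raw = rng.dirichlet(np.ones(5))
        dist = self.make_dist(raw)
        for bracket in cc.BRACKETS:
            shares = {b: float(b == bracket) for b in cc.BRACKETS}
            scalar = sum(
                cc.realize_premium(j, bracket, schedule) * raw[j]
                for j in (1, 2, 3, 4)
            )
            got = cc.lower_bound_mean(dist, shares, schedule).mu_lower
            assert got == pytest.approx(scalar, abs=1e-9)

    def test_share_validation(self, schedule):
        dist = self.make_dist([0, 0, 0, 0, 1])
        with pytest.raises(DataError, match="nonnegative"):
            cc.lower_bound_mean(dist, {"1": -0.5, "2-4": 1.5}, schedule)
        with pytest.raises(DataError, match="sum to 1"):
            cc.lower_bound_mean(dist, {"1": 0.7}, schedule)

    def test_bound_does_not_exceed_weighted_p4(self, survey, schedule):
        _, obs = survey
        est = cc.WtpEstimator().fit(obs)
        weighted_p4 = sum(s * cc.realize_premium(4, b, schedule)
                          for b, s in est.bracket_shares_.items())
        assert 0 <= est.mu_lower_ <= weighted_p4


class TestNegativeMassesAndIsotonic:
    def test_raw_negative_mass_reported(self):
        dist = cc.marginal_cdf(cell_observations([0.9, 0.95, 0.7, 0.6]))
        assert dist.interval_masses[1] == pytest.approx(-0.05)
        assert dist.interval_masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_isotonic_projection(self):
        dist = cc.marginal_cdf(cell_observations([0.9, 0.95, 0.7, 0.6]))
        iso = dist.isotonic()
        assert np.all(np.diff(iso.f_hat) >= -1e-12)
        assert np.all(iso.interval_masses >= -1e-12)
        assert iso.interval_masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cumulative_approval_clips_negative_mass(self):
        """With F(p1) = 6.74% and a negative second interval treated as zero,
        approval up to p3 is 100% - 6.74% = 93.26%."""
        masses = np.array([0.0674, -0.012, 0.05, 0.08, 0.8146 + 0.012 - 0.0674 + 0.0674])
        masses[-1] = 1 - masses[:4].sum()
        f = np.cumsum(masses[:4])
        dist = cc.WtpDistribution(
            f_hat=f, f_hat_se=np.zeros(4), interval_masses=masses,
            interval_se=np.zeros(5), approval_rates=1 - f, approval_se=np.zeros(4),
            n_obs=100, n_per_level=np.full(4, 25), n_clusters=10)
        assert dist.cumulative_approval(2) == pytest.approx(1 - 0.0674)
        assert dist.cumulative_approval(2, clip_negative_masses=False) == pytest.approx(
            1 - 0.0674 + 0.012)


class TestApprovalByAttribute:
    def test_same_level_gives_zero_difference(self, survey):
        _, obs = survey
        filt = cc.boundary_filter(obs)
        cmp = cc.approval_by_attribute(filt, "transportation", "No", "No")
        assert np.all(cmp.diff == 0.0) and np.all(cmp.diff_se == 0.0)

    def test_exact_shift_recovered_by_reranking(self, specs, schedule):
        """Round-trip coverage worth exactly 5,000 LAK to everyone shifts the
        WTP distribution by 5,000; with WTP 20,500 vs 25,500 and thresholds
        18/20/22/24k the approval pattern moves (1,1,0,0) -> (1,1,1,1)."""
        tasks = []
        for k in (1, 2, 3, 4):
            tasks.append(cc.ChoiceTask(
                k - 1, 0,
                profile_with(specs, premium=f"p{k}", pharmaceuticals="Fully"),
                profile_with(specs, premium=f"p{k}", pharmaceuticals="Fully",
                             transportation="Round trip"),
                cc.status_quo_profile(specs)))
        plan = cc.DesignPlan(specs=specs, choice_sets=[tasks], seed=0)
        rng = np.random.default_rng(2)
        respondents, rankings = [], []
        for i in range(6):
            r = make_respondent(rid=i, bracket="2-4")
            r.part_worths[("pharmaceuticals", "Fully")] = 500.0
            r.part_worths[("transportation", "Round trip")] = 5_000.0
            respondents.append(r)
            for task in tasks:
                rankings.append(cc.rank_task(r, task, specs, schedule, rng=rng))
        obs = cc.build_observations(rankings, plan, respondents, schedule)
        cmp = cc.approval_by_attribute(cc.boundary_filter(obs, specs),
                                       "transportation", "No", "Round trip")
        assert np.allclose(cmp.dist_a0.approval_rates, [1, 1, 0, 0])
        assert np.allclose(cmp.dist_a1.approval_rates, [1, 1, 1, 1])
        assert np.allclose(cmp.diff, [0, 0, 1, 1])

    def test_top_bin_shift_within_two_se_of_analytic_truth(self, survey, specs,
                                                           schedule):
        """Parameter recovery: the estimated round-trip effect on the top-bin
        approval rate sits within two cluster-robust SEs of the analytic
        truth computed by enumerating profiles for the realized population."""
        respondents, obs = survey
        filt = cc.boundary_filter(obs, specs)
        cmp = cc.approval_by_attribute(filt, "transportation", "No", "Round trip")
        sigma = cc.PopulationModel().noise_scale * np.sqrt(2)

        # enumerate the boundary-satisfying profile universe at premium p4
        keys = [("traffic_accidents", "Yes"), ("pharmaceuticals", "Fully"),
                ("prepaid_discount", "5%"), ("prepaid_discount", "10%")]
        truth = {}
        for transport in ("No", "Round trip"):
            probs = []
            for r in respondents:
                p4 = cc.realize_premium(4, r.size_bracket, schedule)
                cur = schedule.current(r.size_bracket)
                tw = (r.part_worths[("transportation", transport)]
                      if transport != "No" else 0.0)
                # uniform marginal over traffic (2) x pharma (2) x discount (3)
                cell_p = []
                for ta in (0.0, r.part_worths[("traffic_accidents", "Yes")]):
                    for ph in (0.0, r.part_worths[("pharmaceuticals", "Fully")]):
                        for di in (0.0, r.part_worths[("prepaid_discount", "5%")],
                                   r.part_worths[("prepaid_discount", "10%")]):
                            wtp = ta + ph + di + tw + cur
                            cell_p.append(stats.norm.cdf((wtp - p4) / sigma))
                probs.append(np.mean(cell_p))
            truth[transport] = np.mean(probs)
        delta = truth["Round trip"] - truth["No"]
        assert abs(cmp.diff[3] - delta) < 2 * cmp.diff_se[3]


class TestWtpEstimator:
    def test_fitted_attributes_and_frame(self, survey):
        _, obs = survey
        est = cc.WtpEstimator().fit(obs)
        assert est.n_obs_ == len(cc.boundary_filter(obs))
        frame = est.distribution_.to_frame()
        assert set(frame["quantity"]) == {"F_hat", "approval_rate", "interval_mass"}
        assert list(frame[frame["quantity"] == "interval_mass"]["interval"]) == list(INTERVAL_LABELS)

    def test_explicit_shares_override_empirical(self, survey, schedule):
        _, obs = survey
        shares = {"1": 0.0, "2-4": 1.0, "5-7": 0.0, "8+": 0.0}
        est = cc.WtpEstimator(bracket_shares=shares).fit(obs)
        manual = cc.lower_bound_mean(est.distribution_, shares, schedule)
        assert est.mu_lower_ == manual.mu_lower
        assert est.bracket_shares_ == shares

    def test_sklearn_params_roundtrip(self):
        est = cc.WtpEstimator(isotonic=True)
        assert est.get_params()["isotonic"] is True
        est.set_params(isotonic=False)
        assert est.get_params()["isotonic"] is False


class TestIncomeShare:
    def test_printed_income_ratios(self):
        assert cc.income_share(25_579, 2.81e6) == pytest.approx(10.92, abs=0.01)
        assert cc.income_share(25_579, 9.31e6) == pytest.approx(3.297, abs=0.005)

    def test_nonpositive_income_rejected(self):
        with pytest.raises(DataError):
            cc.income_share(25_579, 0.0)
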