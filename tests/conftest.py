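import numpy as np
import pytest

import cbhi_conjoint as cc


@pytest.fixture(scope="session")
def specs():
    return cc.default_attributes()


@pytest.fixture(scope="session")
def schedule():
    return cc.default_schedule()


@pytest.fixture(scope="session")
def plan575(specs):
    """The full-size design: 575 pairs in 115 choice sets of 5 tasks."""
    return cc.randomize_design(specs, n_pairs=575, tasks_per_set=5, seed=7)


@pytest.fixture(scope="session")
def survey(plan575, schedule):
    """One standard synthetic survey: 580 respondents, noisy choices."""
    model = cc.PopulationModel()
    respondents, obs = cc.simulate_survey(plan575, model, schedule, seed=7)
    return respondents, obs


@pytest.fixture(scope="session")
def zero_noise_survey(plan575, schedule):
    """Deterministic choices: same population heterogeneity, no choice noise."""
    model = cc.default_population_model(noise_scale=0.0)
    respondents, obs = cc.simulate_survey(plan575, model, schedule, seed=11)
    return respondents, obs


def make_respondent(rid=0, bracket="2-4", base=30_000.0, noise=0.0):
    """Respondent with all part-worths zero (set individual levels as needed)."""
    pw = {
        ("consultations", "No"): 0.0,
        ("hospitalizations", "No"): 0.0,
        ("traffic_accidents", "Yes"): 0.0,
        ("pharmaceuticals", "Fully"): 0.0,
        ("transportation", "One way"): 0.0,
        ("transportation", "Round trip"): 0.0,
        ("prepaid_discount", "5%"): 0.0,
        ("prepaid_discount", "10%"): 0.0,
    }
    return cc.Respondent(id=rid, size_bracket=bracket, base_value=base,
                         part_worths=pw, noise_scale=noise)


def profile_with(specs, **levels):
    """Status-quo profile with some attribute levels overridden."""
    lv = {s.name: s.reference_level for s in specs}
    lv.update(levels)
    return cc.Profile(tuple(lv[s.name] for s in specs))
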