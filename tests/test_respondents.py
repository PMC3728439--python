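"""Synthetic respondents: decision rule, bias mechanisms, timing model,
population sampling and the end-to-end study simulator."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leadtto.core import (
    CHINA_EXPERIMENTAL,
    CHINA_STANDARD,
    ConfigError,
    HealthState,
    Offer,
    Response,
    SINGAPORE_EXPERIMENTAL,
    SINGAPORE_STANDARD,
    TaskConfig,
)
from leadtto.engine import run_task
from leadtto.respondents import (
    ProfileParams,
    RespondentProfile,
    StudyDesign,
    sample_population,
    simulate_study,
)

from conftest import SUITE_SEED, exact_agent

STATE = HealthState("11145")
RNG = np.random.default_rng(0)


def offer_at_value(u, cfg, ordinal=1):
    return Offer(duration=cfg.lead_time + u * cfg.unhealthy_time, ordinal=ordinal)


class TestDecide:
    def test_exact_match_within_tolerance_is_indifferent(self, cfg10):
        agent = exact_agent(0.5, indifference_tol=0.1)
        r = agent.decide(offer_at_value(0.5, cfg10), STATE, cfg10, RNG)
        assert r is Response.INDIFFERENT

    def test_strictly_better_offer_preferred(self, cfg10):
        agent = exact_agent(0.5)
        assert agent.decide(offer_at_value(1.0, cfg10), STATE, cfg10, RNG) is Response.PREFER_B
        assert agent.decide(offer_at_value(0.0, cfg10), STATE, cfg10, RNG) is Response.PREFER_A

    def test_framing_bias_lowers_effective_utility_only_at_high_ratio(self):
        agent = exact_agent(0.40, framing_coeff=0.04)
        # LT/UT = 2: one unit of ratio excess
        assert agent.effective_utility(STATE, CHINA_STANDARD) == pytest.approx(0.36)
        # LT/UT = 1: bias vanishes
        assert agent.effective_utility(STATE, CHINA_EXPERIMENTAL) == pytest.approx(0.40)

    def test_visual_error_bias_scales_with_bar_length(self):
        agent = exact_agent(0.40, visual_error_coeff=0.1)
        # 15-year bar: excess (15-10)/10 = 0.5
        assert agent.effective_utility(STATE, CHINA_STANDARD) == pytest.approx(0.35)
        assert agent.effective_utility(STATE, CHINA_EXPERIMENTAL) == pytest.approx(0.40)

    def test_engagement_shrinks_tolerance_only_near_dead_raised_bar(self):
        agent = exact_agent(0.0, indifference_tol=0.1, engagement_gain=1.0)
        mid = offer_at_value(0.1, SINGAPORE_EXPERIMENTAL)
        # |v| <= 0.5 on the raised-bar variant: tolerance halves, 0.1 > 0.05
        assert agent.decide(mid, STATE, SINGAPORE_EXPERIMENTAL, RNG) is Response.PREFER_B
        # same offer on the aligned variant: full tolerance, indifferent
        assert agent.decide(mid, STATE, SINGAPORE_STANDARD, RNG) is Response.INDIFFERENT
        # away from dead the raised-bar tolerance is untouched
        agent_far = exact_agent(1.0, indifference_tol=0.1, engagement_gain=1.0)
        far = offer_at_value(0.9, SINGAPORE_EXPERIMENTAL)
        assert (
            agent_far.decide(far, STATE, SINGAPORE_EXPERIMENTAL, RNG)
            is Response.INDIFFERENT
        )

    def test_negative_parameters_rejected(self):
        with pytest.raises(ConfigError):
            exact_agent(0.5, decision_sd=-0.1)
        with pytest.raises(ConfigError):
            RespondentProfile("a", {"11145": 1.5})


class TestResponseTime:
    def test_no_engagement_no_variant_effect(self):
        agent = exact_agent(0.2, engagement_gain=0.0, time_sd=0.0)
        off = offer_at_value(0.2, SINGAPORE_STANDARD)
        t_std = agent.response_time(off, STATE, SINGAPORE_STANDARD, RNG)
        t_exp = agent.response_time(
            offer_at_value(0.2, SINGAPORE_EXPERIMENTAL), STATE, SINGAPORE_EXPERIMENTAL, RNG
        )
        assert t_std == t_exp == math.exp(agent.base_log_time)

    def test_deliberated_raised_bar_offer_exactly_doubles(self):
        agent = exact_agent(0.2, engagement_gain=1.0, time_sd=0.0)
        off = offer_at_value(0.25, SINGAPORE_EXPERIMENTAL)  # near u_eff, near dead
        t_exp = agent.response_time(off, STATE, SINGAPORE_EXPERIMENTAL, RNG)
        t_std = agent.response_time(
            offer_at_value(0.25, SINGAPORE_STANDARD), STATE, SINGAPORE_STANDARD, RNG
        )
        assert t_exp == 2 * t_std

    def test_no_inflation_when_indifference_region_far_from_dead(self):
        agent = exact_agent(0.9, engagement_gain=1.0, time_sd=0.0)
        off = offer_at_value(0.8, SINGAPORE_EXPERIMENTAL)
        assert agent.response_time(off, STATE, SINGAPORE_EXPERIMENTAL, RNG) == math.exp(
            agent.base_log_time
        )


class TestSamplePopulation:
    def test_seed_determinism(self):
        design = StudyDesign(n_per_arm=2, seed=7)
        params = ProfileParams()
        p1 = sample_population(design, params)
        p2 = sample_population(design, params)
        assert [a.true_utilities for a in p1] == [b.true_utilities for b in p2]
        assert [a.age_group for a in p1] == [b.age_group for b in p2]

    def test_degenerate_sd_gives_state_means(self):
        params = ProfileParams(state_sd=0.0, respondent_sd=0.0)
        pop = sample_population(StudyDesign(n_per_arm=2, seed=1), params)
        for agent in pop:
            for s, u in agent.true_utilities.items():
                assert u == params.state_means[s]

    def test_utilities_within_support(self):
        params = ProfileParams(state_sd=0.8, respondent_sd=0.4)
        pop = sample_population(StudyDesign(n_per_arm=50, seed=3), params)
        us = [u for a in pop for u in a.true_utilities.values()]
        assert min(us) >= -2.0 and max(us) <= 1.0

    def test_bad_design_rejected(self):
        with pytest.raises(ConfigError):
            StudyDesign(n_per_arm=0)
        with pytest.raises(ConfigError):
            StudyDesign(n_per_arm=2, blocks=((), ("11145",)))

    def test_noise_free_population_recovers_means_to_grid_resolution(self):
        """With zero noise/bias, simulated per-state means equal the
        generating means after grid rounding (resolution 0.05)."""
        params = ProfileParams(
            state_sd=0.0, respondent_sd=0.0, decision_sd=0.0,
            indifference_tol=0.0, framing_coeff=0.0, visual_error_coeff=0.0,
            engagement_gain=0.0, time_sd=0.0,
        )
        configs = {"standard": CHINA_STANDARD, "experimental": CHINA_EXPERIMENTAL}
        df = simulate_study(StudyDesign(n_per_arm=4, seed=2), params, configs)
        for s, grp in df.groupby("state"):
            assert abs(grp["U"].mean() - params.state_means[s]) <= 0.05 / 2 + 1e-12


class TestSimulateStudy:
    def test_record_count_and_columns(self):
        params = ProfileParams(time_sd=0.0)
        configs = {"standard": CHINA_STANDARD, "experimental": CHINA_EXPERIMENTAL}
        df = simulate_study(StudyDesign(n_per_arm=1, seed=5), params, configs)
        assert len(df) == 10  # 2 respondents x 5 states
        assert df["respondent_id"].nunique() == 2
        assert set(df["arm"]) == {"standard", "experimental"}

    def test_seed_determinism_byte_identical(self):
        params = ProfileParams()
        configs = {"standard": CHINA_STANDARD, "experimental": CHINA_EXPERIMENTAL}
        a = simulate_study(StudyDesign(n_per_arm=5, seed=11), params, configs)
        b = simulate_study(StudyDesign(n_per_arm=5, seed=11), params, configs)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_study(StudyDesign(n_per_arm=5, seed=12), params, configs)
        assert not a["U"].equals(c["U"])

    def test_no_censoring_when_utilities_inside_range(self):
        params = ProfileParams(
            state_sd=0.0, respondent_sd=0.0, decision_sd=0.0,
            indifference_tol=0.0, time_sd=0.0,
            framing_coeff=0.0, visual_error_coeff=0.0,
        )
        configs = {"standard": CHINA_STANDARD, "experimental": CHINA_EXPERIMENTAL}
        df = simulate_study(StudyDesign(n_per_arm=4, seed=2), params, configs)
        assert not df["censored"].any()

    def test_censored_fraction_matches_analytic_truncnorm_mass(self):
        """With a framing bias pushing effective utilities below -LT/UT,
        censoring has a closed form: a task is censored iff u_eff lies
        closer to the floor than to the lowest positive grid value, i.e.
        u* - kappa < -2 + resolution/2, a truncated-normal tail mass."""
        mean, sd, kappa = -1.8, 0.15, 0.1
        a, b = (-2.0 - mean) / sd, (1.0 - mean) / sd
        # censored iff u* - kappa < -1.975 (closest grid endpoint is T=0)
        p_cens = stats.truncnorm.cdf(-1.875, a, b, loc=mean, scale=sd)
        params = ProfileParams(
            state_means={s: mean for s in ProfileParams().state_means},
            state_sd=sd, respondent_sd=0.0, decision_sd=0.0,
            indifference_tol=0.0, framing_coeff=kappa,
            visual_error_coeff=0.0, engagement_gain=0.0, time_sd=0.0,
        )
        configs = {"standard": CHINA_STANDARD, "experimental": CHINA_STANDARD}
        df = simulate_study(StudyDesign(n_per_arm=150, seed=SUITE_SEED), params, configs)
        n = len(df)
        observed = df["censored"].mean()
        se = math.sqrt(p_cens * (1 - p_cens) / n)
        assert abs(observed - p_cens) < 3.5 * se

    def test_bias_direction_longer_lead_time_lowers_values(self):
        """kappa > 0 or nu > 0 make the 10-year-lead-time arm's mean value
        fall below the 5-year arm's, the direction of the lead-time finding."""
        configs = {"standard": CHINA_STANDARD, "experimental": CHINA_EXPERIMENTAL}
        for bias in ({"framing_coeff": 0.06}, {"visual_error_coeff": 0.12}):
            kwargs = dict(
                state_sd=0.1, respondent_sd=0.1, decision_sd=0.15,
                indifference_tol=0.05, framing_coeff=0.0,
                visual_error_coeff=0.0, engagement_gain=0.0, time_sd=0.0,
            )
            kwargs.update(bias)
            params = ProfileParams(**kwargs)
            df = simulate_study(StudyDesign(n_per_arm=150, seed=SUITE_SEED), params, configs)
            means = df.groupby("arm")["U"].mean()
            assert means["standard"] < means["experimental"]

    def test_missing_arm_config_rejected(self):
        with pytest.raises(ConfigError):
            simulate_study(
                StudyDesign(n_per_arm=1, seed=1),
                ProfileParams(),
                {"standard": CHINA_STANDARD},
            )
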