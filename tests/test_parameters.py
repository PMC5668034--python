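"""Transition-probability machinery: conversions, hazard ratios, life table,
distributions, scenario assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hercea.config import ScenarioConfig
from hercea.errors import ConfigurationError
from hercea.parameters import (
    LifeTable,
    ParameterDistribution,
    apply_hazard_ratio,
    background_mortality,
    build_scenario_parameters,
    derive_lr_probability,
    probability_from_rate,
    rate_from_annual_probability,
)


class TestRateConversion:
    @pytest.mark.parametrize("p, rate", [
        (0.0, 0.0),
        (0.026, 0.02634397533960195),      # subsequent-year overall mortality
        (1.0 - math.exp(-2.0), 2.0),
    ])
    def test_known_values(self, p, rate):
        assert rate_from_annual_probability(p) == pytest.approx(rate, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=0.999))
    def test_round_trip(self, p):
        assert probability_from_rate(rate_from_annual_probability(p)) == \
            pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("p", [1.0, -0.1, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            rate_from_annual_probability(p)


class TestApplyHazardRatio:
    def test_identity_hr(self):
        for cycle in (1, 5, 20):
            assert apply_hazard_ratio(0.3, 1.0, cycle, 8) == pytest.approx(0.3)

    def test_reverts_after_benefit_window(self):
        assert apply_hazard_ratio(0.026, 2.0, 9, 8) == 0.026

    def test_rate_scale_application(self):
        # closed form: -ln(0.8) * 0.5 back-transformed
        assert apply_hazard_ratio(0.2, 0.5, 1, 8) == \
            pytest.approx(0.10557280900008414, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=0.99),
           st.floats(min_value=0.05, max_value=5.0),
           st.floats(min_value=0.05, max_value=5.0))
    def test_monotone_in_hr(self, p, hr1, hr2):
        lo, hi = sorted((hr1, hr2))
        assert apply_hazard_ratio(p, lo, 1, 8) <= \
            apply_hazard_ratio(p, hi, 1, 8) + 1e-15


class TestDeriveLR:
    @pytest.mark.parametrize("p_dfs, p_dm, expected", [
        (0.054, 0.041, 0.013),   # subsequent-year cohort values
        (0.03, 0.05, 0.0),       # trial-style: DM event dominates, no LR
        (0.2, 0.2, 0.0),
    ])
    def test_values(self, p_dfs, p_dm, expected):
        assert derive_lr_probability(p_dfs, p_dm) == pytest.approx(expected)

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_never_exceeds_dfs_event(self, p_dfs, p_dm):
        p_lr = derive_lr_probability(p_dfs, p_dm)
        assert p_lr >= 0.0
        if p_lr > 0.0:
            assert p_lr + p_dm <= p_dfs + 1e-15


class TestLifeTable:
    def test_lookup_and_clamping(self):
        lt = LifeTable(np.array([60, 61]), np.array([0.01, 0.012]))
        assert background_mortality(lt, 60, 2) == 0.012
        # past table end: brute-force expectation is the final row
        assert background_mortality(lt, 60, 40) == 0.012
        assert background_mortality(lt, 10, 1) == 0.01  # below start clamps too

    def test_all_zero(self):
        lt = LifeTable(np.array([0, 1, 2]), np.zeros(3))
        assert all(background_mortality(lt, 0, c) == 0.0 for c in range(1, 10))

    def test_empty_table_rejected(self):
        with pytest.raises(ConfigurationError):
            LifeTable(np.array([]), np.array([]))

    def test_non_contiguous_rejected(self):
        with pytest.raises(ConfigurationError):
            LifeTable(np.array([60, 62]), np.array([0.01, 0.012]))


class TestParameterDistribution:
    def test_fixed_returns_mean(self):
        rng = np.random.default_rng(0)
        d = ParameterDistribution(605.0, 0.0, "fixed")
        assert all(d.sample(rng) == 605.0 for _ in range(5))

    def test_zero_se_degenerates(self):
        rng = np.random.default_rng(0)
        assert ParameterDistribution(0.3, 0.0, "beta").sample(rng) == 0.3

    def test_beta_moments(self):
        a, b = ParameterDistribution(0.2, 0.05, "beta").beta_shapes()
        m = a / (a + b)
        v = a * b / ((a + b) ** 2 * (a + b + 1))
        assert m == pytest.approx(0.2)
        assert math.sqrt(v) == pytest.approx(0.05)

    def test_gamma_moments(self):
        shape, scale = ParameterDistribution(12776.0, 798.14, "gamma").gamma_shapes()
        assert shape * scale == pytest.approx(12776.0)
        assert math.sqrt(shape) * scale == pytest.approx(798.14)

    def test_infeasible_beta_se_truncated_with_warning(self):
        d = ParameterDistribution(0.5, 0.6, "beta")  # se^2 > m(1-m)
        with pytest.warns(UserWarning, match="truncated"):
            a, b = d.beta_shapes()
        assert a > 0.0 and b > 0.0

    def test_large_printed_se_is_feasible(self):
        # an SE larger than the mean can still satisfy se^2 < m(1-m)
        a, b = ParameterDistribution(0.016, 0.031, "beta").beta_shapes()
        assert a / (a + b) == pytest.approx(0.016)

    def test_sample_means_converge(self):
        rng = np.random.default_rng(42)
        d = ParameterDistribution(12776.0, 798.14, "gamma")
        draws = np.array([d.sample(rng) for _ in range(20_000)])
        tol = 3.0 * 798.14 / math.sqrt(draws.size)
        assert abs(draws.mean() - 12776.0) < tol


class TestScenarioAssembly:
    def test_real_world_first_year_death_is_zero(self, real_world_config):
        p = build_scenario_parameters("real_world", "trastuzumab",
                                      real_world_config)
        assert p.transitions.death_probability(1) == 0.0

    def test_control_arm_derived_by_hazard_division(self, real_world_config):
        p = build_scenario_parameters("real_world", "control", real_world_config)
        # 1 - (1 - 0.026)^(1/0.76), independent closed form
        assert p.transitions.death_probability(2) == \
            pytest.approx(0.034069241052547605, abs=1e-12)
        # beyond the benefit window the arms share the observed curve
        assert p.transitions.death_probability(9) == pytest.approx(0.026)

    def test_null_treatment_effect_gives_identical_arms(self, real_world_config):
        cfg = real_world_config.with_overrides({
            "hazard_ratios.dfs": 1.0, "hazard_ratios.os": 1.0,
            "hazard_ratios.dm": 1.0, "hazard_ratios.cardiac_rr": 1.0})
        t = build_scenario_parameters("real_world", "trastuzumab", cfg)
        c = build_scenario_parameters("real_world", "control", cfg)
        assert t.transitions == c.transitions
        # arms still differ in acquisition costs
        assert t.trastuzumab_costs.vial_price > 0.0
        assert c.trastuzumab_costs.vial_price == 0.0

    def test_missing_hr_for_derived_control_errors(self, real_world_config):
        raw = {k: v for k, v in real_world_config.raw.items()
               if k != "hazard_ratios"}
        cfg = ScenarioConfig.from_dict(
            dict(raw, life_table={"ages": [0, 1], "q": [0.01, 0.01]}))
        with pytest.raises(ConfigurationError, match="hazard_ratios"):
            build_scenario_parameters("real_world", "control", cfg)

    def test_trial_arms_read_directly_and_cardiac_via_rr(self, trial_config):
        t = build_scenario_parameters("trial", "trastuzumab", trial_config)
        c = build_scenario_parameters("trial", "control", trial_config)
        assert t.transitions.hr_os == 1.0 and c.transitions.hr_os == 1.0
        assert t.transitions.p_death_overall.subsequent == 0.018
        assert c.transitions.p_death_overall.subsequent == 0.0236
        rr = trial_config.value("hazard_ratios.cardiac_rr")
        assert c.transitions.p_cardiac_first_year == pytest.approx(
            t.transitions.p_cardiac_first_year / rr)
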