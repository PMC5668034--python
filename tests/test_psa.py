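"""Probabilistic sensitivity analysis, acceptability curves, value of
information."""

import math

import numpy as np
import pytest

from hercea.psa import (EffectivePopulation, PSAOutput, ceac,
                        evpi_per_patient, population_evpi, run_psa,
                        sample_parameters)
from hercea.scenarios import run_deterministic


def _toy_psa(nmb_pairs, wtp=1.0):
    """PSAOutput whose net benefits at `wtp` equal the given pairs."""
    t, c = zip(*nmb_pairs)
    return PSAOutput(cost_treat=-np.array(t, float),
                     qaly_treat=np.zeros(len(t)),
                     cost_control=-np.array(c, float),
                     qaly_control=np.zeros(len(c)), seed=0)


class TestSampling:
    def test_fixed_parameters_never_vary(self, real_world_config):
        rng = np.random.default_rng(0)
        draws = [real_world_config.sample_draw(rng) for _ in range(3)]
        assert all("trastuzumab.vial_price" not in d for d in draws)
        for d in draws:
            assert 0.0 < d["transitions.death_overall.subsequent"] < 1.0
            assert d["state_costs.dfs.first_year"] > 0.0

    def test_arms_share_the_same_draw(self, real_world_config):
        rng = np.random.default_rng(3)
        treat, control = sample_parameters(real_world_config, rng)
        # the control arm is the treated arm's sampled curve, hazard-divided
        p_t = treat.transitions.p_death_overall.subsequent
        p_c = control.transitions.p_death_overall.subsequent
        assert p_c == p_t
        hr = real_world_config.value("hazard_ratios.os")
        assert control.transitions.hr_os == pytest.approx(1.0 / hr)


class TestRunPsa:
    def test_all_fixed_reproduces_base_case(self, real_world_config):
        frozen = real_world_config.scale_uncertainty(0.0)
        psa = run_psa(frozen, 3, seed=5)
        _, det = run_deterministic(real_world_config)
        assert np.allclose(psa.delta_cost, det.delta_cost)
        assert np.allclose(psa.delta_qaly, det.delta_qaly)

    def test_seed_reproducibility_bit_for_bit(self, real_world_config):
        a = run_psa(real_world_config, 40, seed=11)
        b = run_psa(real_world_config, 40, seed=11)
        assert np.array_equal(a.to_frame().to_numpy()[:, 1:],
                              b.to_frame().to_numpy()[:, 1:])
        c = run_psa(real_world_config, 40, seed=12)
        assert not np.array_equal(a.delta_cost, c.delta_cost)

    def test_mean_matches_deterministic_where_model_is_smooth(
            self, real_world_config):
        # the local-recurrence probability max(0, p_dfs - p_dm) has a kink
        # that biases the probabilistic mean when draws cross it; with the
        # DFS-event uncertainty kept clear of the kink the model is
        # near-linear and the probabilistic mean must agree with the plug-in
        # estimate within Monte Carlo error
        cfg = real_world_config.with_overrides({
            "transitions.dfs_event.first_year.se": 0.004,
            "transitions.dfs_event.subsequent.se": 0.004})
        psa = run_psa(cfg, 1_500, seed=21)
        _, det = run_deterministic(cfg)
        de = psa.delta_qaly
        se = de.std(ddof=1) / math.sqrt(de.size)
        assert abs(de.mean() - det.delta_qaly) < 4.0 * se


class TestCeac:
    def test_definition_at_grid_ends(self):
        psa = PSAOutput(cost_treat=np.array([10.0, -5.0, 20.0]),
                        qaly_treat=np.array([1.0, 1.0, -1.0]),
                        cost_control=np.zeros(3), qaly_control=np.zeros(3),
                        seed=0)
        curve = ceac(psa, [0.0, 1e9])
        # lambda=0: fraction with negative incremental cost
        assert curve.p_cost_effective.iloc[0] == pytest.approx(1 / 3)
        # lambda->inf: fraction with positive incremental effect
        assert curve.p_cost_effective.iloc[1] == pytest.approx(2 / 3)

    def test_degenerate_psa_steps_at_icer(self, guideline_config):
        # push the treated arm into the north-east quadrant, then freeze all
        # uncertainty: the curve is a step function jumping 0 -> 1 at the ICER
        cfg = guideline_config.with_overrides(
            {"trastuzumab.her2_testing": 40_000.0}).scale_uncertainty(0.0)
        _, det = run_deterministic(cfg)
        assert det.label == "icer"
        psa = run_psa(cfg, 5, seed=0)
        curve = ceac(psa, [det.icer - 1.0, det.icer + 1.0])
        assert list(curve.p_cost_effective) == [0.0, 1.0]

    def test_monotone_when_effect_always_positive(self, real_world_config):
        psa = run_psa(real_world_config, 150, seed=2)
        if not np.all(psa.delta_qaly > 0):  # restrict to the stated premise
            keep = psa.delta_qaly > 0
            psa = PSAOutput(psa.cost_treat[keep], psa.qaly_treat[keep],
                            psa.cost_control[keep], psa.qaly_control[keep],
                            seed=2)
        curve = ceac(psa, np.arange(0, 200_001, 5_000))
        assert np.all(np.diff(curve.p_cost_effective) >= 0.0)


class TestEvpi:
    def test_no_uncertainty_no_value(self, real_world_config):
        psa = run_psa(real_world_config.scale_uncertainty(0.0), 4, seed=0)
        assert evpi_per_patient(psa, 80_000.0) == 0.0

    def test_two_iteration_hand_enumeration(self):
        psa = _toy_psa([(10.0, 0.0), (0.0, 10.0)])
        assert evpi_per_patient(psa, 0.0) == pytest.approx(5.0)

    def test_non_negative_and_equals_opportunity_loss(self, real_world_config):
        psa = run_psa(real_world_config, 120, seed=9)
        for wtp in (0.0, 30_000.0, 80_000.0):
            e = evpi_per_patient(psa, wtp)
            assert e >= 0.0
            # equivalent formulation: mean opportunity loss of the strategy
            # that is optimal on average
            nmb_t = wtp * psa.qaly_treat - psa.cost_treat
            nmb_c = wtp * psa.qaly_control - psa.cost_control
            best = nmb_t if nmb_t.mean() >= nmb_c.mean() else nmb_c
            loss = (np.maximum(nmb_t, nmb_c) - best).mean()
            assert e == pytest.approx(loss, abs=1e-9)

    def test_evpi_shrinks_to_zero_with_uncertainty(self, guideline_config):
        # near the decision margin, shrinking every standard error drives the
        # value of information towards 0; the decay is (at most) linear in
        # the SE scale because EVPI there behaves like sigma * phi(z)
        cfg = guideline_config.with_overrides(
            {"trastuzumab.her2_testing": 40_000.0})
        _, det = run_deterministic(cfg)
        wtp = det.icer  # maximally undecided threshold
        values = []
        for factor in (1.0, 0.3, 0.05):
            psa = run_psa(cfg.scale_uncertainty(factor), 250, seed=17)
            values.append(evpi_per_patient(psa, wtp))
        assert values[0] > 0.0
        assert values[2] <= values[1] <= values[0]
        assert values[2] < 0.25 * values[0]


class TestPopulationEvpi:
    def test_discounted_population_multiplier(self):
        pop = EffectivePopulation(1_743.0, 10, 0.04)
        assert pop.discounted_size() == pytest.approx(14_702.782997, abs=1e-4)
        assert population_evpi(2.0, pop) == pytest.approx(29_405.565994, abs=1e-3)

    def test_degenerate_cases(self):
        assert population_evpi(0.0, EffectivePopulation()) == 0.0
        pop = EffectivePopulation(100.0, 5, 0.0)
        assert population_evpi(3.0, pop) == pytest.approx(1_500.0)
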