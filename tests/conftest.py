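"""Shared fixtures and toy-model builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hercea.config import ScenarioConfig
from hercea.parameters import (HealthState, LifeTable, ModelParameters, Period,
                               PeriodProb, TransitionInputs,
                               TrastuzumabCostInputs)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

LIVE = (HealthState.DFS, HealthState.LR, HealthState.DM)


def const_life_table(q: float) -> LifeTable:
    """A life table with the same annual death probability at every age."""
    return LifeTable(np.array([0, 1]), np.array([q, q]))


def _per_state(spec, default):
    out = {}
    for state in LIVE:
        val = default if spec is None else spec.get(state, default)
        if isinstance(val, (int, float)):
            val = {Period.FIRST_YEAR: float(val), Period.SUBSEQUENT: float(val)}
        out[state] = val
    return out


def _pp(x) -> PeriodProb:
    if isinstance(x, PeriodProb):
        return x
    if isinstance(x, tuple):
        return PeriodProb(*x)
    return PeriodProb(x, x)


def toy_params(*, p_death=0.0, p_dfs=0.0, p_dm=0.0, p_cardiac=0.0, q_bg=0.0,
               hr_dm_after_lr=1.0, fixed_dm_mortality=None, horizon=None,
               costs=None, utils=None, disc_c=0.0, disc_e=0.0,
               arm="trastuzumab", cardiac_disutility=0.0, monitoring=0.0,
               tz=None, start_age=55.0, benefit_duration=0,
               hr_os=1.0, hr_dfs=1.0, hr_dm=1.0) -> ModelParameters:
    """A hand-assembled parameter set for engine/economics unit tests.

    Scalars for ``p_*`` apply to both time strata; pass a ``(first,
    subsequent)`` tuple or :class:`PeriodProb` for a split.  Costs default
    to zero and utilities to one.
    """
    transitions = TransitionInputs(
        p_death_overall=_pp(p_death), p_dfs_event=_pp(p_dfs),
        p_dm_event=_pp(p_dm), p_cardiac_first_year=p_cardiac,
        hr_os=hr_os, hr_dfs=hr_dfs, hr_dm=hr_dm,
        benefit_duration=benefit_duration, hr_dm_after_lr=hr_dm_after_lr)
    return ModelParameters(
        arm=arm, scenario="real_world", transitions=transitions,
        state_costs=_per_state(costs, 0.0), utilities=_per_state(utils, 1.0),
        cardiac_monitoring_cost=monitoring, cardiac_disutility=cardiac_disutility,
        trastuzumab_costs=tz or TrastuzumabCostInputs(),
        discount_costs=disc_c, discount_effects=disc_e,
        start_age=start_age, life_table=const_life_table(q_bg),
        horizon=horizon, fixed_dm_mortality=fixed_dm_mortality)


@pytest.fixture(scope="session")
def real_world_config() -> ScenarioConfig:
    return ScenarioConfig.load("real_world")


@pytest.fixture(scope="session")
def guideline_config() -> ScenarioConfig:
    return ScenarioConfig.load("guideline")


@pytest.fixture(scope="session")
def trial_config() -> ScenarioConfig:
    return ScenarioConfig.load("trial")
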