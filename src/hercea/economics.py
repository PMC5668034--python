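"""Discounted, half-cycle-corrected costs, life years and QALYs.

A cohort trace is integrated cycle by cycle: state occupancy is averaged at
cycle boundaries (half-cycle correction, equivalent to trapezoid-rule
integration of person-time), weighted by annual health-state costs and
utilities, and discounted.  Costs and effects carry separate discount rates
(defaults 4.0%/year and 1.5%/year); the first cycle is undiscounted.

First-year versus subsequent-year cost and utility rates are applied
relative to entry into a state: the disease-free state is entered at model
start, so its first-year rate covers cycle 1; for local recurrence and
distant metastases the incident inflow of each cycle contributes half a
cycle of first-year-rated person-time (entrants arrive mid-cycle on
average), with all remaining person-time rated subsequent-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError
from .markov import CohortTrace
from .parameters import HealthState, ModelParameters, Period

__all__ = [
    "EconomicOutcome",
    "discount_factor",
    "half_cycle_value",
    "trastuzumab_acquisition_cost",
    "accumulate",
]

COST_CATEGORIES = ("trastuzumab_treatment", "cardiac", "dfs", "lr", "dm")


def discount_factor(rate: float, cycle_index: int) -> float:
    """Discount factor ``(1 + rate)**-(cycle_index - 1)``; cycle 1 is worth 1."""
    if rate < 0.0:
        raise ValueError("discount rate must be non-negative")
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    return (1.0 + rate) ** (-(cycle_index - 1))


def half_cycle_value(value_at_start: float, value_at_end: float) -> float:
    """Mid-cycle occupancy estimate: the mean of the two cycle boundaries."""
    return 0.5 * (value_at_start + value_at_end)


def trastuzumab_acquisition_cost(inputs) -> float:
    """One year of trastuzumab: drug, administration and HER2 testing.

    ``administrations × (vials_per_cycle × vial_price + admin_price)
    + her2_testing``, charged to the treated arm in cycle 1.
    """
    return (inputs.n_administrations
            * (inputs.vials_per_cycle * inputs.vial_price + inputs.admin_price)
            + inputs.her2_testing)


@dataclass
class EconomicOutcome:
    """Discounted totals of one cohort run.

    ``costs`` decomposes total cost into the reporting categories
    (trastuzumab treatment, cardiac event/monitoring, and the three live
    health states); ``total_cost`` is their exact sum.  ``cardiac_qaly_loss``
    is the (positive) QALY decrement from first-year cardiac events, already
    subtracted from ``qaly``.
    """

    costs: dict = field(default_factory=dict)
    ly: float = 0.0
    qaly: float = 0.0
    cardiac_qaly_loss: float = 0.0

    @property
    def total_cost(self) -> float:
        return sum(self.costs.values())


_STATE_KEY = {HealthState.DFS: "dfs", HealthState.LR: "lr", HealthState.DM: "dm"}


def accumulate(trace: CohortTrace, params: ModelParameters) -> EconomicOutcome:
    """Integrate a cohort trace into discounted costs, LYs and QALYs.

    Cardiac handling: the monitoring cost applies once, in cycle 1, to the
    whole treated arm (it is surveillance, not event treatment; switchable
    via ``monitoring_whole_arm``), while the cardiac disutility applies for
    one cycle to the fraction actually experiencing an event — in either arm.
    The trastuzumab acquisition cost is charged to the treated arm in
    cycle 1, undiscounted.
    """
    out = EconomicOutcome(costs={c: 0.0 for c in COST_CATEGORIES})
    occ = trace.occupancy
    inflow = {HealthState.LR: trace.new_lr, HealthState.DM: trace.new_dm}

    for t in range(1, occ.shape[0]):
        df_c = discount_factor(params.discount_costs, t)
        df_e = discount_factor(params.discount_effects, t)
        for state in (HealthState.DFS, HealthState.LR, HealthState.DM):
            pt = half_cycle_value(occ[t - 1, state], occ[t, state])
            if pt <= 0.0:
                continue
            if state is HealthState.DFS:
                first_pt = pt if t == 1 else 0.0
            else:
                # entrants arrive mid-cycle on average: half a cycle of
                # first-year-rated time each, never more than total time
                first_pt = min(pt, 0.5 * inflow[state][t])
            subs_pt = pt - first_pt
            key = _STATE_KEY[state]
            try:
                cost = (first_pt * params.state_costs[state][Period.FIRST_YEAR]
                        + subs_pt * params.state_costs[state][Period.SUBSEQUENT])
                util = (first_pt * params.utilities[state][Period.FIRST_YEAR]
                        + subs_pt * params.utilities[state][Period.SUBSEQUENT])
            except KeyError as exc:
                raise ConfigurationError(
                    f"missing cost/utility for occupied state {key}") from exc
            out.costs[key] += df_c * cost
            out.ly += df_e * pt
            out.qaly += df_e * util

    # first-year cardiac monitoring and disutility
    if params.arm == "trastuzumab":
        if params.monitoring_whole_arm:
            monitored = 1.0
        else:
            monitored = trace.cardiac_fraction
        out.costs["cardiac"] += monitored * params.cardiac_monitoring_cost
        out.costs["trastuzumab_treatment"] += trastuzumab_acquisition_cost(
            params.trastuzumab_costs)
    loss = trace.cardiac_fraction * params.cardiac_disutility
    out.cardiac_qaly_loss = loss
    out.qaly -= loss
    return out
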