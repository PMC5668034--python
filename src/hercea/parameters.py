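"""Model inputs for the adjuvant-trastuzumab Markov model.

This module holds everything the cohort engine consumes: annual transition
probabilities (with the first-year / subsequent-year split used throughout),
hazard-ratio handling under an exponential survival assumption, background
mortality from an all-cause female life table, parameter-uncertainty
distributions (fixed / Beta / Gamma from mean and standard error), and the
assembly of a complete per-arm parameter set for each scenario.

Conventions
-----------
* All probabilities are per one-year model cycle and dimensionless.
* Treatment effects are hazard ratios applied on the rate scale,
  ``p -> 1 - (1 - p)**hr``, exact under exponential survival within a cycle.
* Monetary inputs are 2012 euros.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "HealthState",
    "Period",
    "PeriodProb",
    "TransitionInputs",
    "LifeTable",
    "ParameterDistribution",
    "TrastuzumabCostInputs",
    "ModelParameters",
    "rate_from_annual_probability",
    "probability_from_rate",
    "apply_hazard_ratio",
    "derive_lr_probability",
    "background_mortality",
    "build_scenario_parameters",
]

SCENARIOS = ("real_world", "guideline", "trial")
ARMS = ("trastuzumab", "control")

#: age at which the cohort simulation is always stopped
MAX_ATTAINED_AGE = 110


class HealthState(enum.IntEnum):
    """The four mutually exclusive health states of the cohort model.

    ``LR`` bundles locoregional recurrence, contralateral recurrence and a
    new primary tumor.  ``DEAD`` is absorbing and covers both cancer and
    other-cause death.
    """

    DFS = 0
    LR = 1
    DM = 2
    DEAD = 3


LIVE_STATES = (HealthState.DFS, HealthState.LR, HealthState.DM)


class Period(str, enum.Enum):
    """Time stratum for probabilities, costs and utilities."""

    FIRST_YEAR = "first_year"
    SUBSEQUENT = "subsequent"


def period_for_cycle(cycle_index: int) -> Period:
    """Map a 1-based model cycle to its probability stratum."""
    return Period.FIRST_YEAR if cycle_index == 1 else Period.SUBSEQUENT


# ---------------------------------------------------------------------------
# rate <-> probability conversions (exponential survival within a cycle)
# ---------------------------------------------------------------------------

def rate_from_annual_probability(p: float) -> float:
    """Convert an annual event probability to a constant hazard rate.

    Under exponential survival the probability of an event within one year
    at constant hazard ``r`` is ``1 - exp(-r)``; this is the inverse map
    ``r = -ln(1 - p)``.

    Parameters
    ----------
    p : float
        Annual probability, ``0 <= p < 1``.

    Returns
    -------
    float
        Hazard rate per year.

    Raises
    ------
    ValueError
        If ``p`` equals 1 (non-finite hazard) or lies outside ``[0, 1)``.
    """
    if not 0.0 <= p < 1.0:
        if p == 1.0:
            raise ValueError("annual probability 1 implies a non-finite hazard rate")
        raise ValueError(f"annual probability must lie in [0, 1), got {p!r}")
    return -math.log1p(-p)


def probability_from_rate(rate: float) -> float:
    """Annual event probability at constant hazard ``rate`` (per year)."""
    if rate < 0.0:
        raise ValueError(f"hazard rate must be non-negative, got {rate!r}")
    return -math.expm1(-rate)


def apply_hazard_ratio(p: float, hr: float, cycle_index: int,
                       benefit_duration: int) -> float:
    """Apply a hazard ratio to an annual probability, within a bounded window.

    The treatment effect is assumed to last ``benefit_duration`` years; for
    cycles inside the window the probability is transformed on the rate
    scale, ``1 - (1 - p)**hr``, afterwards the hazard ratio reverts to 1 and
    the probability is returned unchanged.

    Parameters
    ----------
    p : float
        Annual probability in ``[0, 1)``.
    hr : float
        Hazard ratio, strictly positive.
    cycle_index : int
        1-based model cycle.
    benefit_duration : int
        Number of cycles during which the hazard ratio applies.
    """
    if hr <= 0.0:
        raise ValueError(f"hazard ratio must be > 0, got {hr!r}")
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    if not 0.0 <= p < 1.0:
        raise ValueError(f"annual probability must lie in [0, 1), got {p!r}")
    if cycle_index > benefit_duration:
        return p
    return 1.0 - (1.0 - p) ** hr


def derive_lr_probability(p_dfs_event: float, p_dm_event: float) -> float:
    """Annual probability of local (incl. contralateral/new-primary) recurrence.

    The cohort data parameterize the composite disease-free-survival event
    (any recurrence or death) and the distant-metastasis-free event
    (distant recurrence or death); the local-recurrence probability is their
    difference, floored at zero.  A trial-style parameter set in which the
    DFS event probability does not exceed the DM event probability therefore
    yields no local recurrences at all.
    """
    for name, p in (("p_dfs_event", p_dfs_event), ("p_dm_event", p_dm_event)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    return max(0.0, p_dfs_event - p_dm_event)


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """All-cause annual death probabilities by single year of age.

    Ages must be contiguous integers; attained ages beyond the final row are
    clamped to the last probability, so a table that ends in ``q = 1`` (or
    near it) guarantees a finite lifetime horizon.
    """

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        if ages.size == 0:
            raise ConfigurationError("life table is empty")
        if ages.size != q.size:
            raise ConfigurationError("life table age/probability length mismatch")
        if not np.all(np.diff(ages) == 1):
            raise ConfigurationError("life table ages must be contiguous")
        if np.any((q < 0.0) | (q > 1.0)):
            raise ConfigurationError("life table probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)

    def q_at(self, age: float) -> float:
        """Annual death probability at (integer part of) ``age``, clamped."""
        idx = int(age) - int(self.ages[0])
        idx = min(max(idx, 0), self.ages.size - 1)
        return float(self.q[idx])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        """Read a two-column delimited file with columns ``age`` and ``qx``."""
        df = pd.read_csv(path, comment="#")
        cols = {c.lower().strip(): c for c in df.columns}
        age_col = cols.get("age")
        q_col = cols.get("qx") or cols.get("q")
        if age_col is None or q_col is None:
            raise ConfigurationError(
                f"life table {path} must have columns 'age' and 'qx' (or 'q')")
        return cls(df[age_col].to_numpy(), df[q_col].to_numpy())


def background_mortality(life_table: LifeTable, start_age: float,
                         cycle_index: int) -> float:
    """Other-cause death probability for the cycle at the attained age.

    The attained age during cycle ``t`` (1-based) is ``start_age + t - 1``;
    ages past the end of the table use the final row.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    return life_table.q_at(start_age + cycle_index - 1)


# ---------------------------------------------------------------------------
# parameter uncertainty distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterDistribution:
    """A ``(mean, se, family)`` triple supporting fixed/Beta/Gamma sampling.

    Beta and Gamma shapes are obtained from the mean and standard error by
    the method of moments.  A zero or missing standard error degenerates to
    a fixed parameter.  A Beta standard error incompatible with the mean
    (``se**2 >= mean*(1-mean)``) is truncated to ``0.999*sqrt(mean*(1-mean))``
    with a warning, since some reported uncertainties exceed what a Beta
    distribution at that mean can carry.
    """

    mean: float
    se: float = 0.0
    family: str = "fixed"

    def __post_init__(self) -> None:
        if self.family not in ("fixed", "beta", "gamma"):
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if self.se < 0.0:
            raise ConfigurationError("standard error must be non-negative")
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            if self.se > 0.0:
                raise ConfigurationError(
                    f"Beta mean must lie in (0, 1), got {self.mean!r}")
        if self.family == "gamma" and self.mean <= 0.0 and self.se > 0.0:
            raise ConfigurationError(f"Gamma mean must be > 0, got {self.mean!r}")

    @property
    def is_stochastic(self) -> bool:
        return self.family != "fixed" and self.se > 0.0

    def beta_shapes(self) -> tuple[float, float]:
        m = self.mean
        vmax = m * (1.0 - m)
        se = self.se
        if se * se >= vmax:
            se = 0.999 * math.sqrt(vmax)
            warnings.warn(
                f"Beta SE {self.se:g} incompatible with mean {m:g}; "
                f"truncated to {se:g}", stacklevel=2)
        k = vmax / (se * se) - 1.0
        if k <= 0.0:
            raise ConfigurationError(
                f"infeasible Beta moments (mean={m!r}, se={self.se!r})")
        return m * k, (1.0 - m) * k

    def gamma_shapes(self) -> tuple[float, float]:
        shape = (self.mean / self.se) ** 2
        scale = self.se ** 2 / self.mean
        return shape, scale

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value; fixed (or zero-SE) parameters return the mean."""
        if not self.is_stochastic:
            return self.mean
        if self.family == "beta":
            a, b = self.beta_shapes()
            return float(rng.beta(a, b))
        shape, scale = self.gamma_shapes()
        return float(rng.gamma(shape, scale))

    @classmethod
    def from_spec(cls, spec: Mapping | float | int) -> "ParameterDistribution":
        """Build from a config node: a bare number or a mean/se/family map."""
        if isinstance(spec, (int, float)):
            return cls(mean=float(spec))
        mean = float(spec["mean"])
        se = float(spec.get("se", 0.0) or 0.0)
        family = str(spec.get("family", "fixed" if se == 0.0 else "fixed"))
        return cls(mean=mean, se=se, family=family)


# ---------------------------------------------------------------------------
# transition inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodProb:
    """An annual probability split into first-year and subsequent-year values."""

    first_year: float
    subsequent: float

    def __post_init__(self) -> None:
        for p in (self.first_year, self.subsequent):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"annual probability must lie in [0, 1], got {p!r}")

    def for_cycle(self, cycle_index: int) -> float:
        return self.first_year if cycle_index == 1 else self.subsequent


@dataclass(frozen=True)
class TransitionInputs:
    """Arm-resolved transition inputs for the cohort engine.

    ``p_death_overall``, ``p_dfs_event`` and ``p_dm_event`` are the arm's
    composite annual probabilities (1 − OS, 1 − DFS, 1 − DM-free survival).
    ``hr_os``/``hr_dfs``/``hr_dm`` are *effective* per-arm hazard multipliers
    applied for cycles up to ``benefit_duration``: they are 1 for the arm
    whose survival was observed directly and ``1 / HR_trial`` for a control
    arm derived from the treated arm's curves (a trial hazard ratio below 1
    for treatment-vs-control inflates the control hazard).
    ``hr_dm_after_lr`` multiplies the distant-metastasis hazard for patients
    in the local-recurrence state, every cycle.
    """

    p_death_overall: PeriodProb
    p_dfs_event: PeriodProb
    p_dm_event: PeriodProb
    p_cardiac_first_year: float
    hr_os: float = 1.0
    hr_dfs: float = 1.0
    hr_dm: float = 1.0
    benefit_duration: int = 8
    hr_dm_after_lr: float = 1.0

    def __post_init__(self) -> None:
        for name, hr in (("hr_os", self.hr_os), ("hr_dfs", self.hr_dfs),
                         ("hr_dm", self.hr_dm),
                         ("hr_dm_after_lr", self.hr_dm_after_lr)):
            if hr <= 0.0:
                raise ValueError(f"{name} must be > 0, got {hr!r}")
        if not 0.0 <= self.p_cardiac_first_year <= 1.0:
            raise ValueError("cardiac probability must lie in [0, 1]")
        if self.benefit_duration < 0:
            raise ValueError("benefit_duration must be >= 0")

    def death_probability(self, cycle_index: int) -> float:
        return apply_hazard_ratio(self.p_death_overall.for_cycle(cycle_index),
                                  self.hr_os, cycle_index, self.benefit_duration)

    def dfs_event_probability(self, cycle_index: int) -> float:
        return apply_hazard_ratio(self.p_dfs_event.for_cycle(cycle_index),
                                  self.hr_dfs, cycle_index, self.benefit_duration)

    def dm_event_probability(self, cycle_index: int) -> float:
        return apply_hazard_ratio(self.p_dm_event.for_cycle(cycle_index),
                                  self.hr_dm, cycle_index, self.benefit_duration)


@dataclass(frozen=True)
class TrastuzumabCostInputs:
    """Acquisition-cost components of one year of trastuzumab."""

    vials_per_cycle: float = 0.0
    n_administrations: float = 0.0
    vial_price: float = 0.0
    admin_price: float = 0.0
    cardiac_monitoring: float = 0.0
    her2_testing: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.vials_per_cycle, self.n_administrations, self.vial_price,
                  self.admin_price, self.cardiac_monitoring, self.her2_testing):
            if f < 0.0:
                raise ValueError("cost inputs must be non-negative")


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set for one scenario arm.

    ``state_costs`` and ``utilities`` map each live health state to its
    first-year and subsequent-year annual value (costs in euros, utilities in
    ``[0, 1]``); first-year rates are applied relative to entry into the
    state.  ``fixed_dm_mortality``, when set, replaces the derived
    distant-metastasis death probability with a constant.
    """

    arm: str
    scenario: str
    transitions: TransitionInputs
    state_costs: Mapping[HealthState, Mapping[Period, float]]
    utilities: Mapping[HealthState, Mapping[Period, float]]
    cardiac_monitoring_cost: float
    cardiac_disutility: float
    trastuzumab_costs: TrastuzumabCostInputs
    discount_costs: float = 0.04
    discount_effects: float = 0.015
    start_age: float = 55.0
    life_table: LifeTable | None = None
    horizon: int | None = None          # None = lifetime (age cap)
    fixed_dm_mortality: float | None = None
    monitoring_whole_arm: bool = True
    wtp: float = 80_000.0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ConfigurationError(f"unknown arm {self.arm!r}")
        if self.discount_costs < 0.0 or self.discount_effects < 0.0:
            raise ConfigurationError("discount rates must be non-negative")
        for state in LIVE_STATES:
            for period in Period:
                c = self.state_costs[state][period]
                u = self.utilities[state][period]
                if c < 0.0:
                    raise ConfigurationError(f"negative cost for {state.name}")
                if not 0.0 <= u <= 1.0:
                    raise ConfigurationError(
                        f"utility for {state.name}/{period.value} outside [0, 1]")
        if not 0.0 <= self.cardiac_disutility <= 1.0:
            raise ConfigurationError("cardiac disutility must lie in [0, 1]")
        if self.life_table is None:
            raise ConfigurationError("a life table is required")


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def _period_prob(config, prefix: str, draw) -> PeriodProb:
    return PeriodProb(
        first_year=min(1.0, max(0.0, config.value(f"{prefix}.first_year", draw))),
        subsequent=min(1.0, max(0.0, config.value(f"{prefix}.subsequent", draw))),
    )


def _divided_hazard(p: float, hr: float) -> float:
    """Control-arm probability from a treated-arm probability and a trial HR."""
    if p >= 1.0:
        return 1.0
    return min(1.0, max(0.0, 1.0 - (1.0 - p) ** (1.0 / hr)))


def build_scenario_parameters(scenario: str, arm: str, config=None,
                              draw: Mapping[str, float] | None = None,
                              ) -> ModelParameters:
    """Assemble the full per-arm parameter set for a scenario.

    For the real-world and guideline scenarios the configured transition
    probabilities are those observed in the trastuzumab-treated cohort; the
    control arm is derived by dividing the treated arm's hazards by the trial
    hazard ratios (within the benefit window).  A trial-style configuration
    instead provides each arm's probabilities directly under per-arm keys.
    In every scenario the control arm's first-year cardiac-event probability
    defaults to the treated arm's probability divided by the relative risk.

    Parameters
    ----------
    scenario : {'real_world', 'guideline', 'trial'}
    arm : {'trastuzumab', 'control'}
    config : ScenarioConfig, optional
        Loaded configuration; defaults to the bundled file for ``scenario``.
    draw : mapping, optional
        Parameter values sampled for one probabilistic iteration, keyed by
        dotted config path; missing paths fall back to the mean.
    """
    from .config import ScenarioConfig  # local import to avoid a cycle

    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    if arm not in ARMS:
        raise ConfigurationError(f"unknown arm {arm!r}")
    if config is None:
        config = ScenarioConfig.load(scenario)

    raw = config.raw
    per_arm = isinstance(raw.get("transitions", {}).get("trastuzumab"), dict)

    benefit_duration = int(raw.get("benefit_duration", 8))
    hr_dm_after_lr = config.value("hazard_ratios.dm_after_lr", draw, default=None)
    if hr_dm_after_lr is None:
        logger.info("hazard_ratios.dm_after_lr not configured; defaulting to 1 "
                    "(local recurrence confers no extra distant-metastasis risk)")
        hr_dm_after_lr = 1.0

    def trial_hr(name: str) -> float:
        v = config.value(f"hazard_ratios.{name}", draw, default=None)
        if v is None:
            raise ConfigurationError(
                f"hazard_ratios.{name} is required to derive the control arm")
        return v

    if per_arm:
        base = f"transitions.{arm}"
        p_death = _period_prob(config, f"{base}.death_overall", draw)
        p_dfs = _period_prob(config, f"{base}.dfs_event", draw)
        p_dm = _period_prob(config, f"{base}.dm_event", draw)
        eff = dict(hr_os=1.0, hr_dfs=1.0, hr_dm=1.0)
        p_cardiac = config.value(f"{base}.cardiac_first_year", draw, default=None)
        if p_cardiac is None:
            p_ct = config.value("transitions.trastuzumab.cardiac_first_year", draw)
            p_cardiac = p_ct if arm == "trastuzumab" else \
                min(1.0, max(0.0, p_ct / trial_hr("cardiac_rr")))
    else:
        p_death = _period_prob(config, "transitions.death_overall", draw)
        p_dfs = _period_prob(config, "transitions.dfs_event", draw)
        p_dm = _period_prob(config, "transitions.dm_event", draw)
        if arm == "trastuzumab":
            eff = dict(hr_os=1.0, hr_dfs=1.0, hr_dm=1.0)
        else:
            eff = dict(hr_os=1.0 / trial_hr("os"),
                       hr_dfs=1.0 / trial_hr("dfs"),
                       hr_dm=1.0 / trial_hr("dm"))
        p_ct = config.value("transitions.cardiac_first_year", draw)
        p_cardiac = p_ct if arm == "trastuzumab" else \
            min(1.0, max(0.0, p_ct / trial_hr("cardiac_rr")))

    transitions = TransitionInputs(
        p_death_overall=p_death, p_dfs_event=p_dfs, p_dm_event=p_dm,
        p_cardiac_first_year=float(p_cardiac),
        benefit_duration=benefit_duration, hr_dm_after_lr=float(hr_dm_after_lr),
        **eff)

    state_key = {"dfs": HealthState.DFS, "lr": HealthState.LR, "dm": HealthState.DM}
    state_costs: dict[HealthState, dict[Period, float]] = {}
    utilities: dict[HealthState, dict[Period, float]] = {}
    control_costs = raw.get("state_costs_control") if arm == "control" else None
    for key, state in state_key.items():
        state_costs[state] = {}
        utilities[state] = {}
        for period in Period:
            prefix = "state_costs"
            if control_costs is not None and key in control_costs:
                prefix = "state_costs_control"
            state_costs[state][period] = config.value(
                f"{prefix}.{key}.{period.value}", draw)
            utilities[state][period] = min(1.0, max(0.0, config.value(
                f"utilities.{key}.{period.value}", draw)))

    her2_testing = config.value("trastuzumab.her2_testing", draw, default=None)
    if her2_testing is None:
        logger.info("trastuzumab.her2_testing not configured; defaulting to 0")
        her2_testing = 0.0
    monitoring = config.value("cardiac_monitoring_cost", draw)
    if arm == "trastuzumab":
        tz = TrastuzumabCostInputs(
            vials_per_cycle=config.value("trastuzumab.vials_per_cycle", draw),
            n_administrations=config.value("trastuzumab.n_administrations", draw),
            vial_price=config.value("trastuzumab.vial_price", draw),
            admin_price=config.value("trastuzumab.admin_price", draw),
            cardiac_monitoring=monitoring,
            her2_testing=float(her2_testing),
        )
    else:
        tz = TrastuzumabCostInputs(cardiac_monitoring=monitoring)

    fixed_dm = raw.get("fixed_dm_mortality")
    return ModelParameters(
        arm=arm,
        scenario=scenario,
        transitions=transitions,
        state_costs=state_costs,
        utilities=utilities,
        cardiac_monitoring_cost=monitoring,
        cardiac_disutility=config.value("cardiac_disutility", draw),
        trastuzumab_costs=tz,
        discount_costs=float(raw.get("discount_costs", 0.04)),
        discount_effects=float(raw.get("discount_effects", 0.015)),
        start_age=float(raw.get("start_age", 55)),
        life_table=config.life_table,
        horizon=raw.get("horizon"),
        fixed_dm_mortality=None if fixed_dm is None else float(fixed_dm),
        monitoring_whole_arm=bool(raw.get("monitoring_whole_arm", True)),
        wtp=float(raw.get("wtp", 80_000.0)),
    )
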