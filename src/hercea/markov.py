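"""Annual-cycle cohort simulation.

The engine advances a closed cohort through the four health states — disease
free (DFS), local recurrence (LR), distant metastases (DM) and death — one
year at a time, starting with the whole cohort disease free.  Exits that
compete within a cycle are resolved on the rate scale: each annual exit
probability is converted to a hazard, hazards are summed, and the combined
exit probability ``1 - exp(-R)`` is allocated proportionally to the
individual hazards, which guarantees the total exit never exceeds 1.

Death is fed from two sources: other-cause (background) mortality acting on
the DFS and LR states at the attained age, and cancer mortality.  The model
is parameterized by the overall-survival curve rather than a distant-
metastasis case-fatality rate, so the per-cycle DM death probability is
derived as the excess of the overall death flow over the expected background
flow, attributed entirely to DM occupants (and capped at 1).  A fixed DM
death probability can be supplied instead via configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NumericalError
from .parameters import (
    MAX_ATTAINED_AGE,
    HealthState,
    ModelParameters,
    background_mortality,
    derive_lr_probability,
)

__all__ = ["CohortTrace", "transition_step", "run_cohort"]

_DFS, _LR, _DM, _DEAD = (int(s) for s in HealthState)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and incident flows of one cohort run.

    ``occupancy[t]`` is the distribution over the four states at the end of
    cycle ``t`` (``occupancy[0]`` is the initial distribution); rows are
    non-negative and sum to one.  ``new_lr[t]`` / ``new_dm[t]`` are the
    fractions entering the local-recurrence / distant-metastasis states
    during cycle ``t`` (index 0 unused).  ``cardiac_fraction`` is the
    fraction of the cohort with a severe cardiac event in the first year.
    """

    occupancy: np.ndarray
    new_lr: np.ndarray
    new_dm: np.ndarray
    cardiac_fraction: float
    start_age: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Delimited-table view (cycle, occupancy by state, incident flows)."""
        t = np.arange(self.occupancy.shape[0])
        return pd.DataFrame({
            "cycle": t,
            "dfs": self.occupancy[:, _DFS],
            "lr": self.occupancy[:, _LR],
            "dm": self.occupancy[:, _DM],
            "dead": self.occupancy[:, _DEAD],
            "new_lr": self.new_lr,
            "new_dm": self.new_dm,
        })


def _rate(p: float) -> float:
    # internal clipped conversion: engine-side probabilities may hit 1 (e.g.
    # the life-table tail), which must swamp competing exits, not crash
    return -math.log1p(-min(p, 1.0 - 1e-12))


def _competing(probs: list[float]) -> list[float]:
    """Allocate a combined exit probability across competing risks.

    Converts each annual probability to a hazard, sums, and splits the joint
    exit probability ``1 - exp(-R)`` proportionally to the hazards.
    """
    rates = [_rate(p) for p in probs]
    total_rate = sum(rates)
    if total_rate <= 0.0:
        return [0.0] * len(probs)
    total_exit = -math.expm1(-total_rate)
    return [total_exit * r / total_rate for r in rates]


def _step(occupancy, params: ModelParameters, cycle_index: int):
    """One annual transition; returns (new_occupancy, new_lr, new_dm)."""
    dfs, lr, dm, dead = occupancy
    tr = params.transitions
    q_bg = background_mortality(params.life_table, params.start_age, cycle_index)

    p_dfs_ev = tr.dfs_event_probability(cycle_index)
    p_dm_ev = tr.dm_event_probability(cycle_index)
    p_lr = derive_lr_probability(p_dfs_ev, p_dm_ev)

    # DFS exits: distant metastases, local recurrence, other-cause death
    dfs_to_dm, dfs_to_lr, dfs_to_dead = (f * dfs for f in
                                         _competing([p_dm_ev, p_lr, q_bg]))
    # LR exits: distant metastases (extra hazard multiplier), other-cause death
    p_lr_dm = 1.0 - (1.0 - min(p_dm_ev, 1.0 - 1e-12)) ** tr.hr_dm_after_lr
    lr_to_dm, lr_to_dead = (f * lr for f in _competing([p_lr_dm, q_bg]))

    # DM deaths: fixed case fatality if configured, else derived so the
    # cohort-level death flow tracks the overall-survival input.  Everyone
    # faces background mortality; the excess of the overall death target
    # over the expected background flow is cancer mortality, attributed to
    # DM occupants on top of their background risk.
    if params.fixed_dm_mortality is not None:
        p_dm_death = params.fixed_dm_mortality
    else:
        alive = dfs + lr + dm
        target_deaths = tr.death_probability(cycle_index) * alive
        bg_deaths = dfs_to_dead + lr_to_dead + dm * q_bg
        cancer_deaths = max(0.0, target_deaths - bg_deaths)
        p_cancer = min(1.0, cancer_deaths / dm) if dm > 1e-15 else 0.0
        p_dm_death = 1.0 - (1.0 - q_bg) * (1.0 - p_cancer)
    dm_to_dead = dm * p_dm_death

    new = [
        dfs - dfs_to_dm - dfs_to_lr - dfs_to_dead,
        lr + dfs_to_lr - lr_to_dm - lr_to_dead,
        dm + dfs_to_dm + lr_to_dm - dm_to_dead,
        dead + dfs_to_dead + lr_to_dead + dm_to_dead,
    ]
    if min(new) < -1e-12:
        raise NumericalError(
            f"negative occupancy at cycle {cycle_index}: {new}")
    total = sum(new)
    if abs(total - sum(occupancy)) > 1e-9:
        raise NumericalError(
            f"probability mass not conserved at cycle {cycle_index}: "
            f"sum={total!r}")
    new = [max(0.0, x) for x in new]
    return new, dfs_to_lr, dfs_to_dm + lr_to_dm


def transition_step(occupancy, params: ModelParameters,
                    cycle_index: int) -> np.ndarray:
    """Advance a valid occupancy vector by one cycle.

    Parameters
    ----------
    occupancy : array-like of 4 floats
        State distribution (DFS, LR, DM, DEAD), non-negative, summing to 1.
    params : ModelParameters
    cycle_index : int
        1-based cycle number (determines the probability stratum, the
        hazard-ratio window and the attained age).
    """
    occ = [float(x) for x in np.asarray(occupancy, dtype=float)]
    if min(occ) < 0.0 or abs(sum(occ) - 1.0) > 1e-9:
        raise ValueError("occupancy must be non-negative and sum to 1")
    new, _, _ = _step(occ, params, cycle_index)
    return np.asarray(new)


def run_cohort(params: ModelParameters) -> CohortTrace:
    """Run the cohort from 100% disease free until (almost) everyone has died.

    The simulation stops when the dead fraction reaches ``1 - 1e-6`` or the
    attained age reaches 110, whichever comes first; an explicit
    ``params.horizon`` (in years) overrides the age cap.  The first-year
    cardiac-event fraction is recorded alongside the trace; cardiac events do
    not change state membership.
    """
    if params.horizon is not None:
        max_cycles = int(params.horizon)
        stop_dead = 1.0 - 1e-15
    else:
        max_cycles = max(1, int(MAX_ATTAINED_AGE - params.start_age) + 1)
        stop_dead = 1.0 - 1e-6

    occ = [1.0, 0.0, 0.0, 0.0]
    occupancy = [occ]
    new_lr = [0.0]
    new_dm = [0.0]
    for cycle in range(1, max_cycles + 1):
        occ, inc_lr, inc_dm = _step(occ, params, cycle)
        occupancy.append(occ)
        new_lr.append(inc_lr)
        new_dm.append(inc_dm)
        if occ[_DEAD] >= stop_dead:
            break
    else:
        if params.horizon is None and occ[_DEAD] < stop_dead:
            warnings.warn(
                "cohort did not die out before the age-110 cap; "
                "trace truncated", stacklevel=2)

    return CohortTrace(
        occupancy=np.asarray(occupancy),
        new_lr=np.asarray(new_lr),
        new_dm=np.asarray(new_dm),
        cardiac_fraction=params.transitions.p_cardiac_first_year,
        start_age=params.start_age,
    )
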