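"""Synthetic patient-level cohort generation and input estimation.

The decision model's inputs come from a real-world cohort: exponential
survival fits of the composite endpoints (overall survival, disease-free
survival, distant-metastasis-free survival) stratified into the first year
after diagnosis versus subsequent years, first-year cardiac events, and
per-health-state annual costs.  This module emulates exactly that data
structure — piecewise-exponential event times with independent right
censoring, Bernoulli first-year cardiac events, Gamma-skewed annual cost
records — so the estimation path (patient records → rates → annual
probabilities → model inputs) can be tested end to end by parameter
recovery.  It is a generator of data with the assumed statistical
structure, not a reproduction of any real cohort.

Endpoint semantics mirror the composite definitions: the disease-free
survival event is the earliest of local recurrence, distant metastasis or
death; the distant-metastasis-free event is the earlier of distant
metastasis or death.  Event times therefore always satisfy
``t_dfs_event <= t_dm <= t_death``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .errors import ConfigurationError
from .parameters import PeriodProb, probability_from_rate, rate_from_annual_probability

__all__ = ["CohortTruth", "EstimatedInputs", "default_truth",
           "generate_cohort", "estimate_inputs", "estimates_as_overrides"]

ENDPOINTS = ("dfs_event", "dm_event", "death_overall")
_TIME_COL = {"dfs_event": "time_to_dfs_event", "dm_event": "time_to_dm",
             "death_overall": "time_to_death"}

#: administrative censoring window in years (accrual over ~3 years with a
#: fixed follow-up cut-off), approximated as uniform
DEFAULT_CENSOR_WINDOW = (3.8, 6.8)


@dataclass(frozen=True)
class CohortTruth:
    """True composite annual event probabilities generating a cohort.

    ``p_os``/``p_dfs``/``p_dm`` are 1−OS, 1−DFS and 1−(DM-free survival)
    per year, each split into first-year and subsequent-year values.
    """

    p_os: PeriodProb
    p_dfs: PeriodProb
    p_dm: PeriodProb
    p_cardiac_year1: float = 0.0


def default_truth(config: ScenarioConfig | None = None) -> CohortTruth:
    """Truth anchored at the real-world treated-arm transition table."""
    if config is None:
        config = ScenarioConfig.load("real_world")
    def pp(endpoint):
        return PeriodProb(
            first_year=config.value(f"transitions.{endpoint}.first_year"),
            subsequent=config.value(f"transitions.{endpoint}.subsequent"))
    return CohortTruth(
        p_os=pp("death_overall"), p_dfs=pp("dfs_event"), p_dm=pp("dm_event"),
        p_cardiac_year1=config.value("transitions.cardiac_first_year"))


def _cause_rates(truth: CohortTruth, hr: dict | None) -> dict:
    """Cause-specific piecewise rates from the composite probabilities.

    The composite hazards nest (DFS event ⊇ DM event ⊇ death), so the
    cause-specific local-recurrence and distant-metastasis rates are hazard
    differences; a configuration in which the DFS event hazard does not
    exceed the DM event hazard simply yields no local recurrences.
    ``hr`` (treatment-vs-control hazard ratios per endpoint) divides the
    composite rates, producing the control arm's curves.
    """
    rates = {}
    for period in ("first_year", "subsequent"):
        r_os = rate_from_annual_probability(getattr(truth.p_os, period))
        r_dmf = rate_from_annual_probability(getattr(truth.p_dm, period))
        r_dfs = rate_from_annual_probability(getattr(truth.p_dfs, period))
        if hr:
            r_os /= hr.get("os", 1.0)
            r_dmf /= hr.get("dm", 1.0)
            r_dfs /= hr.get("dfs", 1.0)
        rates[period] = {
            "death": r_os,
            "dm": max(0.0, r_dmf - r_os),
            "lr": max(0.0, r_dfs - r_dmf),
        }
    return rates


def _piecewise_exponential(rng, n, r_first, r_subsequent, split=1.0):
    """Draw event times with rate ``r_first`` before ``split`` and
    ``r_subsequent`` after; a zero rate means no events in that segment."""
    h = rng.exponential(1.0, size=n)  # cumulative-hazard targets
    t = np.full(n, np.inf)
    h_split = r_first * split
    early = h <= h_split
    if r_first > 0.0:
        t[early] = h[early] / r_first
    else:
        early[:] = False
    late = ~early
    if r_subsequent > 0.0:
        t[late] = split + (h[late] - h_split) / r_subsequent
    return t


def generate_cohort(truth: CohortTruth, n: int,
                    censor_window: tuple[float, float] = DEFAULT_CENSOR_WINDOW,
                    cost_model: dict | None = None,
                    seed: int = 0,
                    arm: str = "trastuzumab",
                    hr: dict | None = None) -> pd.DataFrame:
    """Generate a patient-level table with the assumed data structure.

    Parameters
    ----------
    truth : CohortTruth
        Composite annual event probabilities of the treated arm.
    n : int
        Number of patients.
    censor_window : (float, float)
        Uniform administrative-censoring window in years.
    cost_model : dict, optional
        ``{"<state>_<period>": (mean, patient_sd)}`` Gamma annual-cost
        draws recorded per patient (e.g. ``{"dfs_first_year": (12776,
        12776)}``); omitted keys produce no cost columns.
    seed : int
        Reproducibility seed; identical seeds give identical cohorts.
    arm : {'trastuzumab', 'control'}
    hr : dict, optional
        Endpoint hazard ratios (treatment vs control); required when
        ``arm='control'`` — the control arm's rates are the treated arm's
        divided by these.

    Returns
    -------
    pandas.DataFrame
        Columns ``id, arm, time_to_dfs_event, time_to_dm, time_to_death,
        censor_time, cardiac_event_year1`` plus one ``cost_<key>`` column
        per cost-model entry.  Event times are uncensored latent times; the
        estimator applies the censoring.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if arm == "control" and not hr:
        raise ConfigurationError("control-arm generation requires hazard ratios")
    rng = np.random.default_rng(seed)
    rates = _cause_rates(truth, hr if arm == "control" else None)

    t_death = _piecewise_exponential(
        rng, n, rates["first_year"]["death"], rates["subsequent"]["death"])
    t_dm_lat = _piecewise_exponential(
        rng, n, rates["first_year"]["dm"], rates["subsequent"]["dm"])
    t_lr_lat = _piecewise_exponential(
        rng, n, rates["first_year"]["lr"], rates["subsequent"]["lr"])

    t_dm = np.minimum(t_dm_lat, t_death)
    t_dfs = np.minimum(t_lr_lat, t_dm)
    censor = rng.uniform(censor_window[0], censor_window[1], size=n)

    p_cardiac = truth.p_cardiac_year1
    if arm == "control" and hr and "cardiac_rr" in hr:
        p_cardiac = min(1.0, p_cardiac / hr["cardiac_rr"])
    cardiac = rng.uniform(size=n) < p_cardiac

    df = pd.DataFrame({
        "id": np.arange(n),
        "arm": arm,
        "time_to_dfs_event": t_dfs,
        "time_to_dm": t_dm,
        "time_to_death": t_death,
        "censor_time": censor,
        "cardiac_event_year1": cardiac,
    })
    for key, (mean, sd) in (cost_model or {}).items():
        if mean <= 0.0:
            df[f"cost_{key}"] = 0.0
        else:
            shape = (mean / sd) ** 2
            df[f"cost_{key}"] = rng.gamma(shape, sd * sd / mean, size=n)
    return df


@dataclass
class EstimatedInputs:
    """Estimates recovered from a patient-level table.

    ``probabilities[endpoint][period]`` is ``(annual_probability, se)``;
    ``rates`` holds the underlying exponential rates; ``costs[key]`` is
    ``(mean, se_of_mean)``; ``missing`` lists strata with no person-time.
    """

    probabilities: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    costs: dict = field(default_factory=dict)
    p_cardiac_year1: float = math.nan
    n: int = 0
    missing: list = field(default_factory=list)


def _stratum_rate(obs_time, event, lo, hi):
    """Exponential rate (events / person-time) restricted to ``[lo, hi)``."""
    pt = np.clip(obs_time, None, hi) - lo
    pt = pt[pt > 0].sum()
    ev = int(np.sum(event & (obs_time > lo) & (obs_time <= hi)))
    if pt <= 0.0:
        return math.nan, math.nan, 0
    rate = ev / pt
    se_rate = math.sqrt(ev) / pt if ev else 0.0
    return rate, se_rate, ev


def estimate_inputs(cohort: pd.DataFrame,
                    first_period_end: float = 1.0) -> EstimatedInputs:
    """Maximum-likelihood exponential fits per endpoint and time stratum.

    Each patient's follow-up is split at ``first_period_end`` (one year);
    within each stratum the rate is events divided by person-time — the
    exponential maximum-likelihood estimator — and the annual probability is
    ``1 - exp(-rate)``.  Standard errors come from the Poisson variance of
    the event count, delta-method-transformed to the probability scale.
    Cost means and standard errors (of the mean) are computed per recorded
    cost column, and the first-year cardiac-event fraction among patients
    followed (or dying) past the relevant window is returned.

    A stratum with no person-time yields ``NaN`` and is recorded in
    ``missing``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one patient")
    est = EstimatedInputs(n=len(cohort))
    censor = cohort["censor_time"].to_numpy(float)
    split = first_period_end

    for endpoint in ENDPOINTS:
        t = cohort[_TIME_COL[endpoint]].to_numpy(float)
        obs = np.minimum(t, censor)
        event = t <= censor
        est.probabilities[endpoint] = {}
        est.rates[endpoint] = {}
        for period, (lo, hi) in (("first_year", (0.0, split)),
                                 ("subsequent", (split, np.inf))):
            rate, se_rate, _ = _stratum_rate(obs, event, lo, hi)
            if math.isnan(rate):
                est.missing.append((endpoint, period))
                p, se_p = math.nan, math.nan
            else:
                # probabilities are per stratum length (annual when split=1)
                length = min(split, hi - lo) if np.isfinite(hi) else split
                p = probability_from_rate(rate * length)
                se_p = (1.0 - p) * se_rate * length
            est.rates[endpoint][period] = (rate, se_rate)
            est.probabilities[endpoint][period] = (p, se_p)

    for col in cohort.columns:
        if col.startswith("cost_"):
            x = cohort[col].to_numpy(float)
            est.costs[col[5:]] = (float(x.mean()),
                                  float(x.std(ddof=1) / math.sqrt(x.size)))

    if "cardiac_event_year1" in cohort:
        est.p_cardiac_year1 = float(cohort["cardiac_event_year1"].mean())
    return est


def estimates_as_overrides(est: EstimatedInputs) -> dict:
    """Express recovered transition estimates as scenario-config overrides.

    This closes the loop: the returned mapping feeds
    :meth:`hercea.config.ScenarioConfig.with_overrides`, replacing the
    configured transition means (and standard errors) with the estimates.
    """
    overrides: dict = {}
    for endpoint, periods in est.probabilities.items():
        for period, (p, se) in periods.items():
            if math.isnan(p):
                continue
            base = f"transitions.{endpoint}.{period}"
            family = "beta" if 0.0 < p < 1.0 and se > 0.0 else "fixed"
            overrides[base] = {"mean": float(p), "se": float(se or 0.0),
                               "family": family}
    if not math.isnan(est.p_cardiac_year1):
        overrides["transitions.cardiac_first_year"] = {
            "mean": est.p_cardiac_year1, "se": 0.0, "family": "fixed"}
    for key, (mean, se) in est.costs.items():
        state, _, period = key.partition("_")
        overrides[f"state_costs.{state}.{period}"] = {
            "mean": mean, "se": se, "family": "gamma" if se > 0 else "fixed"}
    return overrides
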