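# hercea

A decision-analytic model of the cost-effectiveness of **one year of
adjuvant trastuzumab versus chemotherapy alone** in HER2-positive early
breast cancer, from the Dutch health-care perspective. The package is aimed
at health-economic modellers who want a scriptable, testable version of a
classic four-state Markov cohort cost-effectiveness analysis: deterministic
base case, scenario analyses (real-world / guideline / trial
parameterizations), one-way sensitivity analyses, probabilistic sensitivity
analysis (PSA) with cost-effectiveness acceptability curves (CEAC), and
expected value of perfect information (EVPI).

## The model

A closed cohort starts disease free at age 55 and moves yearly between four
states: disease free (DFS), local recurrence (LR — locoregional,
contralateral or new primary), distant metastases (DM), and dead. Survival
inputs are composite annual event probabilities (1−OS, 1−DFS, 1−DM-free
survival), split into first-year and subsequent-year values, assumed
exponential within strata:

- rate ↔ probability: `r = −ln(1 − p)`, `p = 1 − e^{−r}`;
- treatment effect: a hazard ratio *h* maps `p → 1 − (1 − p)^h` for the
  first 8 years (the benefit duration), after which *h* = 1;
- local recurrence: `p_LR = max(0, p_DFSevent − p_DMevent)`;
- background mortality: an all-cause female life table drives other-cause
  death at the attained age; cancer mortality is the excess of the overall
  death flow over background, attributed to the DM state;
- severe cardiac events occur in year 1 only and carry a one-cycle utility
  decrement of 0.128 (= 0.728 − 0.600) plus monitoring costs.

Costs (2012 euros) and utilities are per state and year-of-state
(first/subsequent), half-cycle corrected and discounted at 4.0%/year
(costs) and 1.5%/year (effects). The comparison reports incremental costs
and QALYs, the ICER ΔC/ΔE with full dominance handling, net monetary
benefit λ·ΔE − ΔC, CEACs, and per-patient plus population EVPI (eligible
population 1,743/year over 10 years, discounted at 4%).

The control arm is not observed directly in the cohort scenarios: it is
derived by dividing the treated arm's hazards by the trial hazard ratios.
Those hazard ratios — and a few further inputs — are not public at printed
precision; the bundled configuration files carry clearly marked
placeholders for them (see `docs/methods.md`).

A synthetic patient-level cohort generator (`hercea.synthetic`) emulates
the statistical structure of the underlying real-world cohort
(piecewise-exponential event times, uniform administrative censoring,
first-year cardiac events, Gamma-skewed annual costs), so the full
estimation path — patient records → exponential rates → annual
probabilities → model → CEA — is validated by parameter recovery.

## Worked example

```sh
hercea run --scenario real_world
```

```
                  category  cost_trastuzumab  cost_control
     Trastuzumab treatment            31,080             0
Cardiac event / monitoring               467             0
              Disease free            23,647        22,155
          Local recurrence            17,030         6,733
        Distant metastases           152,490       218,378
                     Total           224,715       247,266
LYs: 19.080 vs 18.327; QALYs: 13.983 vs 13.117
ICER: dominant
```

Reading: under the bundled real-world configuration the treated arm costs
€224,715 and yields 13.983 QALYs per patient (discounted, lifetime); the
chemotherapy-only arm costs more (€247,266, driven by distant-metastasis
care) and yields fewer QALYs (13.117), so trastuzumab *dominates* here —
with the placeholder hazard ratios the distant-metastasis savings outweigh
the €31,080 acquisition cost (15 administrations × (3 vials × €605 + €257)).
The same library calls are available programmatically:

```python
from hercea import ScenarioConfig, run_deterministic
outcomes, result = run_deterministic(ScenarioConfig.load("real_world"))
print(result.delta_cost, result.delta_qaly, result.label)
```

Probabilistic analysis and one-way sweeps:

```sh
hercea psa --scenario real_world --iterations 10000 --seed 1 --out out/
hercea sweep benefit_duration 4 8
hercea synth --n 5000 --seed 1 --out cohort.csv
```

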