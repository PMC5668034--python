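# Methods

## Model structure and assumptions

The model is a deterministic Markov cohort simulation with four mutually
exclusive states — disease free (DFS), local recurrence (LR), distant
metastases (DM), dead — an annual cycle, and a lifetime horizon. The whole
cohort starts in DFS at age 55. Flow is forward-only: DFS → {LR, DM, dead},
LR → {DM, dead}, DM → dead. LR bundles locoregional recurrence,
contralateral recurrence and new primary tumors and can be entered once;
there is no cure-of-LR return to DFS. Severe cardiac toxicity occurs during
the first year only and does not change state membership; it attaches a
one-cycle disutility to the affected fraction and monitoring costs to the
treated arm.

Survival inputs are composite annual probabilities (1−OS, 1−DFS,
1−DM-free survival) with a first-year / subsequent-year split, interpreted
as exponential within each stratum. Because the composite endpoints nest
(any-event ⊇ distant-event ⊇ death), the annual LR probability is the
floored difference `max(0, p_DFSevent − p_DMevent)`; a parameter set in
which the DFS event probability never exceeds the DM event probability
(the trial-style configuration) therefore produces no LR occupancy and no
LR costs.

### Treatment effect

Relative effectiveness enters as hazard ratios applied on the rate scale
(`p → 1 − (1 − p)^h`), exact under the exponential assumption, for the
first `benefit_duration` cycles (default 8 years), after which the hazard
ratio is 1. In the cohort-based scenarios the *treated* arm is observed and
the control arm is derived by **dividing** the treated hazards by the trial
hazard ratios (a treatment-vs-control HR < 1 inflates the control hazard);
the direction is explicit in the configuration, so the opposite convention
can be configured. In the trial scenario both arms' probabilities are
supplied directly. The control arm's first-year cardiac probability is the
treated arm's divided by the cardiac relative risk unless given explicitly.

### Mortality

Other-cause mortality comes from an all-cause female life table at the
attained age (clamped to the final row beyond the table's end, so the
cohort necessarily dies out). The model is parameterized by the overall
survival curve rather than a DM case-fatality rate, so the per-cycle DM
death probability is *derived*: the expected overall death flow
(`p_death(cycle) × alive`) minus the expected background flow across all
live states is cancer mortality, attributed entirely to DM occupants on top
of their own background risk (combined multiplicatively on the survival
scale, capped at 1). The background floor matters: without it DM occupants
would stop dying once age-related mortality exceeds the extrapolated
overall-survival input, which is biologically untenable for an elderly
metastatic population and would prevent the cohort from terminating. A
fixed DM death probability can be supplied instead
(`fixed_dm_mortality`), which also makes the chain time-homogeneous for
oracle comparisons.

### Competing risks

Within a cycle, competing exits from a state are resolved on the rate
scale: each annual probability is converted to a hazard, hazards are
summed, and the joint exit probability `1 − e^{−R}` is allocated
proportionally to the hazards. This keeps total exits below 1 for any
input combination (naive subtraction does not) and is consistent with the
exponential framework.

### Termination

The simulation stops when the dead fraction reaches `1 − 1e−6` or the
attained age reaches 110, whichever is first; an explicit `horizon` (used
by tests against closed-form sojourn times) overrides the age cap. A
degenerate input set that cannot terminate raises a warning and truncates.

## Economics

Costs and utilities are per state and *time since entry into the state*
(first year vs subsequent), because metastatic and recurrence care is
front-loaded. In the cohort accounting this is approximated by incident
flows: entrants arrive mid-cycle on average, so each cycle's inflow
contributes half a cycle of first-year-rated person-time, the remainder
being rated subsequent-year. DFS is entered at model start, so its
first-year rate covers cycle 1 exactly. Occupancy is half-cycle corrected
(trapezoid integration of person-time). Costs are discounted at 4.0%/year
and effects at 1.5%/year with cycle 1 undiscounted — the timing convention
is a package choice, applied identically everywhere, including the
population-EVPI multiplier.

The trastuzumab acquisition cost —
`administrations × (vials × vial price + administration price) + HER2
testing` — and the cardiac monitoring cost are charged to the treated arm
in cycle 1. Monitoring is attributed to the whole treated arm (it is
surveillance, not event treatment); the cardiac disutility applies only to
the event fraction, in both arms. Both attributions are switchable
(`monitoring_whole_arm`). HER2 testing has no public unit price and
defaults to €0.

## Parameter uncertainty

Every stochastic input is a `(mean, SE, family)` triple: Beta for
probabilities and utilities, Gamma for costs and counts, fitted by the
method of moments; SE 0 (or family `fixed`) degenerates to the mean.
A Beta SE with `se² ≥ mean(1−mean)` is infeasible at that mean and is
truncated to `0.999·sqrt(mean(1−mean))` with a warning. Hazard ratios are
fixed in the bundled configurations (no published uncertainty).

The PSA samples one value per stochastic leaf per iteration, consuming
draws in the fixed depth-first order of the configuration document from a
single seeded generator, so runs are bit-reproducible from the seed and
both arms share each draw (arms derived from a common curve stay
correlated). CEACs report, per willingness-to-pay λ, the fraction of
iterations with positive incremental net monetary benefit. EVPI per
patient is `E[max(NMB_t, NMB_c)] − max(E[NMB_t], E[NMB_c])`; the population
EVPI multiplies by the discounted eligible population (1,743/year, 10
years, 4%, first year undiscounted — the convention differs from the
alternative by a single 1.04 factor).

Two numerical facts worth knowing when interpreting PSA output at the
bundled uncertainty magnitudes: (i) the LR derivation `max(0, ·)` is
kinked, so when the DFS-event SE is large relative to the mean gap the
probabilistic mean differs from the plug-in (deterministic) estimate by a
term that decays only linearly in the SE scale — the plug-in consistency
check in the test suite is therefore stated on a smooth regime; (ii) for
the same reason EVPI at a threshold near the ICER decays linearly, not
quadratically, as SEs shrink.

## Bundled configurations and placeholders

The three scenario files mirror the published input tables: the real-world
transition probabilities and their SEs, the health-state cost table, the
trastuzumab resource counts and unit prices, the DFS first-year utility
(0.728) and the cardiac disutility (0.128) are public at printed precision.
The following are **not**, and carry clearly commented placeholders chosen
once for internal consistency:

- the trial hazard ratios (DFS/OS 0.76, DM 0.50) and cardiac relative risk
  (5.3, back-derived from the published per-arm cardiac disutility totals);
- the first-year cardiac-event fraction (0.125, back-derived from the
  published −0.016 QALY decrement divided by 0.128);
- non-DFS utilities: 0.80 (DFS subsequent), 0.71 (LR), 0.60 (DM),
  back-derived from the published per-state QALY/LY ratios;
- the guideline subgroup's transition table and the trial scenario's
  per-arm survival blocks;
- the cohort start age (55 years, a plausible mean age at diagnosis).

Published per-arm base-case totals are bundled separately
(`published_base_case.yaml`) as reporting-layer inputs: the incremental
statistics recomputed from them (ΔC €3,559 / ΔE 0.827 → €4,304 per QALY;
€5,495 / 0.861 → €6,382; trial ΔC −€11,450 with dominance) validate the
incremental machinery independently of the placeholder inputs. The
headline published totals themselves are not recomputable from public
inputs, and model output under placeholder hazard ratios is expected to
differ from them in the cost increments (it does: the bundled real-world
configuration yields dominance rather than a small positive ΔC, because
the placeholder DM hazard ratio controls the distant-metastasis cost
offset); per-arm life years and QALYs land within ~0.5% of the published
values.

## Synthetic cohort generator

`generate_cohort` draws, per patient, independent cause-specific
piecewise-exponential latent times (local, distant, death) whose composites
reproduce the configured annual probabilities exactly; observed endpoint
times are nested minima, so the ordering DFS event ≤ DM ≤ death holds by
construction. Censoring is uniform on 3.8–6.8 years (a ~3-year accrual
window with a fixed follow-up cut-off), independent of events. First-year
cardiac events are Bernoulli; annual per-state costs are Gamma draws at a
configurable patient-level coefficient of variation. The control arm
divides the composite rates by the hazard ratios.

`estimate_inputs` is the matching estimator: follow-up is split at one
year, the rate per endpoint and stratum is events/person-time (the
exponential maximum-likelihood estimator), the annual probability is
`1 − e^{−rate}`, and SEs use the Poisson variance of the event count,
delta-method-transformed. Strata without person-time are flagged missing.

What the generator does *not* emulate: confounding by indication
(treatment effects are trial-derived by design), treatment crossover,
competing non-cancer morbidity, cost–survival correlation within patients,
and calendar-time trends. Passing recovery tests therefore show that the
estimation arithmetic is correct for data that satisfy the model's
assumptions, not that the assumptions hold in any real cohort.

## Problem sizes and tolerances

The test suite runs cohorts of 500–50,000 synthetic patients for recovery
(recovering the subsequent-year DM probability within ±0.006 at n = 5,000,
the binomial-scale error at cohort size), a 2,000-iteration PSA for the
acceptability-curve checks, and smaller seeded PSAs (120–1,500 iterations)
for distributional properties; the acceptance script uses 2,000 PSA
iterations. Engine-vs-oracle comparisons (matrix powers, absorbing-chain
fundamental matrix, geometric and discounted-sojourn closed forms) hold to
1e−9 or better; probability conservation to 1e−12 per cycle.

## Known limitations

- Exponential (two-stratum) survival only; no Weibull/spline extrapolation.
- Cohort-level tunnel approximation for time-in-state pricing (half-cycle
  inflow split) rather than explicit tunnel states.
- The derived DM mortality inherits any tension between an extrapolated
  flat overall-survival input and rising background mortality; the excess
  is floored at zero, so modelled all-cause mortality can exceed the OS
  input at old ages.
- Two strategies only; no multi-arm frontier, EVPPI or EVSI.
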