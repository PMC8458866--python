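# Methods

## Model structure

`rccsim` is a patient-level state-transition (microsimulation) model of
first-line therapy for advanced renal cell carcinoma.  Six strategies
share one structure: three active treatment lines followed by best
supportive care (BSC) and death.  The sequences are

| strategy | first line | second line | third line |
|---|---|---|---|
| lenvatinib+pembrolizumab | lenvatinib + pembrolizumab | cabozantinib | sorafenib |
| nivolumab+cabozantinib | nivolumab + cabozantinib | axitinib | sorafenib |
| nivolumab+ipilimumab | nivolumab + ipilimumab | cabozantinib | sorafenib |
| pembrolizumab+axitinib | pembrolizumab + axitinib | cabozantinib | sorafenib |
| avelumab+axitinib | avelumab + axitinib | cabozantinib | sorafenib |
| sunitinib | sunitinib | nivolumab | sorafenib |

Patients enter at age 62 (weight 70 kg) and are simulated on 42-day
cycles until death or age 100.  A month is 30.4375 days throughout, so
one cycle is 1.3799 months.  Costs (2021 USD) and health outcomes are
discounted at 3% per year as `(1.03)^(-elapsed years)`, with the
discount factor taken at cycle start.

Within a cycle, events resolve in a fixed order: (1) background death
from the life table; (2) treatment-related (adverse-event) death, on
active treatment only; (3) progression, via the conditional survival of
the line's PFS law (in BSC, death via its OS law); (4) adverse-event
discontinuation.  With 42-day cycles and small per-cycle probabilities
the ordering is second-order; it is fixed so that runs are exactly
reproducible.  There is no half-cycle correction: events take effect at
cycle end, and the cycle in which a patient dies is accrued in full
(`costing`: "cycle-end accounting").

## Survival laws

Time-to-event laws are parameterized as

* Weibull `S(t) = exp(-(t/scale)^shape)`
* log-logistic `S(t) = 1/(1 + (t/scale)^shape)`
* lognormal `S(t) = 1 - Φ((ln t - μ)/σ)` with `μ = ln(scale)`,
  `σ = 1/shape` (the registry never selects lognormal; the mapping is
  documented and tested so the shape/scale convention is well defined)
* exponential, one parameter.  The registry prints a bare "shape" for
  the sorafenib exponential fit, which is ambiguous; the default
  interpretation is *mean survival time in months*
  (`S(t) = exp(-t/mean)`), switchable to a monthly or annual rate via
  `config.exponential_parameter`.

Per-cycle transition probabilities are `1 - S(t+Δ)/S(t)` with `t` the
time already spent in the phase.  Extrapolated tails are not truncated;
the lifetime horizon (age cap 100) is the only bound.  This matters:
the fitted log-logistic laws are heavy-tailed (the BSC overall-survival
law has median 13.9 months but mean ≈ 29 months), and the model's
life-year totals are correspondingly sensitive to the tails.

Maximum-likelihood fitting of pseudo individual-patient data maximizes
the censored log-likelihood `Σ_events log f(t) + Σ_censored log S(t)`
over log-transformed parameters (enforcing positivity) from three
deterministic starting points (Nelder–Mead, tolerance 1e-8), keeping
the best optimum; model selection takes the minimum AIC
(`2k - 2 log L`), breaking ties toward fewer parameters and then
lexical family order.  lifelines reproduces the same estimates in the
test suite as an independent route.

## Kaplan–Meier reconstruction

Digitized curve coordinates plus a numbers-at-risk table are inverted
into event/censoring times by the iterative KM-inversion scheme:
within each risk-table interval, a trial censor count (spread uniformly
over the interval) is adjusted until the implied number at risk at the
next anchor matches the published one, with events at each digitized
click computed from the running product-limit value and rounded to
integers.  Ties place events before censorings (the standard KM
convention).  Small residuals (≤ max(2, 2% of n)) are tolerated as
rounding artifacts of coarse digitization grids; larger negative
residuals raise an error naming the interval.  After the last anchor,
events come from the remaining clicks and everyone still at risk is
censored at the end of digitized follow-up; a published total event
count, when supplied, is matched by relabelling the latest censorings.

## Adverse events

Trials report *cumulative* proportions of patients discontinuing (or
dying) because of grade ≥3 adverse events over the whole treatment
period.  These are converted to constant per-cycle hazards calibrated
so that the cumulative incidence over the line's **median PFS** equals
the printed proportion: `h = 1 - (1-p)^(1/median_cycles)`.  Median PFS
is the natural exposure anchor because it is available for every line.

What a discontinuation *does* is a genuine structural choice the source
material does not settle, so it is a configuration switch
(`discontinuation_mode`):

* `advance` (default): the patient moves to the next treatment line
  immediately, as if the discontinuation were a progression event.
* `stop_drug`: drug acquisition/administration cost and
  treatment-related mortality stop, but the patient remains
  progression-free on the line's PFS clock (keeping the line's utility)
  and starts the next line at progression.

The choice is consequential.  Under `advance`, high-discontinuation
regimens (pembrolizumab+axitinib, 48%) are pushed through the sequence
quickly, which shortens their time at high utility and makes the
strategy strictly dominated in the base case; under `stop_drug` the
published frontier ordering (sunitinib → pembrolizumab+axitinib →
nivolumab+cabozantinib) is reproduced, at the price of 35–60% higher
life-year totals for every strategy.  The default follows the
convention that both progression and discontinuation advance the
sequence; `stop_drug` is the recommended structural sensitivity.

AE management is a one-off cost charged on line entry (charging it per
cycle would dwarf drug costs).  The utility decrement for grade ≥3 AEs
(0.157) applies for exactly one cycle at line entry, weighted by the
line's AE proxy probability (discontinuation + mortality proportions);
this is deliberately conservative and switchable
(`apply_entry_disutility`).

## Costing

Drug cost per cycle follows label dosing schedules mapped onto the
42-day cycle (q3w → 2 administrations, q2w → 3): weight-based IV doses
round *up* to whole billing units (no vial sharing, one-unit floor);
flat IV doses consume `ceil(dose/unit)` units per administration; oral
agents are costed per day on drug at the printed unit strength
(sunitinib 4-weeks-on/2-off = 28 days per cycle).  The
nivolumab+ipilimumab regimen has a two-cycle induction block (four q3w
combination doses) followed by nivolumab maintenance, priced per phase.
Administration fees are $148.30 per first/single infusion and $71.88
per sequential infusion; oral-only cycles are free.  BSC costs $1,256
per cycle.  A `stop_rule` (maximum treatment duration in cycles) exists
per regimen but defaults to none.

## Background mortality

The packaged life table (`data/life_table_us2017_synthetic.tsv`) is a
synthetic Gompertz-shaped stand-in for a recent US period life table:
`q(age) = 0.0098 × 1.0935^(age-62)`, ages 62–100 (q(100) ≈ 0.29).
Annual probabilities convert to cycle probabilities as
`1-(1-q)^(42/365.25)`.  Any two-column table (age, q_annual) can be
substituted.  Background mortality is a second-order driver at this
horizon; the tail behaviour of the fitted survival laws matters far
more.

## Simulation engine and randomness

`run_cohort` is vectorised across patients but each patient consumes an
independent uniform stream derived from `(master seed, patient index)`
(numpy `SeedSequence.spawn`), so results are independent of execution
order and batch size, and common random numbers across strategies come
free by reusing the seed.  `cohort_expectation` is the deterministic
oracle: it propagates the full probability mass over (phase,
time-in-phase, on/off-drug) with the same per-cycle probabilities and
no random numbers; the microsimulation mean must sit within Monte-Carlo
error of it, which the test suite checks on randomized parameter sets.

## Sensitivity and scenario machinery

Probabilistic sensitivity analysis samples costs from gamma, utilities
and probabilities from beta, and starting age and weight from truncated
normal distributions; hyperparameters come from the method of moments
with SD = (upper − lower)/(2×1.96) unless an SD is printed (second- and
third-line utilities).  Parameters without a printed range vary ±20%.
Infeasible beta moments are clamped with a warning.  Two registry
ranges are normalised before sampling: the ipilimumab and avelumab cost
ranges are per 70-kg dose and are divided by the dose's billing units
(7 and 70); the sorafenib AE-management range does not bracket its mean
and defaults to ±20% of the mean.  One-way (tornado) analysis pushes
each parameter to its bounds with everything else at base, under common
random numbers, and sorts by ICER span.  CEAC probabilities are the
fraction of PSA iterations in which a strategy attains the maximal net
monetary benefit (`wtp × QALY − cost`), ties split equally; the default
willingness-to-pay grid is 0–300,000 in steps of 10,000.

Scenario analyses are declarative overrides: restricted horizons
(5/10/20 years), an independent Bernoulli election of BSC at each first-
or second-line exit (10–30%), second-line substitution of cabozantinib
by nivolumab or axitinib with a cross-substitution lookup for
strategies already carrying the substitute in first line, and a
multiplicative price cut applied to nivolumab acquisition cost only
inside the nivolumab+cabozantinib first-line regimen.

## Synthetic data

The generators exercise every pipeline stage with known ground truth:
digitized KM fixtures (inverse-CDF event times, optional uniform or
exponential censoring, step-function sampling on a 1-month grid with
risk anchors every 3 months, mimicking published figures), Gompertz
life tables, and random (cost, QALY) tables for frontier stress tests.
They emulate digitization granularity and administrative censoring but
not trial-specific censoring patterns, informative censoring, or
digitization *noise* (mis-read pixels); passing round-trip tests
therefore show algorithmic correctness, not robustness to sloppy
digitization.

## Problem sizes and numerical choices

Default runs use 5,000 patients per cohort (Monte-Carlo SE on QALYs
≈ 0.015); the acceptance script uses the same size, and the scaled-down
PSA uses 200 iterations × 500 patients.  Oracle-equivalence checks use
20,000–100,000 patients.  ICERs are computed unrounded and displayed
rounded to the nearest dollar; monetary table output uses two decimals.
Degenerate inputs are defined rather than errors: zero survival mass
makes the transition certain, `q_annual = 1` kills within the cycle,
and a one-patient cohort is valid (with wide standard errors).

## Known limitations

* The printed per-strategy lifetime costs of the source analysis cannot
  be derived from its own unit prices under any uniform dosing
  convention; this package's costs are internally consistent with the
  registry's unit prices and label dosing, and run higher than the
  published totals.  ICER-level comparisons with the published values
  inherit that gap.
* Discontinuation semantics change the base-case ordering (see above);
  conclusions about the cost-effectiveness frontier should be reported
  under both modes.
* No within-line dose reductions, treatment interruptions, or
  re-challenge; no direct progression-to-death channel (death is
  background, treatment-related, or BSC); no societal perspective.
* Pooling of multi-trial arms is concatenation of reconstructed IPD;
  published pooled parameters need not be exactly reproducible.
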