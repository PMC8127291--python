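# Methods

## Model structure

The evaluation couples a one-shot screening decision tree to a Markov cohort
model, the standard architecture for screening cost-effectiveness analyses.

**Decision tree.** True sarcopenia status is Bernoulli(prevalence); the test
result is Bernoulli(sensitivity) for the sarcopenic and
Bernoulli(1 − specificity) for the healthy. The tree is evaluated in
expectation (exact fractions), so `classify_cohort` is deterministic; the
microsimulation realizes the same tree stochastically. Screening happens
once, before the first cycle, and its cost is undiscounted.

Strategies are reduced to (sensitivity, specificity, stage-1 cost, stage-2
cost). The stage-2 cost (DXA for EWGSOP, the high-risk assessment for
SARC-F) is charged to the *final* positive rate because the first-stage
referral rate of the staged algorithms is not reported; only overall
operating characteristics are. This is the identifiable lower bound on
staged testing cost; `stage2_charge_multiplier` scales the charged fraction
for sensitivity analysis. SarSA-Mod and MSRA are modelled as single-stage
(no confirmatory DXA charge), matching their single cost rows. "No
screening" is the null test: sensitivity 0, specificity 1, zero cost.

**Health states.** Healthy, sarcopenia without CVD, sarcopenia with CVD,
dead. Progression is forward-only: sarcopenia and CVD are irreversible and
the healthy never become sarcopenic after the single screen (the cohort is
screened once at entry). Pre-/severe-sarcopenia staging and comorbidities
other than CVD are out of scope.

**Fracture as an event, not a state.** Each cycle, a person in a sarcopenia
state has a fall-with-fracture event with probability
`p_fall × p_fracture_given_fall` (0.273 × 0.40 = 0.1092 untreated; the 0.40
is read as conditional on falling, since the narrative chains
fall → fracture). In an event cycle the person's utility is the fracture
utility of their state (0.51, or 0.42 with CVD) and their death probability
for that cycle is the fracture-specific 0.171, *replacing* (not
compounding) the state value; the fracture cost of $3599.05 is charged once
per event; survivors return to the underlying state's utility next cycle.

**Within-cycle order.** Event first (it fixes the cycle's death probability
and utility), then death, then — among survivors of the sarcopenia state —
the CVD transition. The order is shared verbatim between the cohort engine
and the microsimulation through one `TransitionModel` object, so the oracle
tests actually constrain the engine.

**Treatment efficacy.** The 40% intervention efficacy multiplies (i) the
fall probability, (ii) CVD incidence, and (iii) the sarcopenia-attributable
*excess* mortality — state minus healthy, floored at zero — by
(1 − efficacy). Excess-risk scaling keeps a treated patient's mortality at
or above the healthy baseline for any efficacy in [0, 1]; at efficacy 1 the
treated death probability equals the healthy one exactly. The fracture-cycle
case fatality is deliberately not scaled (treatment reduces how often people
fall, not the lethality of a fracture that has happened). Only true
positives are treated; false positives are clinically re-examined, pay one
cycle of intervention cost and are otherwise unaffected.

**Accounting.** 25 annual cycles. QALYs use a trapezoidal half-cycle
correction applied per within-cycle subcohort: a subcohort entering with
mass *m* and cycle death probability *q* earns *m·(1 + (1−q))/2* cycles at
its utility, so a mid-cycle death earns half a cycle — identically in the
microsimulation, where a death counts 0.5. Recurring costs (treatment,
continuing CVD care) are charged on start-of-cycle occupancy, which makes
the false-positive arm's extra cost exactly one undiscounted treatment
price at a 0% discount rate; one-off costs (fracture, first CVD cycle) are
charged on the event mass. Everything accrued in cycle *t* is discounted by
(1+d)^−t, d = 0.05/year (range 0.03–0.12). The horizon truncates
accumulation; no forced death at the final cycle, which would distort
half-cycle QALYs.

## Healthy-arm mortality: constant vs life table

The inputs give a single healthy death probability (0.09/cycle, sourced from
a national life table) alongside state-specific sarcopenia mortalities. Two
modes ship:

* `constant` (default): 0.09 every cycle, exactly as printed;
* `vector`: an age-indexed annual probability for ages 60–84. The shipped
  vector is a **synthetic approximation** of a national period life table
  (0.012/0.018/0.030/0.050/0.085 per year in 5-year blocks), not an official
  table; cycles beyond its length reuse the last entry.

The choice is consequential. A fixed 0.09 gives a 60-year-old healthy cohort
a discounted life expectancy of ≈ 6.6 years (≈ 5.0 QALYs), far below the
published per-strategy effects of 7.4–8.5 QALYs, which are only attainable
with age-specific rates; published incremental *costs* are reproduced well
in vector mode (e.g. 1990 vs the printed 2064 USD for EWGSOP). In vector
mode the treated excess-mortality baseline is the cycle's healthy
probability, so treated state mortality is cycle-varying; untreated state
mortalities stay at their absolute printed values in both modes.

## Parameters and uncertainty

Every scalar is an `UncertainParameter` with a family (Beta for
probabilities/utilities, Gamma for costs, `fixed`) and one of: a printed SD,
a printed 95% CI (converted by SD = (hi − lo)/(2·1.96)), or nothing — then
SD defaults to 12.5% of the mean (midpoint of the stated 10–15% band,
configurable within that band). The intervention-efficacy "±15%" is an
absolute SD of 0.15. EWGSOP's sensitivity of exactly 1 is held fixed in PSA
(no Beta distribution has mean 1, and no uncertainty is printed for it).
Beta/Gamma parameters are moment-matched so the fitted distribution's
analytic mean and SD equal the inputs (to 1e-9 relative, tested).

PSA draws all uncertain parameters independently (no correlation structure
is reported). Joint draws violating the structural invariants — the utility
ordering (healthy ≥ sarcopenia; CVD+fracture ≤ each of CVD, fracture) or any
derived transition probability leaving [0, 1] — are rejected and redrawn
from the same stream, preserving the marginals conditional on feasibility.
With default SDs the utility marginals overlap, so the rejection rate is
substantial (roughly 35–40% of joint draws); it is counted and logged.
A single seeded generator drives all iterations, making PSA output
bit-identical under a fixed seed.

## Decision analysis

Both ICER conventions are implemented because published screening analyses
mix them: a common-reference table (every strategy vs no screening) and a
frontier table (sequential ICERs after removing strongly/weakly dominated
strategies — costlier, no more effective; the cheaper member survives an
equal-effect tie — then iteratively removing extendedly dominated ones,
i.e. non-increasing sequential ICERs; exactly collinear points keep the
middle member, since removal requires a strict inequality). The frontier is
validated against an NMB-sweep oracle: a strategy is retained iff it
uniquely maximizes λ·E − C for some λ ≥ 0. NMB uses λ = $5520.311/QALY (one
GDP per capita).

CEAC: for each λ on a grid (default 0 to 3λ in 100 steps), the fraction of
PSA iterations in which each strategy has the strictly highest NMB; exact
ties split an iteration's mass equally (a measure-zero event for continuous
draws; it matters only in degenerate tests). Selection probabilities are the
CEAC at λ itself.

The tornado's default outcome is the NMB gap of EWGSOP over its best
alternative at the threshold (the ICER vs no screening is available by
flag); ranges are printed CIs where available, else base ± 1 SD, clipped to
each parameter's domain and to the structural utility ordering with a
warning.

## Microsimulation oracle

`simulate_individuals` draws individual trajectories with Bernoulli
transitions at the same per-cycle probabilities, the same competing-risk
order and the same accounting conventions as the cohort engine, taken from
the shared objects rather than re-derived — a deliberate coupling, because
an oracle with independently re-implemented conventions would silently
diverge on convention changes rather than on genuine bugs; what remains
independent is expectation-vs-realization. Tests require per-arm mean
discounted cost and QALYs at n = 10⁵ to fall within 3 Monte-Carlo standard
errors of the cohort result for all five strategies, empirical transition
frequencies to recover the input probabilities within 3 binomial SEs, and
cells with no sampling variance (the false-positive arm's cost is one fixed
treatment cycle) to match exactly. The oracle report simulates under
SarSA-Mod because EWGSOP's perfect sensitivity leaves the false-negative arm
empty.

What the synthetic cohort does *not* emulate: covariate heterogeneity
(age/sex-specific risks beyond the optional mortality vector), repeat
screening, imperfect treatment adherence, or correlated parameter
uncertainty. Passing oracle tests therefore demonstrates internal
consistency of the two engines under the stated model, not external
validity of the inputs.

## Numerical choices and problem sizes

Cohort propagation is exact expectation algebra on a unit-mass vector
(occupancy conservation checked to 1e-9; dead occupancy monotone).
The engine agrees with the closed-form trapezoidal geometric series to
1e-10 in the constant-hazard no-event limit. Default analysis sizes —
1000 PSA replications, 10⁵ simulated individuals for oracle checks — match
the published analysis scale and keep any full run to seconds on one core.

## Known limitations

* The mechanism by which the published analysis applied treatment efficacy
  inside its proprietary TreeAge model is not stated. Under this package's
  mechanism (efficacy on transition and event probabilities only, as the
  published assumptions describe) the per-treated-patient QALY gain is
  ≈ 1.1; the published per-strategy effects imply ≈ 4.5, which would require
  a treated sarcopenic to exceed the utility-weighted healthy life
  expectancy given the printed utilities. Consequently the published
  base-case NMB ranking (EWGSOP first) and the ≈ 70% EWGSOP selection
  probability are not recovered: this implementation finds no-screening
  NMB-optimal at the threshold, with EWGSOP selected in ≈ 17–19% of PSA
  iterations in life-table mode. Incremental costs, cost ordering, effect
  ordering, the ICER/NMB arithmetic on the published table, and MSRA's
  dominance all reproduce.
* Whether the published analysis charged DXA confirmation to SarSA-Mod/MSRA
  positives is unstated; single-stage costing is used (printed cost
  differences cannot disambiguate this at printed precision).
* Calibration procedures behind several "calibration / expert opinion"
  inputs are unreported; base values are taken as printed.
* The CVD incidence (0.27) is applied per cycle, and fracture-cycle
  mortality replaces state mortality; both readings are flagged as
  interpretive choices in the parameter documentation.
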