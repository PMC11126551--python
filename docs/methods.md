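# Methods

This note documents the model, the estimation choices, the synthetic
data regime and the numerical conventions implemented in `worklife`,
together with their rationale and known limitations.

## Model and assumptions

The population is followed from exact age 40 to a censoring age — 75
when observations are annual (step 1), 76 when biennial (step 2) — so
the last modelled origin age is 74 in both designs.  Four mutually
exclusive states: employed, jobless (unemployed, inactive, students,
permanently disabled, housekeepers and other residual non-employment),
retired (retired only), and dead.  Death is absorbing; the three
labor-force states are transient and can be revisited.

Transitions follow a first-order discrete-time Markov assumption given
covariates: the state at t+step depends on the state at t (categorical
lagged-state indicators), a restricted cubic spline in age, and fixed
covariates — education (low/medium/high), parity (0/1/2/3+), marital
status (married/single/divorced/widowed) and one extra categorical
(country-style control, e.g. nativity), plus an education × parity
interaction.  Models are estimated separately by gender, which is
equivalent to interacting gender with every term (verified against a
pooled block-diagonal fit in the test suite).

Key parameters and defaults:

- **Age spline**: 5 knots at quantiles (0.05, 0.275, 0.5, 0.725, 0.95)
  of observed origin ages, the conventional placement; configurable, and
  the basis is linear beyond the boundary knots.  Data-driven knots are
  resolved once per analysis and held fixed across bootstrap replicates,
  treating the basis as part of the model specification.
- **Reference categories**: destination employed, origin employed,
  education low, parity 0, marital married, first extra level.  Fixed
  and arbitrary; they affect the parameterization only.
- **Optimisation**: Newton–Raphson on person-period counts aggregated
  over identical design rows (ages and covariates are discrete, so
  aggregation is lossless), gradient tolerance 1e-8 per observation,
  at most 500 iterations, step-halving; on separation or
  non-convergence the fit is retried with a ridge penalty of 1e-6 per
  observation and flagged.  Destinations never observed in a stratum
  get probability exactly zero rather than a divergent coefficient.
- **Prediction profiles**: population estimates set every categorical
  to its sample (person-period) proportion; group estimates set the
  group's indicators to one and the remaining blocks to within-group
  proportions.  Interaction cells use the joint sample proportions, so
  they are always consistent with the margins.
- **Radix**: the state distribution at the baseline age, estimated
  within each group by default ("observed"); an explicit distribution
  may be supplied instead.  The default initial mix in the generator is
  employed 0.75, jobless 0.20, retired 0.05.

## Expectancies

The age-expanded chain has 3 × (number of occupancy ages) transient
composite states ordered age-major; U is block-superdiagonal and
nilpotent, so (I − U) is always invertible.  Expected years in a state
are step × the radix-weighted occupancies from the fundamental matrix,
equal (to 1e-10, tested) to forward-iterated occupancy sums.  A person
in state s at exact age a is credited `step` years in s for
[a, a + step); no half-interval correction.  This convention makes the
conservation identity (employment + joblessness + retirement = residual
LE) and the zero-mortality horizons (35 years annual, 36 biennial)
exact, at the cost of attributing a full interval to the state at its
start — the reason a biennial chain slightly overestimates expectancies
relative to an annual chain over the same span (demonstrated exactly
and on synthetic data in the test suite).

## Mortality matching

Panel-based mortality follow-up can be too thin to pin down the level
of mortality; matching rescales it to an official period life table
without disturbing the labor-force structure.  Sequentially in age, a
single factor c(a) ≥ 0 solves Σᵢ πᵢ(a) · min(1, c(a) qᵢ(a)) =
q_lt(a) by bisection to 1e-12, where π(a) is the alive-state occupancy
under the already-adjusted younger ages; each row's transient
probabilities are rescaled by (1 − q'ᵢ)/(1 − qᵢ).  The matched chain's
population survival equals the life table's at every age (tested to
1e-8) and its total residual LE equals the table's temporary life
expectancy under the same occupancy convention.  Proportionality
preserves the ordering of state-specific mortality and, in practice,
the ordering of clearly separated status expectancies; near-ties can
flip, which is inherent to any reweighting.  Factors estimated at the
gender level are applied to each group's matrices, preserving relative
group differences.  If model mortality is identically zero at an age
with a positive target there is no direction to scale; an additive
fallback exists but is off by default.  Matching is opt-in
(`match: true` with a life table), as it is only appropriate when an
authoritative external mortality schedule exists for the population.

## Bootstrap

Nonparametric percentile intervals from B = 1,000 person-level
resamples by default (2.5th/97.5th percentiles).  The person is the
resampling unit — the only unit that preserves the longitudinal
structure — and each replicate re-runs the entire pipeline (records →
stratified fits → profiles → prediction → optional matching →
expectancies).  Internally a replicate weights the once-built records
by each person's resampling multiplicity, which is exactly equivalent
to materialising the resample with fresh person ids (asserted in the
tests); replicate seeds are spawned from one master seed, so results
are deterministic and independent of execution order.  Replicates in
which a stratum, an origin state present in the full sample, or a
reported group comes up empty are dropped and counted; more than 5%
dropped aborts the run.  The point estimate is the full-sample
estimate, not the bootstrap mean, and the percentile interval is not
forced to bracket it.

A scaled-down calibration study (200 synthetic datasets × 200
replicates, 2,000 persons, single-stratum design with origin and
age-spline terms only so the model is correctly specified and the study
runs at desk scale) checks that the nominal 95% interval covers the
true employment expectancy at the expected rate.

## Synthetic data

The generator emulates the two study designs — annual register-style
panels censored at 75 and biennial survey-style panels censored at 76 —
with covariates drawn independently per person from marginals of a
realistic order (53% women; parity 16/18/36/30; education 31/38/31;
marital 60/17/17/6; 3.5% foreign-born) and held fixed from age 40
onward.  Freezing covariates matches the modelling frame (they enter
the lagged-state regression as covariates, not as states) and keeps
the ground truth computable; real panels have some post-40 parity and
marital-status change that this abstracts away.  The default truth
coefficients describe a stylized Nordic-like regime: persistent
joblessness (log-odds +4.0 for the lagged state), a steep retirement
hazard rising from the late fifties (intercept −30, slope 0.45 per
year of age), log-linear mortality from ≈0.002 at 40 to ≈0.025 at 74
(higher for men), a parity-2 employment maximum for both genders with
a motherhood penalty at parity 3+, and protective education gradients.
The biennial regime shifts exit intercepts by log 2, approximately
doubling small one-year hazards.  One master seed drives covariate
draws and the vectorised state stepping, so panels are byte-identical
given (config, seed).  An optional thinning mode observes an annual
panel every second wave, assigning deaths between waves to the next
coarse wave, for studying the biennial discretization bias.

Passing tests on these panels show that the pipeline recovers a known
data-generating process of realistic magnitude at realistic sample
sizes; they do not speak to misspecification present in real data
(duration dependence beyond first-order lag, time-varying covariates,
attrition correlated with outcomes, measurement error in self-reported
states).

## Numerical and degenerate-input conventions

Softmax linear predictors are max-shifted before exponentiation; rows
of every transition matrix are validated to sum to 1 within 1e-10.
Gap pairs (non-adjacent observations) are dropped, not imputed.  Deaths
reported between waves are assigned to the destination of the pair
whose origin is the last alive observation.  Panels whose ages are
non-monotone within a person are rejected with the offending person id.
Life tables accept qx or lx columns; two-year probabilities are the
survival products 1 − (1 − qx)(1 − qx₊₁).  Structural zeros (e.g.
forbidding retirement reversals) are available as an explicit mask
that zeroes named cells and renormalizes, but are off by default so
rare back-flows stay estimable.

## Study sizes used by the checks

The recovery study uses 20,000-person panels (annual and biennial);
the chain oracles use 100,000 simulated trajectories per chain; the
bootstrap calibration uses 200 datasets × 200 replicates at 2,000
persons.  At 20,000 persons the per-cell sampling standard error of a
gender × parity expectancy is roughly 0.06–0.10 years (it is governed
by the counts of rare events — deaths and retirements within a parity
cell), which bounds how closely any single synthetic run can be
expected to track the ground truth cell by cell.

## Known limitations

First-order Markov dynamics given covariates; no duration dependence.
Covariates frozen at baseline.  No survey weights.  No continuous-time
or half-interval refinements — expectancies are step-quantized by
design.  Matching assumes a proportional mortality adjustment; it
cannot create mortality where the model has none.  The percentile
bootstrap ignores simulation error in very small strata beyond the
drop rule.
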