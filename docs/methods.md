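# Methods

This note records the models, the calibration procedure, the numerical
choices, and the limitations of the package. Units throughout: intakes in
µg RAE/day, populations in '000s of children 6–59 months, money in '000s of
2013 USD (500 CFA = 1 USD underlies the source budgets; no discounting).

## 1. Synthetic survey generator

No public microdata exist for the 2009 Cameroon micronutrient survey, so
the pipeline runs on synthetic surveys with the same structure: one 24-h
vitamin A recall per child, a second recall for a 30% subsample, habitual
fortification-vehicle consumption, a VAS-receipt flag, and three
macroregion strata (North, South, Cities).

Per child in a region:

* usual intake `U = exp(μ + σ_b z)` with `z ~ N(0,1)`;
* recall days `Y_j = U · exp(e_j)`, `e_j ~ N(0, σ_w)` with a default
  within-person CV of 0.5 (not printed in the source; typical for single
  nutrients);
* vehicle consumption: a Bernoulli consumer indicator whose propensity may
  correlate with `z` (Gaussian copula), and a lognormal amount (CV 0.6)
  that may also correlate with `z`, clipped at a dietary-plausibility
  ceiling (oil 80 g/d, bouillon 15 g/d, maize 650 kcal/d — roughly half a
  toddler's energy intake for the staple);
* bouillon amounts are a two-class mixture: a substantial-use class
  (bouillon-seasoned family dishes daily) and a token-use class at one
  tenth the amounts. "Consumed yesterday" reach counts both;
* maize consumers are a subset of bouillon consumers (both mark access to
  market foods), drawn from the substantial-use class first;
* VAS receipt is Bernoulli with the region's measured reach, with its own
  propensity–intake correlation.

A final calibration loop rescales the usual intakes so the generator-known
prevalence below the EAR matches the region's baseline to ±0.01 (bisection
on a log-scale shift; monotone in the target).

Age is uniform over 6–59 months; survey weights default to 1. The EAR
table uses the IOM cutoffs (210 µg for 12–47 months, 275 µg for 48–59
months) and 190 µg for 6–11 months, where no formal EAR exists; all values
live in configuration.

## 2. Calibration to the printed anchors

The regional generating distributions are solved, at run time, from the
printed ten-year tables of the source analysis. An analytic population
model (`calibration.PopulationModel`) computes, by quadrature over the
intake driver `z`, the exact prevalence of `U + Σ program doses < EAR` for
any program combination — doses add within a child, so a combination can
cover children no single program covers. Identification proceeds in
stages:

1. **Intake distribution** (μ, σ_b): baseline prevalence plus the VAS
   coverage cell (VAS adds a fixed 167 µg/day, so its coverage pins the
   probability mass within 167 µg of the cutoff).
2. **Oil** (amount median, consumption–intake correlation, VAS-receipt
   correlation): the oil-44 cell, the enhanced-oil (44–72–100 ramp) cell,
   and the BAU (oil-44 + VAS union) coverage cell, jointly. In the South
   the printed cells *require* a negative consumption–intake coupling —
   reach times baseline prevalence is already below the oil-44 cell — which
   matches how adequacy arises in these diets: children already rich in
   vitamin A (red palm oil) are not the refined-oil consumers. Where the
   enhanced-oil and BAU cells cannot both be met (North, Cities), the BAU
   cell wins — it equals the optimization floor and fixes the VAS coverage
   margins — and the enhanced-oil deviation is recorded in the
   diagnostics.
3. **Bouillon and maize** amount medians: their mature-year coverage
   cells.
4. **Bouillon use-intensity mixture** (substantial-use share): the
   year-4 combined-coverage cell of the mature optimal program pair, which
   is what identifies how the oil and bouillon benefits overlap.
5. **Cities baseline prevalence** — the one distribution anchor with no
   printed value — is solved so the national year-4 combined cell is met
   (the printed Cities coverage cells bound it below ≈0.40; it lands at
   ≈0.50, keeping the national baseline at "roughly half").

Anchors that remain unattainable at a bound are reported as explicit
shortfall diagnostics, never silently absorbed. A regression test checks
that the generator reproduces the analytic model's coverages to ±0.006.

## 3. Usual-intake estimation

The estimator is an amount-only variant of the measurement-error
("NCI-method") family: vitamin A intake is near-daily in this population,
so the probability part of the two-part model is omitted. On a Box-Cox
scale (λ selected by profile likelihood over {0, 0.25, 1/3, 0.5}; ties to
the smaller value) a one-way random-effects model is fitted by profiled
REML — a one-dimensional bounded search over the variance ratio with
closed-form profiles, cross-checked against `statsmodels` MixedLM in the
test suite. If no child has a second recall day the within-person variance
is unidentified and the fit raises, rather than silently degrading. At the
degenerate boundary (identical repeat days) the components are estimated
directly so that usual intakes equal the observed person means.

Per-child usual intakes are exposed two ways:

* **point values** (`person_usual`): shrunken person means, rescaled on the
  transformed scale to the estimated between-person variance before
  back-transformation. Plain shrunken means compress the tails and bias
  cutoff prevalences by up to ~0.02–0.03 at high within-person CV; the
  variance-matching step removes this while preserving ranks. Plain and
  second-order-Taylor back-transformations remain available.
* **posterior distributions** (`person_blups`, `person_cond_sd`): the
  conditional normal of `μ + b_i` given the child's recalls. Scenario
  prevalence defaults to averaging each child's posterior probability of
  falling below the (dose-shifted) cutoff — closed form, monotone in the
  dose, and unbiased in the tails, which matters because the portfolio
  comparison runs on small differences of large coverage numbers. The
  point mode remains a config switch (`intake.prevalence_mode`).

Parameter recovery (prevalence bias < 0.02 for n ≥ 1000 across a
within-person-CV grid of 0.3–0.7) is enforced in the test suite.

## 4. Scenario engine and benefits

A scenario activates programs per (region, year). Each active program's
contribution is added to every child's intake — oil `g/day × 12 µg/g ×
dose factor`, bouillon `g/day × 80 µg/g`, maize `kcal/day × 0.34 µg/kcal`,
VAS 167 µg for reached children — and prevalence is re-evaluated under the
fitted machinery (deterministic per-child shifts reusing the baseline
variance components; this keeps scenario prevalence monotone in the dose,
which the pathway logic requires). Effective coverage is baseline minus
scenario prevalence, floored at zero per region-year (a withdrawn program
cannot create negative coverage); reach is the share receiving any
addition; child-years multiply by the population trajectory (geometric,
1.5%/yr, bases set so the ten-year totals equal the printed 12.7/13.9/5.8
million child-years).

Deaths averted use a region-level envelope of vitamin-A-preventable deaths
(year-1 value growing with the population) times the share of the dietary
burden resolved: `deaths = envelope(y) · EC_frac / baseline_prev`, capped
at the envelope. This collapses the source's Lives Saved Tool projection
into its observable behaviour — the printed deaths-averted cells are very
nearly proportional to coverage within each region (≈2.62 deaths per
thousand covered child-years in the North, ≈1.8 South, ≈1.4 Cities) — and
the South/Cities envelopes are anchored to the printed ≈780 and ≈355
annual totals, the North's derived from its printed VAS deaths-averted
cell. No cause-of-death structure, no mortality uncertainty.

## 5. Costs

Fortification programs carry national annual cost streams with
start-up-era (years 1–3) and mature (years 4–10) levels, apportioned to
regions by fixed shares; the split is calibrated jointly to the printed
program totals, the optimal-scenario annual cost stream, and the mature
South fortification pair (≈$336k/yr), which are mutually consistent. VAS
is costed per region as 60% fixed plus a per-child component scaling with
the population (the only time-varying cost), embedding the 90% share of
Child Health Days overhead attributed to VAS. Validation studies cost $450k
per study (South and North) and $350k (Cities; only "lower" is stated).
Costs are undiscounted 2013 USD.

## 6. Portfolio optimization

Decision structure: fortification programs are all-horizon national
commitments (start-up capital is sunk; the two oil variants are mutually
exclusive), VAS is free per macroregion-year. The solver enumerates the
twelve fortification configurations; for each, a small MILP (HiGHS via
`scipy.optimize.milp`, integrality gap zero) selects the VAS years closing
the remaining gaps at minimum cost. Ties break toward the
lexicographically smallest activation set (a tiny index-proportional
epsilon makes the MILP optimum unique). Correctness is tested against
brute-force enumeration on reduced instances.

Two floors express "meet at least the BAU outcomes": total child-years
covered *and* total deaths averted, both evaluated on the model's own BAU
bundle. The lives floor is not decorative: coverage alone is satisfied by
one year of northern VAS, and biofortified maize is a cheaper coverage
filler than supplementation — the deaths constraint is what requires VAS
North in years 1–2 (before fortification matures) and excludes maize
(broad but shallow benefits). A config switch drops it.

## 7. Pathways

Each region runs the enhanced-oil + bouillon build-out with VAS retained.
The withdrawal trigger evaluates *dietary* adequacy — fortification only,
since VAS is the program being judged and is not diet — against the 2.5%
threshold. The first sub-threshold year schedules a validation study; in
two-study mode a second follows two years later ("nonconsecutive" = trigger
+ 2, matching the year-4/year-6 narrative); VAS is withdrawn the year
after the final confirming study. Studies are assumed to confirm the
prediction; a hook injects failures, which reset the machinery. Regions
never crossing the threshold keep VAS throughout and are charged one study
(year 4) documenting that withdrawal conditions are unmet.

## 8. Monte Carlo robustness

Each of 1000 replicates perturbs benefit streams (normal, 5% CV, truncated
at zero — the source does not print its standard errors) and costs
(uniform ±20%), then re-solves the optimization. Three correlation choices
matter and are deliberate, config-exposed defaults:

* benefit draws are shared per *region*: every program's coverage estimate
  in a region derives from the same survey and the same fitted intake
  distribution, so their errors co-move (per-family and per-program modes
  available);
* cost draws are a common costing-level factor: the budgets descend from
  one costing exercise and one CFA/USD exchange rate
  (`cost_common_share` < 1 adds program-specific residuals);
* the benefit floors track each replicate's perturbed BAU bundle — the
  benchmark is estimated by the same model, which also guarantees the BAU
  bundle stays feasible in every replicate.

Under fully independent per-program draws with fixed floors, a
continue-oil-44 portfolio with five years of northern VAS sits ~4% from
the optimum and the selection flips in a large minority of draws; the
correlated design reflects how these uncertainties actually arise and
keeps the program *selection* stable while totals still vary.

VAS counts as "included" in a replicate only if active at least three
years (configurable). Infeasible replicates are counted and reported,
never dropped.

## 9. Problem sizes and numerics

Default runs use 60,000 synthetic children per macroregion (the package's
choice for stable coverage tabulation; the estimator suite also runs at
n ≈ 1,200–2,000), 1000 Monte Carlo replicates, and an 80-node
Gauss-Legendre / 20-node Gauss-Hermite quadrature in the calibration
model. All randomness flows from a single run seed (per-stage streams
derived below 2³¹); identical (config, seed) pairs reproduce every output
bit-for-bit. Calibration results are cached per config hash within a
process.

## 10. What passing tests do and do not show

The generator emulates the *statistical structure* the analysis assumes —
lognormal usual intake, within-person recall noise, copula-coupled vehicle
consumption — calibrated so printed coverage and cost anchors are
reproduced. It does not reproduce the real survey's sampling design
(clusters, strata, weights), seasonal intake variation, age–intake
correlation, or the joint food-composition detail of real recalls. Tests
passing here show the pipeline's machinery is correct and that the printed
results follow from the printed anchors under these structural
assumptions; they cannot validate the assumptions against the 2009 data.

Known limitations and internal tensions of the source tables are carried
openly: the BAU total cost is ~1.6% above the sum of its program rows (the
program rows are used); the printed enhanced-oil coverage cells in the
North and Cities exceed what any consumption–intake coupling can deliver
once the other cells are matched (the deviations are recorded in the
calibration diagnostics); the bouillon anchors imply large effective doses
among substantial users; and the source's Monte Carlo inclusion rates for
VAS North (99.5% at ≥3 years, against a printed optimum with 2 years) and
maize (11.3%) are reported by this package as 0% under its perturbation
design — both are monitored, not asserted.
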