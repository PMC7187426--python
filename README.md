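# vitaplan

Vitamin A intervention planning for young children, built around the
Cameroon case: given dietary-recall survey data (here: calibrated synthetic
surveys), the package estimates the distribution of habitual vitamin A
intake per macroregion, simulates what fortification and supplementation
programs would add to each child's diet, prices the programs, finds the
cheapest program portfolio that matches business-as-usual (BAU) benefits
over ten years, and traces GAVA-compliant policy pathways for withdrawing
vitamin A supplementation (VAS) once fortification makes diets adequate.

It is written for nutrition and health-policy modellers who want a tested,
reproducible version of this analysis chain rather than a spreadsheet.

## The models inside

**Usual intake.** A child's single 24-h recall `Y_ij` mixes habitual intake
with day-to-day noise. On a Box-Cox scale `g(·)` (log when λ = 0) the
package fits the measurement-error model

    g(Y_ij) = μ + b_i + e_ij,   b_i ~ N(0, σ²_b),   e_ij ~ N(0, σ²_w),

by profiled REML, identifying σ²_w from the repeat-recall subsample. A
child's habitual intake is recovered from the conditional distribution of
`μ + b_i` given their recalls; the prevalence of inadequate intake is the
weighted share with usual intake below the age-specific Estimated Average
Requirement (EAR).

**Programs.** Fortified oil (44% or ramping 44–72–100% of the 12 mg/kg
target), fortified bouillon (80 mg/kg from year 4), biofortified maize
(0.34 µg RAE/kcal from year 4) and VAS (a 167 µg RAE/day equivalent for
reached children) each add `dose × amount` to a child's intake. Effective
coverage of a program set is the drop in prevalence it causes; deaths
averted scale the region's envelope of vitamin-A-preventable deaths by the
share of the dietary burden resolved.

**Optimization.** Fortification programs are national sunk commitments; VAS
switches per macroregion and year. The solver enumerates the fortification
configurations and solves a small mixed-integer program (HiGHS) for the VAS
years, minimizing ten-year cost subject to covering at least the BAU
child-years *and* averting at least the BAU deaths.

**Pathways.** Each region runs the efficient fortification build-out with
VAS retained until dietary inadequacy falls below 2.5%, then one or two
biomarker validation studies (nonconsecutive years) precede withdrawal.

All regional distributions are calibrated at run time to the printed
anchors of the underlying study (baseline prevalences, per-program
coverage cells, reach fractions, cost totals); see `docs/methods.md`.

## Worked example

```python
from vitaplan import Pipeline
from vitaplan.optimizer import solve
from vitaplan.regions import Region

pl = Pipeline.from_config(seed=1, n_children=60_000)
print(pl.fits[Region.NORTH].summary())
print(solve(pl.problem()).summary())
```

```
Usual intake model (amount-only measurement-error fit)
--------------------------------------------------------
children:            60000
repeat-day children: 18181
Box-Cox lambda:      0
fixed mean (transformed): 4.6442
var between persons:      1.4852
var within person:        0.2256
backtransform correction: variance_match
median usual intake:      103.5 ug RAE/d

status: optimal
total cost ('000s USD): 9,495
total coverage ('000s CY): 13,355
total deaths averted: 26,828
coverage slack: 519
fortification: oil_enhanced, bouillon
VAS NORTH: years [1, 2]
```

The North's fitted intake distribution (median ≈ 104 µg RAE/day against a
210 µg EAR for most ages) carries 73% inadequacy. The optimal portfolio
upgrades the oil program, launches bouillon fortification, and keeps VAS
only in the North and only for the first two years — after which the
fortification programs deliver the benefits. It covers ≈13.4m child-years
for ≈$9.5m ($0.71 per child-year effectively covered), versus ≈$29.6m
($2.32/CY) for continuing BAU.

The same pipeline is scriptable from the shell (`vitaplan --help`):
`simulate-survey`, `estimate`, `scenario`, `optimize`, `pathway`,
`montecarlo`, and `report` each write tidy CSV/JSON plus a run manifest.

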