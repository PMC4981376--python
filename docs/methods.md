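# Methods

This note records the modeling conventions of `rhdcea`: the Markov cohort
model of ARF/RHD natural history, the outcome and cost accounting, the
sensitivity-analysis machinery, and the design choices made where the
published description of the original spreadsheet tool is silent.

## State space and transitions

Nine states: `WELL`, `ARF_FIRST`, `RF_REMISSION`, `ARF_RECUR`, `RHD`,
`SEVERE_HF`, `STROKE_AF`, `DEAD_DISEASE`, `DEAD_OTHER`. The two ARF states
are one-cycle tunnels — every occupant exits each cycle to death
(case-fatality rate), chronic RHD (progression probability) or remission
(the remainder). First and recurrent episodes are separate tunnels because
their case-fatality rates (0.010 vs 0.020) and RHD-progression
probabilities (0.360 vs 0.720) differ; the recurrent case-fatality rate is
the standard assumption of twice the first-episode rate. Chronic RHD
progresses to severe heart failure (0.008/yr) or to stroke/atrial
fibrillation (0.003/yr). There is no remission from severe heart failure
absent surgery (probability pinned at 0).

Annual transition probabilities, effect sizes, disability weights and
milestone ages, with their low/high bounds and PSA distribution families,
live in `rhdcea.parameters.BASE_PARAMETERS` and are exported as the CSV
tables of the input bundle.

**Age windows and decay.** The first-ARF probability applies at its base
value at ages 5–14 and is zero before age 5; the recurrence probability
applies at ages 5–24. Past its window each probability decays
exponentially, `TP_t = TP_0 · exp(−0.1 Δt)` with `Δt` the years past the
window end. (An alternative reading of the source material has the
recurrence risk extend to 40 years after onset; we follow the stated age
ranges and treat the decayed tail as covering later ages.)

**Interventions.** Coverage enters through the weighted-average probability
`TP(c) = c·TP_off·(1−RR) + (1−c)·TP_off`. Primary prevention (RR 0.320)
acts on the first-ARF probability, secondary prevention (RR 0.450) on the
recurrence probability, and valve surgery (RR 0.800) on the heart-failure
death probability. Both surgery delivery options (build a center, refer
abroad) move the same clinical lever and differ only in program cost.
Surgical survivors remain in `SEVERE_HF` for costing and disability; no
post-surgical remission state is modeled. In a given scenario the two
non-focal interventions stay at the baseline coverage in both arms.

**Stroke mortality.** Stroke carries a one-time acute case fatality of
0.167 applied on entry: the RHD→stroke flow is split at transition time
into `p_stroke · 0.167` (disease death) and `p_stroke · 0.833` (chronic
stroke/AF), which is equivalent to dying in the first cycle in state and
keeps the chain Markovian. The chronic stroke state carries the stroke
disability weight and state cost but no further disease mortality.

**Background mortality.** Background death `q(age)` from the life table
competes with disease transitions within a cycle: `q` is applied first and
the disease transitions are distributed among survivors
(`row = q·e_DEAD_OTHER + (1−q)·disease_row`). This multiplicative
composition guarantees row-stochastic matrices for any admissible parameter
draw. Cycle k of a trace corresponds to age `start_age + k`, with `q` and
`e` capped at the table's closing age (100, matching the 100-cycle
horizon). No half-cycle correction is applied to the trace.

**Reference cohorts.** PP is evaluated for a newborn in the general
population (`WELL`, age 0); SP for an individual with ARF history
(`RF_REMISSION`, the average age of first attack, 8); VS for an individual
with prevalent RHD (`RHD`, the average age of RHD prevalence, 24). Start
ages are wired to the age parameters, so the sensitivity analyses vary
them.

## Life tables

A period life table supplies `q(a)` and remaining life expectancy `e(a)`,
computed with the mid-interval convention (deaths contribute half a
survived year): `e(a) = Σ_{t≥1} Π_{k=a}^{a+t−1}(1−q_k) + 0.5`.

The base case uses a synthetic table for a life expectancy at birth of 68
years, generated from a two-component hazard: a constant child/adult
background hazard (0.0015/yr) plus a Gompertz senescent term
`B·exp(0.09·a)`, with `B` solved by bisection to hit the target e0 within
0.01 years and the table closed at age 100. This hazard family and its
fixed components are this package's choice — the original analysis does not
publish its life table — and users can substitute a real country table as a
two-column CSV (`age,q`).

## Health outcomes

DALYs = YLL + YLD per reference individual, discounted at 3%/yr with
`(1+r)^−k` (cycle 0 undiscounted). YLD sums disability-weighted occupancy
over the 100 lived cycles (ARF tunnels carry the ARF weight for their
single cycle; no age weighting). YLL counts only new entries into
`DEAD_DISEASE` — excluding background deaths operationalizes the
subtraction of background mortality from both arms — each weighted by the
life-table expectancy at the age of death, discounted as an annuity
continuing from the death cycle. Discounting the lost years as an annuity
(rather than adding `e(age)` undiscounted) is our choice, consistent with
discounting all health outcomes at the same rate; at `r = 0` it reduces to
the plain sum.

The healthy-life-expectancy gain is the undiscounted difference (post −
ante) in `Σ occupancy·(1 − disability weight)` over alive states.
Population extrapolation multiplies per-individual DALYs averted by the
scenario's reference population and divides by the 100-year horizon to give
an average annual figure; the bundled reference populations are 20.9 M
(total population, PP), 83,300 (ARF history: 1.7% cumulative incidence ×
4.9 M aged 5–24, SP) and 49,000 (1% RHD prevalence × 4.9 M, VS).

## Costs

Nominal 2010 US$, health-system perspective, discounted at 3%. State costs
accrue per person-cycle: ARF episodes $1,490 (hospitalization), remission
under secondary prophylaxis $288, chronic RHD under secondary prevention
$617.10, severe heart failure $957.10, stroke/AF $617.10.

**Every occupant of a state accrues its cost** (the standard Markov costing
convention). We examined the alternative of charging the two
secondary-prevention state costs only to the covered fraction of occupants:
it inflates the SP scenario's incremental cost by roughly $7,900 per
person and pushes its ICER far above the surgical-referral option,
contradicting the published qualitative ordering (PP cost saving, then SP,
then referral, then building a center) that the unweighted convention
reproduces. The coverage-weighted variant remains available via
`healthcare_costs(..., sp_coverage=...)`.

Program costs are per-reference-individual discounted amounts added to the
post arm only (they are the cost of moving coverage from ante to post):
PP $3.66, SP $2,226.59, build-center $25,626.54, refer-abroad $3,711.69.
A `ProgramCosting` worksheet alternatively builds the figure from capital
annualization (standard capital-recovery factor
`K·r/(1−(1+r)^−L)`; straight-line at `r = 0`), recurrent operating costs,
admin-loaded per-case costs, and per-capita add-on components, discounted
over a 30-year horizon and divided by the reference population. Note the
published example quotes "about $970,000" for annualizing $20 M over 30
years at 3%; the standard formula gives ≈$1.02 M, and we use the standard
formula.

## CEA conventions

`ICER = Δcost / ΔDALYs` when DALYs averted are positive, flagged *cost
saving* when Δcost < 0 (reported as a negative ratio); scenarios with
non-positive health gains are flagged *dominated* (Δcost ≥ 0) or
*SW-quadrant* (Δcost < 0) with the ratio withheld. League tables sort
cost-saving first, then ascending ICER, dominated last, with GDP multiples
rounded to one decimal and printed as `---` where undefined. Acceptability
curves compare the scenarios and the status quo (zero incremental cost and
effect) by net monetary benefit `wtp·ΔE − ΔC` per PSA trial; ties break
toward the status quo.

## Sensitivity analysis

**One-way (tornado).** Every parameter and cost row is set to its low and
high bound in turn (all else at base) and the scenario ICER recomputed;
impact = |ICER(high) − ICER(low)|, ranked descending, top ten flagged for
plotting. For competing-transition rows the implicit remainder absorbs the
change. The discount rate is included as an input, varied over 0–6% (the
conventional range; the source does not state its bounds). A dominance flag
at an extreme is recorded in place of a number and ranks after all numeric
bars.

**Distribution fitting.** Bounds are read as 95% intervals,
`sd = (high − low)/3.92`, fitted by method of moments: beta for standalone
probabilities and disability weights (falling back to `uniform(low, high)`
with a logged warning when the moments are infeasible); gamma for ages and
for all costs (whose printed bounds are ±50% of base); lognormal on the
relative-risk scale for the three risk reductions, with
`median(1 − RR) = 1 − base` and `σ = (ln(1−low) − ln(1−high))/3.92`.
Lognormal draws are clipped into (0, 1) so sampled risk reductions stay
proportional — for the wide SP interval (0.22–0.92) about 15% of unclipped
draws would imply a harmful effect, and clipping piles that mass at "no
effect" instead; the sampled *median* is the calibrated quantity for these
rows (their mean is not `base` by construction, which is inherent to a
median-parameterised lognormal). Rows with degenerate bounds sample as
point masses, so an all-degenerate PSA reproduces the deterministic result
exactly.

**Dirichlet groups.** Competing exits from one state — {first-ARF exits},
{recurrent-ARF exits}, {RHD exits}, {severe-HF exits} — are sampled jointly
from a Dirichlet whose mean is the base shares closed with the implicit
remainder, with the concentration chosen so the largest-variance member
matches its method-of-moments variance. Zero-share members (heart-failure
remission) are structural zeros.

**PSA.** 2000 trials by default. Per-trial substreams are spawned from the
root seed by counter, so results are bit-reproducible for a given seed and
the sampled inputs of trial k are independent of the scenario list. Trials
whose draws compose to an invalid matrix are resampled with a logged
counter (the run aborts beyond 1%; in practice the joint distributions make
violations impossible by construction). The summary reports mean
incremental costs and effects, the ICER of means, and the mean and
2.5/97.5-percentile interval of per-trial ICERs over trials with positive
health gains — per-trial ICERs are heavy-tailed when sampled effects
approach zero (the SP scenario especially), which is why the ICER of means
is reported alongside.

## What the base case does and does not reproduce

The desk-checkable arithmetic reproduces exactly: the coverage-weighting
worked example (8% ante / 76% post), the GDP multiples of the published
ICERs (0.6 / 2.9 / 18.3 at $1,300), and the doubled recurrence case
fatality (0.020).

The absolute published base-case results (ICERs of −$2,539 / $752 /
$23,827 / $3,814, their credible intervals, healthy-life-expectancy gains
and population DALYs) depend on inputs the publication does not contain:
the hypothetical country's full life table, the spreadsheet's internal
distribution parameterizations, and its program-costing worksheet. They are
therefore not expected to match numerically. With the bundled inputs this
implementation yields the same qualitative league table — PP cost saving
(−$3,477), SP $1,467, referral $5,169, build $29,089 — with every ICER
within a factor of about two of the published value, and the same
qualitative sensitivity structure (the SP risk reduction dominates the SP
tornado; acceptability shifts from PP to SP at low willingness to pay and
toward referral-based surgery at high willingness to pay).

The synthetic life table and the bundled scenario configuration emulate a
stylized low-income country; they capture the age structure of background
mortality and the published coverage targets but not country-specific
mortality shocks (HIV, conflict), secular trends in ARF incidence, or
heterogeneity in care access. Passing tests on these inputs validates the
decision-model arithmetic, not the epidemiology of any real country;
applying the tool to a real setting requires a national life table, local
ARF incidence, and locally costed program worksheets.

## Numerical choices and problem sizes

Matrices are built vectorized over all cycle ages; row sums are enforced to
1e-12 and trace mass conservation to 1e-10. The default test-suite and CLI
runs use 100-cycle traces, 2000-trial PSAs and 10⁴–10⁵-draw Monte-Carlo
checks, which complete in well under a minute on a single CPU. Known
limitations beyond those above: no maternal, endocarditis or surgical
complication sequelae; no echocardiographic active case-finding pathway; no
societal-perspective costs; no extended dominance / frontier analysis
across mutually exclusive intervention mixes.
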