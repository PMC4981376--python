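# rhdcea

A Markov cohort cost-effectiveness model for prioritizing interventions
against acute rheumatic fever (ARF) and rheumatic heart disease (RHD) in
endemic, resource-limited settings.

RHD — chronic valve damage following untreated streptococcal pharyngitis and
ARF — remains a leading cause of cardiovascular death among children and
working-age adults in much of Africa. Ministries of health must choose
between three broad strategies: **primary prevention** (PP, antibiotic
treatment of streptococcal sore throat), **secondary prevention** (SP, a
patient registry delivering monthly prophylactic penicillin to people with a
history of ARF), and **valve surgery** (VS, delivered either by building a
local surgical center or by referring patients to high-volume centers
abroad). `rhdcea` estimates the incremental cost-effectiveness of scaling up
coverage of each strategy, for analysts planning RHD control programs and
universal-health-coverage benefit packages.

## The model

A nine-state Markov cohort model of the ARF/RHD natural history is run over
a lifetime horizon of 100 one-year cycles: Well → first-episode ARF (a
one-cycle tunnel) → RF remission ⇄ recurrent ARF (tunnel) → chronic RHD →
severe RHD with heart failure, with a stroke/atrial-fibrillation branch, and
separate absorbing states for disease and background deaths. Background
mortality comes from a country life table (or a synthetic one matched to a
target life expectancy at birth).

Intervention coverage `c` enters as a weighted average of the transition
probability with and without the intervention,

```
TP(c) = c · TP_on + (1 − c) · TP_off ,    TP_on = TP_off · (1 − RR),
```

where RR is the intervention's proportional risk reduction (PP 0.32 on first
ARF, SP 0.45 on ARF recurrence, VS 0.80 on heart-failure death). Each
scale-up scenario compares an *ante* trace (current coverage) with a *post*
trace (target coverage); health outcomes are disability-adjusted life-years
(DALYs = YLL + YLD, GBD disability weights), costs are 2010 US$ from a
health-system perspective, and both are discounted at 3%/yr. The incremental
cost-effectiveness ratio is

```
ICER = (ΔhealthcareCost + programCost) / DALYs averted   [US$ per DALY],
```

reported in a league table with multiples of GDP per capita. One-way
(tornado) sensitivity analysis and probabilistic sensitivity analysis
(beta/Dirichlet/lognormal/gamma input distributions, 2000 Monte-Carlo
trials) with cost-effectiveness acceptability curves are built in.

## Worked example

The bundled base case is a hypothetical African country of 20.9 million
people (4.9 million aged 5–24), life expectancy at birth 68 years, GDP per
capita US$1,300, with 10% baseline coverage of every intervention and
targets of 70% (PP), 92% (SP) and 95% (VS):

```python
from rhdcea import RhdCeaModel

model = RhdCeaModel.base_case()
results = model.fit()
print(results.summary())
```

```
ARF/RHD scale-up cost-effectiveness (per reference individual, discounted)
==========================================================================
                    scenario       icer        flag gdp_multiple delta_cost dalys_averted hle_gain
                 Scale up PP $-3,476.92 cost saving          ---    $-10.52        0.0030     0.01
                 Scale up SP  $1,467.28                      1.1    $993.78        0.6773     2.10
VS: refer for surgery abroad  $5,168.61                      4.0  $4,735.17        0.9161     2.29
   VS: build surgical center $29,089.42                     22.4 $26,650.02        0.9161     2.29
```

Each row is one scale-up scenario evaluated for its reference individual
(PP: a newborn in the general population; SP: a child with ARF history; VS:
an adult with prevalent RHD). Scaling primary prevention averts more in
downstream care costs than the program costs — it is *cost saving* (negative
ICER, no GDP multiple). Secondary prevention costs ~$1,467 per DALY averted
(1.1× GDP per capita, cost-effective at conventional thresholds); surgical
referral abroad costs ~$5,169 per DALY (4.0×); building a local surgical
center is by far the least efficient (~$29,089, 22.4×), since both surgery
options buy the same health gain (0.92 DALYs averted, 2.3 healthy life-years
per RHD patient) at very different program cost.

Sensitivity analyses:

```python
model.tornado("SP").head(3)          # most influential one-way inputs
psa = model.run_psa(n_trials=2000, seed=1)
psa.summary()                        # mean ICERs and 95% credible intervals

from rhdcea import ceac
import numpy as np
curves = ceac(psa, np.linspace(0, 50_000, 51))   # acceptability curves
```

The same analyses run from the shell:

```
rhdcea fixture --out inputs/                 # write the editable input bundle
rhdcea run     --config inputs/scenarios.yaml --out results/
rhdcea psa     --trials 2000 --seed 1 --out results/
rhdcea tornado --scenario SP --out results/
rhdcea ceac    --trials 2000 --seed 1 --out results/
```

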