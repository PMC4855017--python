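# amdcea

A lifetime Markov cohort cost-utility model comparing four management
strategies for neovascular ("wet") age-related macular degeneration in a
resource-limited health system: intravitreal **bevacizumab**, intravitreal
**ranibizumab**, **verteporfin photodynamic therapy** (PDT), and **usual
(supportive) care**.

Wet AMD destroys central vision through choroidal neovascularization.
Anti-VEGF agents changed its management, but ranibizumab's price puts it out
of reach in many health systems, while off-label bevacizumab costs two
orders of magnitude less per dose with similar efficacy. This package is for
health economists and HTA analysts who want a transparent, fully tested
implementation of the decision model behind that trade-off: which strategy
buys QALYs at an acceptable cost per QALY in a setting where the
willingness-to-pay threshold is around one per-capita GDP ($7,480/QALY)?

## The model

Patients occupy one of six states: five visual-acuity (VA) bands of the
better-seeing eye on the Snellen chart — >20/40, ≤20/40 to >20/80, ≤20/80 to
>20/200, ≤20/200 to >20/400, ≤20/400 — plus death. Every 3-month cycle the
cohort can stay, improve by >3 lines (one band up), lose 3–6 lines (one band
down), or lose >6 lines (two bands down), and can die from any state at the
age-specific natural mortality rate *q_x*.

Trial-reported cumulative probabilities *P* over a one-year period are
converted to per-cycle probabilities under a constant-rate (exponential)
assumption,

```
q = 1 − (1 − P)^(1/4)        (so compounding q over 4 cycles recovers P)
```

Strategies never trialled head-to-head are linked by risk ratios on the
cumulative probabilities (indirect comparison): ranibizumab is anchored on
PDT for predominantly classic lesions and on usual care for minimally
classic and occult lesions; bevacizumab chains a second risk ratio onto the
derived ranibizumab probabilities. Active treatment lasts two years; from
year 3 every arm follows the usual-care year-2 transition probabilities
until death.

Costs (2012 US$) cover drugs and administration, follow-up (consultation,
OCT, fluorescein angiography), serious adverse events of the injection arms,
and low-vision comorbidities (depression, falls, assisted living) for the
three worst VA bands. Utilities per VA band come from time-tradeoff
valuations. Costs and QALYs are discounted at 3%/year and accrued at cycle
start (no half-cycle correction; a config switch enables it). Results are
summarized as

```
ICER = (C_b − C_a) / (E_b − E_a)      [$ per QALY]
NMB  = λ·E − C                        [λ = willingness to pay]
```

with strict and extended dominance flagged on the efficiency frontier, plus
one-way (tornado) sensitivity analysis, scenario analysis over starting age
and initial VA band, a 1000-draw probabilistic sensitivity analysis (beta
for probabilities and utilities, lognormal for costs, frequencies and risk
ratios; SD = 20% of the mean), and cost-effectiveness acceptability curves.

Two inputs of the original study are not published as numbers and are
replaced by documented synthetic stand-ins: the national 2011 life table
(a Gompertz–Makeham hazard calibrated so residual life expectancy at the
base-case starting age of 73.6 years is ≈12 years) and the initial VA
distribution (uniform over the five VA bands by default). Both are plain
config entries — drop in a real life-table CSV (`age,qx`) to override.

## Worked example

The base case needs no input files:

```sh
amdcea basecase --lesion occult --out results/
```

prints (dollars, discounted lifetime totals per patient):

```
lesion    strategy         cost  vision_years    qalys  icer_vs_usual_care             status               comment
occult  usual_care  4497.266922      2.578043 4.762573                 NaN        on-frontier
occult         pdt 13963.243477      2.870450 4.859294        97868.760423 strictly dominated             Dominated
occult ranibizumab 25321.841217      3.782962 5.171402        50937.086410        on-frontier    Not cost-effective
occult bevacizumab  5219.469593      3.726091 5.152134         1853.884548        on-frontier Highly cost-effective
```

Reading the table: ranibizumab buys the most QALYs (5.17) but at ~$50,900
per QALY gained over usual care — far above three times per-capita GDP
($22,440), so not cost-effective. PDT costs more and yields fewer QALYs than
bevacizumab, so it is strictly dominated. Bevacizumab gains 0.39 QALYs and
1.15 vision-years (undiscounted years with VA better than 20/200) over usual
care for about $722 extra, an ICER of ~$1,854/QALY — well below one
per-capita GDP, hence highly cost-effective.

The same pipeline is scriptable:

```python
from amdcea import default_parameter_set, strategy_result, build_frontier, icer
from amdcea.states import Strategy, Lesion

params = default_parameter_set()
results = [strategy_result(params, s, Lesion.OCCULT) for s in Strategy]
frontier = build_frontier(results, gdp_per_capita=params.cohort.gdp_per_capita)
print(frontier.to_frame())
```

Sensitivity analyses:

```sh
amdcea sensitivity oneway   --lesion occult --out results/   # tornado CSV
amdcea sensitivity scenario --lesion all    --out results/   # age / initial VA band
amdcea sensitivity psa  --n 1000 --seed 42 --plot --out results/
amdcea sensitivity ceac --n 1000 --seed 42 --plot --out results/
amdcea synth lifetable --out lifetable.csv   # synthetic life table as CSV
amdcea synth config    --out config.yaml     # editable copy of all defaults
```

Every run writes a `manifest.json` recording the config, seed, version, and
output files.

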