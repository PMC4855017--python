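# Methods

## Model structure

The model is a deterministic Markov cohort simulation over six health
states: five Snellen visual-acuity (VA) bands of the better-seeing eye —
`>20/40`, `≤20/40 to >20/80`, `≤20/80 to >20/200`, `≤20/200 to >20/400`,
`≤20/400` — and absorbing death. Each band spans roughly one Snellen
doubling (~3 lines), which fixes the transition geometry: a gain of >3 lines
moves one band up, a loss of 3–6 lines one band down, a loss of >6 lines two
bands down. Moves past the best or worst band fold into the boundary band
(total event probability is preserved rather than renormalized across the
row). The cycle length is 3 months and the horizon is lifetime (to the life
table's terminal age).

Within a cycle, death is applied first at the age-specific natural rate and
the vision transition happens among survivors. This ordering is a modelling
choice; it makes mortality independent of VA state and of utilities.
Mortality is natural only — no excess mortality is attached to vision loss.
The annual probability `q_x` is looked up at the integer part of the
cohort's current age and converted to a per-cycle probability with the same
exponential transform used for vision outcomes. The final schedule cycle
falls at the terminal age, where `q_x = 1`, so the cohort is absorbed and
the engine stops (or earlier, once dead-state occupancy reaches 1 − 1e-9).

## Effectiveness inputs and calibration

Trial arms observed directly (usual care and PDT) supply cumulative
probabilities of the three vision outcomes over year 1 and year 2, per
lesion subtype (predominantly classic, minimally classic, occult). The
printed year-2 values are interpreted as the probability of the event
occurring *during* year 2 — the conditioning is not stated in the source
tables, and this reading lets both years use the same period-to-cycle
transform with 4 cycles per period:

    q = 1 − (1 − P)^(1/4),

exact under a constant event rate within the period (the rate form
`1 − exp(ln(1−P)/4)` is algebraically identical; a property test holds the
two to 1e-14). `P = 1` is rejected since it implies an infinite rate.

Ranibizumab and bevacizumab are calibrated indirectly. Ranibizumab scales
its trial comparator's cumulative probabilities by published risk ratios —
the comparator is PDT for predominantly classic lesions and usual care
otherwise, matching the designs of the underlying trials. Bevacizumab
multiplies the derived ranibizumab probabilities by a second,
year-invariant, risk-ratio set. Products are clamped at 1 with a logged
warning (the base-case inputs never clamp). The three outcomes are treated
as mutually exclusive within a cycle, matching the trial endpoint
definitions; per-cycle probabilities summing above 1 after conversion are a
hard error rather than silently renormalized.

Active treatment and trial-informed transitions last two years. From year 3
until death, every arm — including the treated ones — uses the usual-care
year-2 outcome probabilities: the benefit accrued during treatment persists
only through the state distribution the cohort has reached, not through
continued differential transition rates.

## Costs, utilities, outcomes

All costs are 2012 US$ from the health-system perspective; indirect and
productivity costs are out of scope.

* **Treatment** (years 1–2 only): PDT is verteporfin + laser activation at
  2.05 administrations in year 1 and 1.54 in year 2; the injection arms are
  drug (ranibizumab $1,523.8, bevacizumab $10.5 per dose) plus the
  intravitreal-injection procedure ($41.3), at 8 injections in year 1 and 6
  in year 2. 100% of living patients are assumed treated.
* **Follow-up** (all arms, lifelong): ophthalmologist consultation and OCT
  once per cycle; fluorescein angiography at its published annual mean total
  ($234.8 — taken as authoritative over the printed per-year frequency,
  which is internally inconsistent with it).
* **Serious adverse events** (injection arms, both active-treatment years):
  published annual mean costs for endophthalmitis, lens damage, and retinal
  detachment ($34.2/yr ranibizumab, $56.4/yr bevacizumab). The source is
  ambiguous about whether "during 1 year" means year 1 only; both years is
  the conservative reading and the window is configurable (`sae_years`).
* **Comorbidities** (lifelong): depression, falls, and assisted living at
  their published annual mean totals ($103.9/yr combined), applied to
  occupancy of the three worst VA bands (≤20/80 and worse). The source says
  these costs vary with "degrees of visual acuity" without printing a
  per-state split; the eligible-state set is configurable
  (`comorbidity_states`). The printed fall and assisted-living unit-cost ×
  probability products appear swapped relative to their annual means; the
  annual means are stored as authoritative.

Annual amounts are spread evenly over the four cycles of each year and
apply to living occupancy only. QALYs are cycle length × Σ occupancy ×
utility, with published time-tradeoff utilities 0.89/0.81/0.57/0.52/0.40
from best to worst band and 0 for death. "Vision-years" — undiscounted
expected years with VA better than 20/200 (bands 0–2) — is a reporting
convention; the metric is not defined in the source and the cutoff is
configurable (`vision_states`).

Discounting is 3%/year for costs and QALYs, evaluated at each cycle's start
time as `(1.03)^(−t)`. Accrual uses start-of-cycle occupancy with **no
half-cycle correction** by default; `half_cycle_correction: true` switches
to averaging start- and end-of-cycle occupancy. The willingness-to-pay
threshold defaults to $7,480/QALY (1× per-capita GDP, 2011), with WHO
verdict bands at 1× ("highly cost-effective") and 3× ("cost-effective").

## Economic analysis

ICERs are pairwise incremental cost over incremental QALYs; a QALY
difference below 1e-9 is flagged "no incremental effect" rather than
divided through, and negative ratios are flagged "dominant"/"dominated"
with the signed value retained for reporting. The frontier removes strictly
dominated strategies (no cheaper, no more effective, worse on one margin),
then extendedly dominated ones iteratively until sequential ICERs strictly
increase. ICERs versus usual care are reported for every strategy,
dominated or not, because the reference-case table convention reports them.
A test oracle cross-checks frontier membership against an independent
welfare characterization (a strategy is on the frontier iff it strictly
maximizes net monetary benefit on some willingness-to-pay segment) on 1,000
random instances.

## Sensitivity analyses

**One-way (tornado).** Each input in the default list — starting age (55 /
88), the six bevacizumab-vs-ranibizumab risk-ratio components (±20%), the
five utilities (published ranges), bevacizumab and injection unit costs,
injection frequencies, and the time horizon (2 / 10 years) — is pinned to
each bound and the full pipeline re-run; the report is the
bevacizumab-vs-usual-care ICER at each bound. Pinning enforces only the
pinned value's own type bound: one-way analysis legitimately explores
utility values that break the base-case monotonicity across bands (the
published ranges themselves overlap).

**Scenario.** Degenerate initial distributions per VA band and alternative
starting ages, re-running all four arms.

**PSA.** Second-order Monte Carlo with 1,000 draws by default.
Probabilities (trial outcomes, SAE and comorbidity probabilities) and
utilities are drawn from beta distributions; costs, resource frequencies,
and risk ratios from lognormal distributions. Risk ratios are not
probabilities, so the lognormal family is used for them — the source names
distributions only for proportions, probabilities, utilities, and costs.
All distributions are parameterized by method of moments with SD = 20% of
the base value; where a beta with that SD would be infeasible (mean near 0
or 1) the SD is shrunk to 97% of the feasibility bound. Draws whose three
competing outcome probabilities sum above 1 are regenerated and counted in
the log. Utility draws are independent across bands; ordering violations
are logged, not corrected. Within a draw, all four strategies share the
same sampled parameters (common random parameters), so incremental
quantities are coherent; the year-invariant bevacizumab risk-ratio set is
drawn once per draw and shared across years and lesions, mirroring its
base-case structure. `sd_fraction = 0` makes every distribution degenerate
and reproduces the base case to machine precision (tested).

**CEAC.** At each point of the WTP grid (0–30,000 $/QALY in steps of 250,
covering 1× and 3× GDP), the probability that each strategy has the maximal
net monetary benefit across draws; probabilities sum to 1 by construction.
A pairwise-versus-reference variant is available
(`compute_ceac(..., pairwise_reference=...)`); best-of-four is the default.

## Synthetic inputs

Two study inputs are unpublished and are generated rather than transcribed:

* **Life table.** A Gompertz–Makeham hazard, `μ(x) = λ + a·e^{bx}` with
  `λ = 5×10⁻⁴`, `a = 2.1263×10⁻⁵`, `b = 0.10` over ages 40–105 (terminal
  age absorbing), calibrated so cohort residual life expectancy at the
  base-case starting age of 73.6 years is ≈12 years — a plausible value for
  the study population and period. A real period life table drops in as a
  two-column CSV (`age,qx`).
* **Initial VA distribution.** Uniform over the five VA bands. Newly
  diagnosed cohorts in practice are likely concentrated in the middle
  bands; the scenario analysis covers the degenerate cases.

Because these stand-ins replace real inputs, the *absolute* reference-case
totals and the headline ICERs shift with them; what the test suite
guarantees is the arithmetic (published per-table cost products exactly),
the qualitative economics (ranibizumab most effective, PDT strictly
dominated by bevacizumab, in every lesion subtype), the scenario and
horizon orderings, and the model-wide invariants below. Passing tests do
not certify that absolute QALY totals match any particular population, and
the synthetic generator emulates neither state-dependent mortality nor any
correlation between baseline VA and age.

The module also provides randomized-but-always-valid parameter sets for
property testing (outcome triples via scaled Dirichlet draws so competing
probabilities can never exceed 1; risk ratios backed out from directly
drawn treated-arm outcomes so no product clamps) and a first-order
Monte-Carlo **microsimulation oracle**: individuals walk the same cycle
matrices by categorical sampling, with per-state accrual taken from the
engine's own costing on one-hot occupancies, so agreement (within 3
standard errors at 100,000 individuals, tested) isolates the correctness of
the deterministic occupancy evolution.

## Numerical conventions

* Row-stochasticity enforced to 1e-12 on every cycle matrix.
* Occupancy conservation checked to 1e-10 per cycle in the trace invariants.
* NMB ties in the CEAC (measure zero under continuous draws) break toward
  the first-listed strategy.
* Life-table CSVs round-trip bit-identically (shortest-repr write,
  round-trip float parsing on read).
* Validation is two-tier: `validate_parameters` returns findings without
  raising; `load_parameters` raises on any finding. Base-case-only
  conventions (utility monotonicity, year-invariance of the bevacizumab
  risk ratios) are enforced at load but deliberately not re-enforced when
  the sensitivity machinery pins single values.

## Problem sizes

Default runs used throughout the tests and the acceptance script: 127
cycles per cohort (ages 73.6→105), 1,000 PSA draws, 100,000 microsimulation
paths for the oracle check, 100 random parameter sets for the
row-stochasticity sweep, 1,000 random instances for the frontier oracle.
The full test suite completes in well under a minute on one CPU.

## Known limitations

* No treatment beyond two years ("continuous treatment" is out of scope),
  no retreatment or discontinuation logic, no per-patient dosing variation.
* No utility decrements for adverse events (excluded by design); SAEs enter
  as costs only.
* No excess mortality from severe vision loss.
* The indirect comparison inherits the heterogeneity of its source trials;
  risk ratios are applied to cumulative probabilities, which can require
  clamping in extreme sensitivity scenarios.
* No EVPI or budget-impact analysis; no currency conversion machinery
  (everything is fixed in 2012 US$).
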