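"""Markov cohort simulation: occupancy evolution and discounted accrual.

The cohort starts distributed over the five VA bands and is evolved by
left-multiplication with the per-cycle transition matrices.  Costs and QALYs
are accrued on the occupancy at the start of each cycle and discounted at
the cycle-start time (no half-cycle correction by default; a config switch
averages start and end occupancy instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from amdcea.calibration import TransitionSchedule, build_schedule
from amdcea.parameters import ParameterError, ParameterSet, UtilitySet
from amdcea.states import (
    ACTIVE_INJECTION_STRATEGIES,
    DEAD_INDEX,
    N_STATES,
    N_VA_STATES,
    Lesion,
    Strategy,
)

DEAD_TOL = 1e-9


@dataclass
class MarkovTrace:
    """Per-cycle record of a cohort run.

    ``occupancy[k]`` is the state distribution at the START of cycle k+1
    (so ``occupancy[0]`` is the initial distribution); the trailing row is
    the distribution after the last executed cycle.
    """

    strategy: Strategy
    lesion: Lesion
    occupancy: np.ndarray       # (n_cycles+1, 6)
    ages: np.ndarray            # (n_cycles,) cohort age at cycle start
    cost_cycle: np.ndarray      # undiscounted per-cycle cost
    qaly_cycle: np.ndarray      # undiscounted per-cycle QALY
    disc_cost_cycle: np.ndarray
    disc_qaly_cycle: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.disc_cost_cycle.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.disc_qaly_cycle.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost_cycle.sum())

    @property
    def total_qalys_undiscounted(self) -> float:
        return float(self.qaly_cycle.sum())

    def to_frame(self) -> pd.DataFrame:
        n = len(self.ages)
        df = pd.DataFrame(self.occupancy[:n],
                          columns=[f"state_{i}" for i in range(N_STATES)])
        df.insert(0, "cycle", np.arange(1, n + 1))
        df.insert(1, "age", self.ages)
        df["cost_cycle"] = self.cost_cycle
        df["qaly_cycle"] = self.qaly_cycle
        df["cum_disc_cost"] = np.cumsum(self.disc_cost_cycle)
        df["cum_disc_qaly"] = np.cumsum(self.disc_qaly_cycle)
        return df


@dataclass(frozen=True)
class StrategyResult:
    """Lifetime discounted totals for one (strategy, lesion) arm."""

    strategy: Strategy
    lesion: Lesion
    cost: float
    qalys: float
    vision_years: float


def discount_factor(t: float, annual_rate: float) -> float:
    """Present-value multiplier at time ``t`` years: (1+rate)^(-t)."""
    if t < 0:
        raise ParameterError(f"time must be >= 0 (got {t})")
    if annual_rate < 0:
        raise ParameterError(f"discount rate must be >= 0 (got {annual_rate})")
    return (1.0 + annual_rate) ** (-t)


def annual_drug_cost(params: ParameterSet, strategy: Strategy,
                     year_index: int) -> float:
    """Annual drug cost: administration frequency x unit drug price.

    For PDT the "drug" is one verteporfin infusion plus its laser activation
    (one administration requires both); for the injection arms it is the
    per-dose drug price alone (the injection procedure is costed separately).
    Zero for usual care and for every arm after year 2.
    """
    strategy = Strategy(strategy)
    if year_index > 2 or strategy is Strategy.USUAL_CARE:
        return 0.0
    u, f = params.costs.unit, params.costs.frequencies
    if strategy is Strategy.PDT:
        freq = f["pdt_year1"].base if year_index == 1 else f["pdt_year2"].base
        return freq * (u["verteporfin"].base + u["laser_activation"].base)
    freq = (f["injections_year1"].base if year_index == 1
            else f["injections_year2"].base)
    drug = (u["ranibizumab_dose"].base if strategy is Strategy.RANIBIZUMAB
            else u["bevacizumab_dose"].base)
    return freq * drug


def annual_treatment_cost(params: ParameterSet, strategy: Strategy,
                          year_index: int) -> float:
    """Annual active-treatment cost: drug plus administration procedure.

    Active treatment runs for two years; usual care has no active component.
    """
    strategy = Strategy(strategy)
    drug = annual_drug_cost(params, strategy, year_index)
    if year_index > 2 or strategy in (Strategy.USUAL_CARE, Strategy.PDT):
        return drug
    f = params.costs.frequencies
    freq = (f["injections_year1"].base if year_index == 1
            else f["injections_year2"].base)
    return drug + freq * params.costs.unit["intravitreal_injection"].base


def annual_followup_cost(params: ParameterSet) -> float:
    """Annual monitoring cost common to all arms (consultation, OCT, angiography)."""
    u, f = params.costs.unit, params.costs.frequencies
    return (f["consultation_per_year"].base * u["consultation"].base
            + f["oct_per_year"].base * u["oct"].base
            + params.costs.fluorescein_angiography_annual_mean.base)


def cycle_costs(params: ParameterSet, strategy: Strategy,
                state_occupancy: np.ndarray, year_index: int) -> float:
    """Cost accrued in one cycle given the occupancy at the cycle start.

    Treatment, follow-up, and SAE costs apply to living occupancy;
    comorbidity costs apply to occupancy of the configured low-vision states.
    Annual amounts are spread evenly over the cycles of the year.
    """
    strategy = Strategy(strategy)
    if year_index < 1:
        raise ParameterError(f"year_index must be >= 1 (got {year_index})")
    occ = np.asarray(state_occupancy, dtype=float)
    if occ.shape != (N_STATES,):
        raise ParameterError(f"occupancy must have {N_STATES} entries")
    alive = float(occ[:N_VA_STATES].sum())
    per_cycle = 1.0 / params.cohort.cycles_per_year

    cost = alive * per_cycle * annual_treatment_cost(params, strategy, year_index)
    cost += alive * per_cycle * annual_followup_cost(params)
    if (strategy in ACTIVE_INJECTION_STRATEGIES
            and year_index in params.cohort.sae_years):
        cost += alive * per_cycle * params.costs.sae_annual_cost(strategy)
    comorb_occ = float(occ[list(params.cohort.comorbidity_states)].sum())
    cost += comorb_occ * per_cycle * params.costs.comorbidity_annual_cost()
    return cost


def cycle_qalys(utilities: UtilitySet, state_occupancy: np.ndarray,
                cycle_length: float) -> float:
    """QALYs accrued in one cycle: cycle_length x sum(occupancy x utility)."""
    occ = np.asarray(state_occupancy, dtype=float)
    return float(cycle_length * occ @ utilities.as_array()[:len(occ)])


def run_cohort(params: ParameterSet, schedule: TransitionSchedule,
               max_cycles: int | None = None) -> MarkovTrace:
    """Evolve the cohort through the schedule, accruing discounted outcomes.

    Stops when the dead-state occupancy reaches 1 (to within 1e-9), the
    schedule is exhausted, or ``max_cycles`` is hit (used for truncated-
    horizon sensitivity analysis).
    """
    c = params.cohort
    if abs(schedule.start_age - c.start_age) > 1e-9:
        raise ParameterError("schedule was built for a different starting age")
    init = np.asarray(c.initial_distribution, dtype=float)
    if abs(init.sum() - 1.0) > 1e-9:
        raise ParameterError("initial distribution does not sum to 1")

    occ = np.concatenate([init, [0.0]])
    occupancy = [occ.copy()]
    ages, costs, qalys, dcosts, dqalys = [], [], [], [], []

    n = len(schedule.matrices)
    if max_cycles is not None:
        n = min(n, max_cycles)
    for k in range(1, n + 1):
        if occ[DEAD_INDEX] >= 1.0 - DEAD_TOL:
            break
        year_index = (k - 1) // c.cycles_per_year + 1
        t = (k - 1) * c.cycle_length_years
        matrix = schedule.matrices[k - 1]
        occ_end = occ @ matrix
        if c.half_cycle_correction:
            accrual_occ = 0.5 * (occ + occ_end)
        else:
            accrual_occ = occ
        cost = cycle_costs(params, schedule.strategy, accrual_occ, year_index)
        qaly = cycle_qalys(params.utilities, accrual_occ, c.cycle_length_years)
        disc = discount_factor(t, c.discount_rate)
        ages.append(schedule.ages[k - 1])
        costs.append(cost)
        qalys.append(qaly)
        dcosts.append(disc * cost)
        dqalys.append(disc * qaly)
        occ = occ_end
        occupancy.append(occ.copy())

    return MarkovTrace(strategy=schedule.strategy, lesion=schedule.lesion,
                       occupancy=np.array(occupancy), ages=np.array(ages),
                       cost_cycle=np.array(costs), qaly_cycle=np.array(qalys),
                       disc_cost_cycle=np.array(dcosts),
                       disc_qaly_cycle=np.array(dqalys))


def vision_years(trace: MarkovTrace, params: ParameterSet) -> float:
    """Undiscounted expected years with VA better than the configured cutoff.

    Counts cycle-start occupancy of the configured "seeing" states (default:
    better than 20/200) times the cycle length.
    """
    states = list(params.cohort.vision_states)
    n = len(trace.ages)
    return float(trace.occupancy[:n, states].sum()
                 * params.cohort.cycle_length_years)


def strategy_result(params: ParameterSet, strategy: Strategy, lesion: Lesion,
                    max_cycles: int | None = None) -> StrategyResult:
    """Build the schedule, run the cohort, and summarize lifetime totals."""
    schedule = build_schedule(params, strategy, lesion)
    trace = run_cohort(params, schedule, max_cycles=max_cycles)
    return StrategyResult(strategy=Strategy(strategy), lesion=Lesion(lesion),
                          cost=trace.total_cost, qalys=trace.total_qalys,
                          vision_years=vision_years(trace, params))
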