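"""From yearly trial outcomes to per-cycle transition matrices.

The trials report cumulative probabilities of vision change over one-year
periods; the model moves in 3-month cycles.  Under a constant-rate
(exponential) assumption within a period, the per-cycle probability of an
event with period probability P over ``m`` cycles is ``1 - (1 - P)**(1/m)``
(equivalently, via the rate form ``1 - exp(ln(1-P)/m)``).

Strategies never trialled head-to-head are compared indirectly: the
ranibizumab cumulative probabilities are the comparator's (PDT for
predominantly classic lesions, usual care otherwise) scaled by the published
risk ratios, and bevacizumab chains a second risk ratio onto the derived
ranibizumab probabilities.  Beyond the two trial years, every arm reverts to
the usual-care year-2 outcome probabilities until death; only age-specific
natural mortality changes from cycle to cycle thereafter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from amdcea.parameters import ParameterError, ParameterSet, VisionOutcomeProbs
from amdcea.states import DEAD_INDEX, N_STATES, N_VA_STATES, Lesion, Strategy

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class CycleOutcomeProbs:
    """Per-cycle (3-month) probabilities of the three vision outcomes."""

    q_gain: float
    q_loss_3_6: float
    q_loss_gt6: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.q_gain, self.q_loss_3_6, self.q_loss_gt6)


@dataclass
class TransitionSchedule:
    """Per-cycle 6x6 row-stochastic matrices for one (strategy, lesion) arm.

    ``matrices[k]`` governs the transition during cycle k+1; ``ages[k]`` is
    the cohort age at the start of that cycle.  The final matrix is fully
    absorbing (the cohort has reached the life table's terminal age).
    """

    strategy: Strategy
    lesion: Lesion
    start_age: float
    matrices: np.ndarray  # (n_cycles, 6, 6)
    ages: np.ndarray      # (n_cycles,)

    def __len__(self) -> int:
        return len(self.matrices)

    def to_frame(self):
        """Long-format audit table (cycle, from_state, to_state, probability)."""
        import pandas as pd
        n = len(self.matrices)
        cyc, frm, to = np.meshgrid(np.arange(1, n + 1), np.arange(N_STATES),
                                   np.arange(N_STATES), indexing="ij")
        return pd.DataFrame({"cycle": cyc.ravel(), "from_state": frm.ravel(),
                             "to_state": to.ravel(),
                             "probability": self.matrices.ravel()})


def annual_to_cycle_prob(p: float, cycles_in_period: int) -> float:
    """Per-cycle probability equivalent to cumulative probability ``p`` over a period.

    Constant-rate (exponential) assumption: compounding the result over
    ``cycles_in_period`` cycles recovers ``p`` exactly.
    """
    if p < 0.0:
        raise ParameterError(f"cumulative probability must be >= 0 (got {p})")
    if p >= 1.0:
        raise ParameterError("cumulative probability of 1 implies an infinite rate")
    if cycles_in_period < 1:
        raise ParameterError("cycles_in_period must be >= 1")
    return 1.0 - (1.0 - p) ** (1.0 / cycles_in_period)


def apply_risk_ratio(p: float, rr: float) -> float:
    """Scale a cumulative probability by a risk ratio, clamping at 1."""
    if rr < 0.0:
        raise ParameterError(f"risk ratio must be >= 0 (got {rr})")
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"probability out of [0,1] (got {p})")
    scaled = p * rr
    if scaled > 1.0:
        logger.warning("risk ratio %.4g on probability %.4g clamped to 1", rr, p)
        return 1.0
    return scaled


def derive_arm_outcomes(params: ParameterSet, strategy: Strategy,
                        lesion: Lesion, year: int) -> VisionOutcomeProbs:
    """Cumulative vision-outcome probabilities for any arm in a trial year.

    Usual care and PDT return the published values unchanged.  Ranibizumab
    scales its comparator's probabilities (PDT for predominantly classic,
    usual care otherwise) by the published risk ratios; bevacizumab scales
    the derived ranibizumab probabilities again.
    """
    strategy = Strategy(strategy)
    lesion = Lesion(lesion)
    if year not in (1, 2):
        raise ParameterError(f"trial outcomes cover years 1-2 only (got {year})")

    if strategy in (Strategy.USUAL_CARE, Strategy.PDT):
        return params.trial_outcomes[(strategy, lesion, year)]

    if lesion is Lesion.PREDOMINANTLY_CLASSIC:
        comparator, comparison = Strategy.PDT, "ranibizumab_vs_pdt"
    else:
        comparator, comparison = Strategy.USUAL_CARE, "ranibizumab_vs_usual_care"
    base = params.trial_outcomes[(comparator, lesion, year)]
    rr = params.rr(comparison, lesion, year)
    rani = VisionOutcomeProbs(
        p_gain=apply_risk_ratio(base.p_gain, rr.rr_gain),
        p_loss_3_6=apply_risk_ratio(base.p_loss_3_6, rr.rr_loss_3_6),
        p_loss_gt6=apply_risk_ratio(base.p_loss_gt6, rr.rr_loss_gt6))
    if strategy is Strategy.RANIBIZUMAB:
        return rani
    if strategy is Strategy.BEVACIZUMAB:
        rr2 = params.rr("bevacizumab_vs_ranibizumab", lesion, year)
        return VisionOutcomeProbs(
            p_gain=apply_risk_ratio(rani.p_gain, rr2.rr_gain),
            p_loss_3_6=apply_risk_ratio(rani.p_loss_3_6, rr2.rr_loss_3_6),
            p_loss_gt6=apply_risk_ratio(rani.p_loss_gt6, rr2.rr_loss_gt6))
    raise ParameterError(f"unknown strategy: {strategy}")


def to_cycle_outcomes(probs: VisionOutcomeProbs,
                      cycles_in_period: int) -> CycleOutcomeProbs:
    """Convert each competing annual outcome probability to its per-cycle value."""
    return CycleOutcomeProbs(
        q_gain=annual_to_cycle_prob(probs.p_gain, cycles_in_period),
        q_loss_3_6=annual_to_cycle_prob(probs.p_loss_3_6, cycles_in_period),
        q_loss_gt6=annual_to_cycle_prob(probs.p_loss_gt6, cycles_in_period))


def build_cycle_matrix(cycle_probs: CycleOutcomeProbs,
                       cycle_mortality: float) -> np.ndarray:
    """One 6x6 row-stochastic cycle matrix.

    Death is applied first to every living state; among survivors, a gain
    moves one VA band up, a 3-6 line loss one band down, a >6 line loss two
    bands down.  Moves past the best/worst band fold into the boundary band
    (total event probability is preserved, not renormalized).  Residual mass
    stays in place.  The death row is absorbing.
    """
    if not 0.0 <= cycle_mortality <= 1.0:
        raise ParameterError(f"cycle mortality out of [0,1] (got {cycle_mortality})")
    q_gain, q_l36, q_lgt6 = cycle_probs.as_tuple()
    for name, q in (("q_gain", q_gain), ("q_loss_3_6", q_l36), ("q_loss_gt6", q_lgt6)):
        if not 0.0 <= q <= 1.0:
            raise ParameterError(f"{name} out of [0,1] (got {q})")
    q_stay = 1.0 - q_gain - q_l36 - q_lgt6
    if q_stay < -ROW_SUM_TOL:
        raise ParameterError(
            f"survivor outcome probabilities sum to {q_gain + q_l36 + q_lgt6:.6g} > 1")
    q_stay = max(q_stay, 0.0)

    m = np.zeros((N_STATES, N_STATES))
    surv = 1.0 - cycle_mortality
    for i in range(N_VA_STATES):
        m[i, DEAD_INDEX] = cycle_mortality
        m[i, max(i - 1, 0)] += surv * q_gain
        m[i, min(i + 1, N_VA_STATES - 1)] += surv * q_l36
        m[i, min(i + 2, N_VA_STATES - 1)] += surv * q_lgt6
        m[i, i] += surv * q_stay
    m[DEAD_INDEX, DEAD_INDEX] = 1.0
    return m


def cycle_mortality_at(params: ParameterSet, age: float) -> float:
    """Per-cycle death probability from the annual life table at floor(age)."""
    q = params.life_table.annual_q(int(math.floor(age)))
    if q >= 1.0:
        return 1.0
    return annual_to_cycle_prob(q, params.cohort.cycles_per_year)


def build_schedule(params: ParameterSet, strategy: Strategy,
                   lesion: Lesion) -> TransitionSchedule:
    """The full lifetime sequence of cycle matrices for one arm.

    Trial year 1 outcomes govern the first year of cycles, trial year 2 the
    second; every later cycle uses the usual-care year-2 outcomes regardless
    of arm.  Mortality advances with cohort age each cycle; the schedule ends
    with the first cycle at the life table's terminal age, which is fully
    absorbing (q_x = 1).
    """
    strategy = Strategy(strategy)
    lesion = Lesion(lesion)
    c = params.cohort
    cpy = c.cycles_per_year
    if not (params.life_table.ages[0] <= c.start_age <= params.life_table.terminal_age):
        raise ParameterError("starting age outside life table; horizon exceeds table")

    cyc_y1 = to_cycle_outcomes(derive_arm_outcomes(params, strategy, lesion, 1), cpy)
    cyc_y2 = to_cycle_outcomes(derive_arm_outcomes(params, strategy, lesion, 2), cpy)
    cyc_ext = to_cycle_outcomes(
        derive_arm_outcomes(params, Strategy.USUAL_CARE, lesion, 2), cpy)

    matrices: list[np.ndarray] = []
    ages: list[float] = []
    terminal = params.life_table.terminal_age
    k = 1
    while True:
        age = c.start_age + (k - 1) * c.cycle_length_years
        if k <= cpy:
            outcomes = cyc_y1
        elif k <= 2 * cpy:
            outcomes = cyc_y2
        else:
            outcomes = cyc_ext
        mort = cycle_mortality_at(params, age)
        matrices.append(build_cycle_matrix(outcomes, mort))
        ages.append(age)
        if int(math.floor(age)) >= terminal:
            break
        k += 1

    return TransitionSchedule(strategy=strategy, lesion=lesion,
                              start_age=c.start_age,
                              matrices=np.array(matrices), ages=np.array(ages))


def export_schedule_csv(schedule: TransitionSchedule, path) -> None:
    """Write the audit-format schedule (cycle, from_state, to_state, probability)."""
    schedule.to_frame().to_csv(path, index=False)
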