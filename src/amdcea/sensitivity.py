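"""Sensitivity analyses: one-way (tornado), scenarios, PSA, and CEAC.

One-way analysis re-runs the full pipeline with a single input pinned to each
of its range bounds.  Scenario analysis varies the starting age and the
initial VA state.  The probabilistic sensitivity analysis is a second-order
Monte-Carlo: probabilities and utilities are drawn from beta distributions
and costs, frequencies, and risk ratios from lognormal distributions, all
parameterized by method of moments with SD equal to 20% of the base value
(shrunk where a valid beta requires it).  All four strategies share the same
draw, so incremental quantities are coherent.  Acceptability curves report,
at each willingness-to-pay value, the fraction of draws in which each
strategy has the maximal net monetary benefit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from amdcea import economics
from amdcea.engine import strategy_result
from amdcea.parameters import (
    OUTCOME_KEYS,
    UTILITY_KEYS,
    ComorbidityEntry,
    ParameterError,
    ParameterSet,
    RiskRatioSet,
    SAEEntry,
    UtilitySet,
    ValueRange,
    VisionOutcomeProbs,
)
from amdcea.states import ALL_STRATEGIES, Lesion, Strategy

logger = logging.getLogger(__name__)

DEFAULT_SD_FRACTION = 0.2


# ---------------------------------------------------------------------------
# Parameter resolution for one-way analysis


def _with_base(vr: ValueRange, value: float) -> ValueRange:
    return ValueRange(base=value, low=min(vr.low, value), high=max(vr.high, value))


def set_parameter(params: ParameterSet, parameter_id: str, value: float) -> ParameterSet:
    """A copy of ``params`` with one input pinned to ``value``.

    Dotted identifiers address the input tables, e.g.
    ``cohort.start_age``, ``utilities.va_better_20_40``,
    ``costs.unit.bevacizumab_dose``, ``costs.frequencies.injections_year1``,
    ``risk_ratios.bevacizumab_vs_ranibizumab.occult.year1.gain``,
    ``trial_outcomes.usual_care.occult.year1.loss_gt6``.

    Only the pinned value's own type bound is enforced here (probability or
    utility in [0,1], cost/frequency/risk ratio >= 0): one-way analysis
    legitimately explores values that break base-case-only conventions such
    as utility monotonicity across states.
    """
    parts = parameter_id.split(".")
    p = params.copy()

    if parts[0] == "cohort":
        if len(parts) != 2 or not hasattr(p.cohort, parts[1]):
            raise ParameterError(f"unknown cohort setting: {parameter_id}")
        if parts[1] == "start_age" and not (
                p.life_table.ages[0] <= value <= p.life_table.terminal_age):
            raise ParameterError("start_age outside life-table range")
        setattr(p.cohort, parts[1], float(value))
        return p

    if parts[0] == "utilities":
        if len(parts) != 2 or parts[1] not in UTILITY_KEYS:
            raise ParameterError(f"unknown utility: {parameter_id}")
        if not 0.0 <= value <= 1.0:
            raise ParameterError(f"{parameter_id}: utility out of [0,1]")
        idx = UTILITY_KEYS.index(parts[1])
        vals = list(p.utilities.values)
        vals[idx] = _with_base(vals[idx], value)
        p.utilities = UtilitySet(values=tuple(vals))
        return p

    if parts[0] == "costs":
        if value < 0:
            raise ParameterError(f"{parameter_id}: cost/frequency must be >= 0")
        if parts[1] == "unit" and parts[2] in p.costs.unit:
            p.costs.unit[parts[2]] = _with_base(p.costs.unit[parts[2]], value)
            return p
        if parts[1] == "frequencies" and parts[2] in p.costs.frequencies:
            p.costs.frequencies[parts[2]] = _with_base(
                p.costs.frequencies[parts[2]], value)
            return p
        if parts[1] == "fluorescein_angiography_annual_mean":
            p.costs.fluorescein_angiography_annual_mean = _with_base(
                p.costs.fluorescein_angiography_annual_mean, value)
            return p
        if parts[1] == "sae" and len(parts) == 5:
            arm, event, which = parts[2], parts[3], parts[4]
            entry = p.costs.sae[arm][event]
            if which == "annual_mean_cost":
                p.costs.sae[arm][event] = replace(
                    entry, annual_mean_cost=_with_base(entry.annual_mean_cost, value))
                return p
            if which == "annual_prob":
                if not 0.0 <= value <= 1.0:
                    raise ParameterError(f"{parameter_id}: probability out of [0,1]")
                p.costs.sae[arm][event] = replace(
                    entry, annual_prob=_with_base(entry.annual_prob, value))
                return p
        if parts[1] == "comorbidities" and len(parts) == 4:
            name, which = parts[2], parts[3]
            entry = p.costs.comorbidities[name]
            if which == "annual_mean_cost":
                p.costs.comorbidities[name] = replace(
                    entry, annual_mean_cost=_with_base(entry.annual_mean_cost, value))
                return p
        raise ParameterError(f"unknown cost input: {parameter_id}")

    if parts[0] == "risk_ratios" and len(parts) == 5:
        comparison, lesion, yearkey, outcome = parts[1], Lesion(parts[2]), parts[3], parts[4]
        if value < 0:
            raise ParameterError(f"{parameter_id}: risk ratio must be >= 0")
        year = int(yearkey.removeprefix("year"))
        rr = params.risk_ratios[comparison][lesion][year]
        kwargs = {f"rr_{k}": v for k, v in zip(OUTCOME_KEYS, rr.as_tuple())}
        kwargs[f"rr_{outcome}"] = float(value)
        p.risk_ratios[comparison][lesion][year] = RiskRatioSet(**kwargs)
        return p

    if parts[0] == "trial_outcomes" and len(parts) == 5:
        strategy, lesion = Strategy(parts[1]), Lesion(parts[2])
        year = int(parts[3].removeprefix("year"))
        outcome = parts[4]
        if not 0.0 <= value <= 1.0:
            raise ParameterError(f"{parameter_id}: probability out of [0,1]")
        probs = params.trial_outcomes[(strategy, lesion, year)]
        kwargs = {f"p_{k}": v for k, v in zip(OUTCOME_KEYS, probs.as_tuple())}
        kwargs[f"p_{outcome}"] = float(value)
        p.trial_outcomes[(strategy, lesion, year)] = VisionOutcomeProbs(**kwargs)
        return p

    raise ParameterError(f"cannot resolve parameter id: {parameter_id}")


# ---------------------------------------------------------------------------
# One-way (tornado) analysis


@dataclass(frozen=True)
class OneWayResult:
    parameter_id: str
    lesion: Lesion
    strategy: Strategy
    low: float
    high: float
    icer_low: float
    icer_high: float
    icer_base: float


def _icer_vs_usual_care(params: ParameterSet, lesion: Lesion, strategy: Strategy,
                        max_cycles: int | None = None) -> float:
    uc = strategy_result(params, Strategy.USUAL_CARE, lesion, max_cycles=max_cycles)
    active = strategy_result(params, strategy, lesion, max_cycles=max_cycles)
    return economics.icer(uc, active).value


def one_way(params: ParameterSet, parameter_id: str, low: float, high: float,
            lesion: Lesion, strategy: Strategy = Strategy.BEVACIZUMAB) -> OneWayResult:
    """Re-run the pipeline with one input at each bound; report ICER vs usual care.

    The special identifier ``horizon_years`` truncates the run instead of
    changing an input.
    """
    if low > high:
        raise ParameterError(f"{parameter_id}: low bound exceeds high bound")
    lesion, strategy = Lesion(lesion), Strategy(strategy)
    cpy = params.cohort.cycles_per_year

    if parameter_id == "horizon_years":
        icer_base = _icer_vs_usual_care(params, lesion, strategy)
        icer_lo = _icer_vs_usual_care(params, lesion, strategy,
                                      max_cycles=int(round(low * cpy)))
        icer_hi = _icer_vs_usual_care(params, lesion, strategy,
                                      max_cycles=int(round(high * cpy)))
    else:
        icer_base = _icer_vs_usual_care(params, lesion, strategy)
        icer_lo = _icer_vs_usual_care(set_parameter(params, parameter_id, low),
                                      lesion, strategy)
        icer_hi = _icer_vs_usual_care(set_parameter(params, parameter_id, high),
                                      lesion, strategy)
    return OneWayResult(parameter_id=parameter_id, lesion=lesion, strategy=strategy,
                        low=low, high=high, icer_low=icer_lo, icer_high=icer_hi,
                        icer_base=icer_base)


def default_tornado_spec(params: ParameterSet, lesion: Lesion) -> list[tuple[str, float, float]]:
    """The standard one-way list: age, bevacizumab-vs-ranibizumab risk ratios
    (+/-20% per year and outcome), utilities over their published ranges,
    bevacizumab and injection unit costs, injection frequencies, and the
    time horizon (2 and 10 years)."""
    lesion = Lesion(lesion)
    spec: list[tuple[str, float, float]] = [("cohort.start_age", 55.0, 88.0)]
    for year in (1, 2):
        rr = params.risk_ratios["bevacizumab_vs_ranibizumab"][lesion][year]
        for key, base in zip(OUTCOME_KEYS, rr.as_tuple()):
            pid = f"risk_ratios.bevacizumab_vs_ranibizumab.{lesion.value}.year{year}.{key}"
            spec.append((pid, 0.8 * base, 1.2 * base))
    for key, vr in zip(UTILITY_KEYS, params.utilities.values):
        spec.append((f"utilities.{key}", vr.low, vr.high))
    for name in ("bevacizumab_dose", "intravitreal_injection"):
        vr = params.costs.unit[name]
        spec.append((f"costs.unit.{name}", vr.low, vr.high))
    for name in ("injections_year1", "injections_year2"):
        vr = params.costs.frequencies[name]
        spec.append((f"costs.frequencies.{name}", vr.low, vr.high))
    spec.append(("horizon_years", 2.0, 10.0))
    return spec


def tornado(params: ParameterSet, lesion: Lesion,
            spec: list[tuple[str, float, float]] | None = None,
            strategy: Strategy = Strategy.BEVACIZUMAB) -> list[OneWayResult]:
    """One-way results for every entry of the tornado specification."""
    if spec is None:
        spec = default_tornado_spec(params, lesion)
    return [one_way(params, pid, lo, hi, lesion, strategy) for pid, lo, hi in spec]


def tornado_frame(results: list[OneWayResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": r.parameter_id, "lesion": r.lesion.value, "low": r.low,
        "high": r.high, "icer_low": r.icer_low, "icer_high": r.icer_high,
        "icer_base": r.icer_base} for r in results])


# ---------------------------------------------------------------------------
# Scenario analysis: initial VA state and starting age


def scenario_initial_state(params: ParameterSet, lesion: Lesion,
                           state: int | None = None,
                           age: float | None = None) -> dict[Strategy, float]:
    """ICER vs usual care per active strategy under a modified starting cohort.

    ``state`` (0-4) makes the initial distribution degenerate at one VA band;
    ``age`` overrides the starting age; either may be omitted to keep the
    base case.
    """
    lesion = Lesion(lesion)
    p = params.copy()
    if state is not None:
        if not 0 <= state <= 4:
            raise ParameterError(f"initial state must be a VA state 0-4 (got {state})")
        dist = np.zeros(5)
        dist[state] = 1.0
        p.cohort.initial_distribution = dist
    if age is not None:
        p = set_parameter(p, "cohort.start_age", age)
    uc = strategy_result(p, Strategy.USUAL_CARE, lesion)
    out: dict[Strategy, float] = {}
    for s in (Strategy.PDT, Strategy.RANIBIZUMAB, Strategy.BEVACIZUMAB):
        out[s] = economics.icer(uc, strategy_result(p, s, lesion)).value
    return out


# ---------------------------------------------------------------------------
# PSA sampling


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if mean <= 0 or sd <= 0:
        return mean
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _beta(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0 or mean <= 0.0 or mean >= 1.0:
        return mean
    cap = 0.97 * math.sqrt(mean * (1.0 - mean))
    sd = min(sd, cap)
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:  # pragma: no cover - cap prevents this
        return mean
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def sample_psa_parameters(params: ParameterSet, n: int, seed: int,
                          sd_fraction: float = DEFAULT_SD_FRACTION) -> list[ParameterSet]:
    """``n`` parameter-set draws for the PSA.

    Probabilities and utilities ~ beta, costs / frequencies / risk ratios
    ~ lognormal, all by method of moments with SD = ``sd_fraction`` x base.
    With ``sd_fraction=0`` every draw equals the base case exactly.  Draws
    whose competing outcome probabilities sum above 1 are regenerated (the
    count is logged).  Utility ordering across VA states is not enforced;
    violations are logged.
    """
    if n < 1:
        raise ParameterError(f"need at least one draw (got {n})")
    rng = np.random.default_rng(seed)
    draws: list[ParameterSet] = []
    n_regenerated = 0
    n_disordered = 0

    for _ in range(n):
        p = params.copy()

        for key, probs in params.trial_outcomes.items():
            for _attempt in range(100):
                vals = [_beta(rng, v, sd_fraction * v) for v in probs.as_tuple()]
                if sum(vals) <= 1.0:
                    break
                n_regenerated += 1
            else:  # pragma: no cover - fallback after persistent failure
                vals = list(probs.as_tuple())
            p.trial_outcomes[key] = VisionOutcomeProbs(*vals)

        for comparison, by_lesion in params.risk_ratios.items():
            year_invariant = comparison == "bevacizumab_vs_ranibizumab"
            if year_invariant:
                # one draw shared across lesions and years, as in the base case
                rr0 = next(iter(next(iter(by_lesion.values())).values()))
                shared = RiskRatioSet(*[_lognormal(rng, v, sd_fraction * v)
                                        for v in rr0.as_tuple()])
                for lesion in by_lesion:
                    for year in by_lesion[lesion]:
                        p.risk_ratios[comparison][lesion][year] = shared
            else:
                for lesion, by_year in by_lesion.items():
                    for year, rr in by_year.items():
                        p.risk_ratios[comparison][lesion][year] = RiskRatioSet(
                            *[_lognormal(rng, v, sd_fraction * v) for v in rr.as_tuple()])

        for name, vr in params.costs.unit.items():
            p.costs.unit[name] = replace(
                vr, base=_lognormal(rng, vr.base, sd_fraction * vr.base))
        for name, vr in params.costs.frequencies.items():
            p.costs.frequencies[name] = replace(
                vr, base=_lognormal(rng, vr.base, sd_fraction * vr.base))
        fa = params.costs.fluorescein_angiography_annual_mean
        p.costs.fluorescein_angiography_annual_mean = replace(
            fa, base=_lognormal(rng, fa.base, sd_fraction * fa.base))
        for arm, events in params.costs.sae.items():
            for name, e in events.items():
                p.costs.sae[arm][name] = SAEEntry(
                    annual_prob=replace(e.annual_prob, base=_beta(
                        rng, e.annual_prob.base, sd_fraction * e.annual_prob.base)),
                    annual_mean_cost=replace(e.annual_mean_cost, base=_lognormal(
                        rng, e.annual_mean_cost.base,
                        sd_fraction * e.annual_mean_cost.base)))
        for name, e in params.costs.comorbidities.items():
            p.costs.comorbidities[name] = ComorbidityEntry(
                unit_cost=e.unit_cost,
                annual_prob=replace(e.annual_prob, base=_beta(
                    rng, e.annual_prob.base, sd_fraction * e.annual_prob.base)),
                annual_mean_cost=replace(e.annual_mean_cost, base=_lognormal(
                    rng, e.annual_mean_cost.base,
                    sd_fraction * e.annual_mean_cost.base)))

        utils = [_beta(rng, vr.base, sd_fraction * vr.base)
                 for vr in params.utilities.values]
        if any(a < b for a, b in zip(utils, utils[1:])):
            n_disordered += 1
        p.utilities = UtilitySet(values=tuple(
            replace(vr, base=u) for vr, u in zip(params.utilities.values, utils)))

        draws.append(p)

    if n_regenerated:
        logger.info("PSA: regenerated %d outcome triples whose sum exceeded 1",
                    n_regenerated)
    if n_disordered:
        logger.info("PSA: %d/%d draws had non-monotone utilities across VA states "
                    "(left uncorrected)", n_disordered, n)
    return draws


# ---------------------------------------------------------------------------
# PSA execution, CE plane, CEAC


@dataclass
class PSAResult:
    """Per-draw costs and QALYs for each strategy under common draws."""

    lesion: Lesion
    strategies: tuple[Strategy, ...]
    costs: np.ndarray   # (n_draws, n_strategies)
    qalys: np.ndarray   # (n_draws, n_strategies)
    seed: int

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def column(self, strategy: Strategy) -> int:
        return self.strategies.index(Strategy(strategy))

    def ce_plane(self, reference: Strategy = Strategy.USUAL_CARE) -> pd.DataFrame:
        """Incremental cost and QALYs of every strategy vs the reference, per draw."""
        ref = self.column(reference)
        rows = []
        for j, s in enumerate(self.strategies):
            if j == ref:
                continue
            rows.append(pd.DataFrame({
                "draw": np.arange(self.n_draws), "strategy": s.value,
                "d_cost": self.costs[:, j] - self.costs[:, ref],
                "d_qaly": self.qalys[:, j] - self.qalys[:, ref]}))
        return pd.concat(rows, ignore_index=True)

    def prob_cost_effective_pairwise(self, strategy: Strategy, wtp: float,
                                     reference: Strategy = Strategy.USUAL_CARE) -> float:
        """Fraction of draws in which ``strategy`` beats the reference on NMB at ``wtp``
        (equivalently: ICER below ``wtp`` or outright dominance)."""
        j, ref = self.column(strategy), self.column(reference)
        nmb_j = wtp * self.qalys[:, j] - self.costs[:, j]
        nmb_r = wtp * self.qalys[:, ref] - self.costs[:, ref]
        return float(np.mean(nmb_j > nmb_r))


def run_psa(params: ParameterSet, lesion: Lesion, n: int = 1000,
            seed: int | None = None,
            sd_fraction: float = DEFAULT_SD_FRACTION) -> PSAResult:
    """Second-order Monte-Carlo: rebuild and run all strategies per draw.

    Every strategy within a draw sees the same sampled parameters, so
    incremental costs and QALYs are internally consistent.
    """
    lesion = Lesion(lesion)
    if seed is None:
        seed = params.cohort.seed
    draws = sample_psa_parameters(params, n, seed, sd_fraction)
    strategies = ALL_STRATEGIES
    costs = np.empty((n, len(strategies)))
    qalys = np.empty((n, len(strategies)))
    for i, p in enumerate(draws):
        for j, s in enumerate(strategies):
            res = strategy_result(p, s, lesion)
            costs[i, j] = res.cost
            qalys[i, j] = res.qalys
    return PSAResult(lesion=lesion, strategies=strategies, costs=costs,
                     qalys=qalys, seed=seed)


@dataclass
class CEACCurve:
    """Probability each strategy is optimal (max NMB) along a WTP grid."""

    wtp: np.ndarray                     # (n_wtp,)
    strategies: tuple[Strategy, ...]
    probability: np.ndarray             # (n_wtp, n_strategies), rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, s in enumerate(self.strategies):
            rows.append(pd.DataFrame({"wtp": self.wtp, "strategy": s.value,
                                      "probability": self.probability[:, j]}))
        return pd.concat(rows, ignore_index=True)


def compute_ceac(psa: PSAResult, wtp_grid: np.ndarray,
                 pairwise_reference: Strategy | None = None) -> CEACCurve:
    """Acceptability curves over a WTP grid.

    Default convention: at each WTP the winning strategy of a draw is the one
    with maximal net monetary benefit (ties broken toward the cheaper
    strategy), so probabilities sum to 1 across strategies.  With
    ``pairwise_reference`` given, each curve is instead the probability of
    beating that reference strategy head-to-head.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ParameterError("empty willingness-to-pay grid")
    n, m = psa.costs.shape
    prob = np.empty((wtp_grid.size, m))
    # NMB ties (measure zero under continuous draws) break toward the
    # first-listed strategy via argmax.
    for i, w in enumerate(wtp_grid):
        nmb = w * psa.qalys - psa.costs
        if pairwise_reference is not None:
            ref = psa.column(pairwise_reference)
            prob[i] = np.mean(nmb > nmb[:, [ref]], axis=0)
            prob[i, ref] = np.mean(np.all(nmb <= nmb[:, [ref]], axis=1))
        else:
            winners = np.argmax(nmb, axis=1)
            prob[i] = np.bincount(winners, minlength=m) / n
    return CEACCurve(wtp=wtp_grid, strategies=psa.strategies, probability=prob)
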