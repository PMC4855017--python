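"""Synthetic stand-ins for unpublished inputs, plus a microsimulation oracle.

Two model inputs are not published as numbers: the national 2011 period life
table and the initial visual-acuity distribution of newly diagnosed patients.
This module generates plausible substitutes — a Gompertz-Makeham life table
calibrated to a stated residual life expectancy, and configurable initial
state vectors — and provides randomized-but-valid parameter sets for
property-based testing, together with a first-order Monte-Carlo
microsimulation that serves as an independent oracle for the cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_MAKEHAM = 5.0e-4
DEFAULT_GOMPERTZ_A = 2.1263e-5
DEFAULT_GOMPERTZ_B = 0.10


@dataclass(frozen=True)
class GompertzMakehamSpec:
    """Parameters of the synthetic annual mortality hazard.

    The hazard at age x is ``makeham + gompertz_a * exp(gompertz_b * x)``;
    annual probability q_x = 1 - exp(-hazard).  Defaults are calibrated so
    that cohort life expectancy at age 73.6 is about 12 years, a plausible
    figure for the Chinese population around 2011.
    """

    makeham: float = DEFAULT_MAKEHAM
    gompertz_a: float = DEFAULT_GOMPERTZ_A
    gompertz_b: float = DEFAULT_GOMPERTZ_B
    start_age: int = 40
    terminal_age: int = 105


def generate_life_table(spec: GompertzMakehamSpec):
    """Annual q_x per age from the Gompertz-Makeham hazard; terminal age absorbing."""
    from amdcea.parameters import LifeTable, ParameterError

    if spec.makeham < 0 or spec.gompertz_a < 0 or spec.gompertz_b < 0:
        raise ParameterError("Gompertz-Makeham parameters must be non-negative")
    if spec.terminal_age <= spec.start_age:
        raise ParameterError("terminal age must exceed start age")
    ages = np.arange(spec.start_age, spec.terminal_age + 1)
    hazard = spec.makeham + spec.gompertz_a * np.exp(spec.gompertz_b * ages)
    qx = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


# ---------------------------------------------------------------------------
# Randomized valid parameter sets


def _jitter_outcomes(rng: np.random.Generator, scale: float = 0.8) -> dict:
    # Three mutually exclusive outcome probabilities with headroom below 1.
    raw = rng.dirichlet(np.ones(4))  # 4th component is "no change"
    return {"gain": float(raw[0] * scale), "loss_3_6": float(raw[1] * scale),
            "loss_gt6": float(raw[2] * scale)}


def _jitter_rr(rng: np.random.Generator, comparator: dict) -> dict:
    """Risk ratios backed out from a directly drawn treated-arm outcome set.

    Drawing the treated arm's probabilities (sum < 0.8) and dividing by the
    comparator's guarantees the risk-ratio products stay strictly below 1
    even after the bevacizumab chain (factor <= 1.2), so every generated set
    yields representable per-cycle rates.
    """
    treated = _jitter_outcomes(rng, scale=0.8)
    return {k: treated[k] / comparator[k] for k in ("gain", "loss_3_6", "loss_gt6")}


def generate_parameter_set(seed: int):
    """A random but always-valid ParameterSet for property-based testing.

    Vision-outcome probabilities are drawn from a Dirichlet (so the three
    competing outcomes never exceed total probability 1), risk ratios
    uniformly over plausible magnitudes, costs lognormally around the base
    case, and utilities as a sorted decreasing sequence in (0, 1).
    """
    from amdcea._defaults import default_config
    from amdcea.parameters import parameter_set_from_config

    rng = np.random.default_rng(seed)
    cfg = default_config()

    for arm in ("usual_care", "pdt"):
        for lesion in cfg["trial_outcomes"][arm]:
            for year in ("year1", "year2"):
                cfg["trial_outcomes"][arm][lesion][year] = _jitter_outcomes(rng)

    rrs = cfg["risk_ratios"]
    for year in ("year1", "year2"):
        rrs["ranibizumab_vs_pdt"]["predominantly_classic"][year] = _jitter_rr(
            rng, cfg["trial_outcomes"]["pdt"]["predominantly_classic"][year])
    for lesion in ("minimally_classic", "occult"):
        for year in ("year1", "year2"):
            rrs["ranibizumab_vs_usual_care"][lesion][year] = _jitter_rr(
                rng, cfg["trial_outcomes"]["usual_care"][lesion][year])
    rrs["bevacizumab_vs_ranibizumab"]["all_lesions"] = {
        "gain": float(rng.uniform(0.5, 1.2)),
        "loss_3_6": float(rng.uniform(0.5, 1.2)),
        "loss_gt6": float(rng.uniform(0.5, 1.2))}

    for name, entry in cfg["costs"]["unit"].items():
        base = entry["base"] * float(rng.lognormal(0.0, 0.15))
        cfg["costs"]["unit"][name] = {"base": base, "low": 0.8 * base, "high": 1.2 * base}

    utils = np.sort(rng.uniform(0.05, 0.99, size=5))[::-1]
    for key, u in zip(("va_better_20_40", "va_20_40_to_20_80", "va_20_80_to_20_200",
                       "va_20_200_to_20_400", "va_20_400_or_worse"), utils):
        cfg["utilities"][key] = {"base": float(u), "low": float(max(0.0, u - 0.05)),
                                 "high": float(min(1.0, u + 0.05))}

    init = rng.dirichlet(np.ones(5))
    cfg["cohort"]["initial_distribution"] = [float(x) for x in init]
    cfg["cohort"]["start_age"] = float(rng.uniform(55.0, 90.0))
    cfg["cohort"]["discount_rate"] = float(rng.uniform(0.0, 0.05))
    return parameter_set_from_config(cfg)


# ---------------------------------------------------------------------------
# Microsimulation oracle


@dataclass
class MicrosimResult:
    """Monte-Carlo estimate of lifetime totals with standard errors."""

    total_cost: float
    total_qalys: float
    vision_years: float
    se_cost: float
    se_qalys: float
    n_individuals: int


def microsim_oracle(schedule, params, n_individuals: int, seed: int) -> MicrosimResult:
    """First-order Monte-Carlo re-implementation of the cohort simulation.

    Individuals are walked through the same per-cycle transition matrices by
    categorical sampling; per-cycle cost and QALY accrual reuses the engine's
    own per-state accrual (evaluated on one-hot occupancies), so any
    discrepancy with the cohort result isolates an error in the cohort
    occupancy evolution itself.
    """
    from amdcea.engine import cycle_costs, cycle_qalys, discount_factor
    from amdcea.states import DEAD_INDEX, N_STATES

    rng = np.random.default_rng(seed)
    c = params.cohort
    init = np.concatenate([c.initial_distribution, [0.0]])
    states = rng.choice(N_STATES, size=n_individuals, p=init / init.sum())

    cost = np.zeros(n_individuals)
    qaly = np.zeros(n_individuals)
    vyears = np.zeros(n_individuals)
    vision_states = np.array(c.vision_states)

    # Per-state accrual vectors from the engine (one-hot occupancies).
    eye = np.eye(N_STATES)

    for k, matrix in enumerate(schedule.matrices, start=1):
        if np.all(states == DEAD_INDEX):
            break
        year_index = (k - 1) // c.cycles_per_year + 1
        t = (k - 1) * c.cycle_length_years
        disc = discount_factor(t, c.discount_rate)
        cost_by_state = np.array([
            cycle_costs(params, schedule.strategy, eye[s], year_index)
            for s in range(N_STATES)])
        qaly_by_state = np.array([
            cycle_qalys(params.utilities, eye[s], c.cycle_length_years)
            for s in range(N_STATES)])
        cost += disc * cost_by_state[states]
        qaly += disc * qaly_by_state[states]
        vyears += np.isin(states, vision_states) * c.cycle_length_years

        # Categorical transition via inverse-CDF per current state (vectorized).
        cdf = np.cumsum(matrix, axis=1)
        u = rng.random(n_individuals)
        nxt = np.empty(n_individuals, dtype=int)
        for s in range(N_STATES):
            mask = states == s
            if mask.any():
                nxt[mask] = np.searchsorted(cdf[s], u[mask], side="right")
        states = np.minimum(nxt, N_STATES - 1)

    def _se(x: np.ndarray) -> float:
        if n_individuals < 2:
            return 0.0
        return float(x.std(ddof=1) / np.sqrt(n_individuals))

    return MicrosimResult(
        total_cost=float(cost.mean()),
        total_qalys=float(qaly.mean()),
        vision_years=float(vyears.mean()),
        se_cost=_se(cost),
        se_qalys=_se(qaly),
        n_individuals=n_individuals)
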