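"""Model inputs: typed containers, config loading, and validation.

A :class:`ParameterSet` bundles everything the pipeline consumes: yearly
cumulative vision-outcome probabilities for the trial-observed arms (usual
care and PDT), risk ratios for the indirect comparison, unit costs and
resource frequencies, per-state utilities, an annual life table, and cohort
run settings.  The base case is fully specified by the packaged defaults
(:func:`default_parameter_set`), so the pipeline runs with zero user input;
:func:`load_parameters` reads the same schema from a YAML document.
"""

from __future__ import annotations

import copy
import math
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from amdcea._defaults import default_config
from amdcea.states import (
    N_VA_STATES,
    Lesion,
    Strategy,
)

UTILITY_KEYS = (
    "va_better_20_40",
    "va_20_40_to_20_80",
    "va_20_80_to_20_200",
    "va_20_200_to_20_400",
    "va_20_400_or_worse",
)

OUTCOME_KEYS = ("gain", "loss_3_6", "loss_gt6")


class ParameterError(ValueError):
    """Raised when a configuration is incomplete or violates an invariant."""


@dataclass(frozen=True)
class ValueRange:
    """A base-case value with its low/high sensitivity bounds."""

    base: float
    low: float
    high: float

    @classmethod
    def from_mapping(cls, m: Any, where: str) -> "ValueRange":
        if isinstance(m, (int, float)):
            b = float(m)
            return cls(b, 0.8 * b, 1.2 * b)
        try:
            base = float(m["base"])
        except (KeyError, TypeError) as exc:
            raise ParameterError(f"{where}: missing 'base' value") from exc
        low = float(m.get("low", 0.8 * base))
        high = float(m.get("high", 1.2 * base))
        return cls(base, low, high)

    def to_mapping(self) -> dict:
        return {"base": self.base, "low": self.low, "high": self.high}


@dataclass(frozen=True)
class VisionOutcomeProbs:
    """Cumulative probabilities of vision change over one trial year.

    ``p_gain``: gain of >3 lines; ``p_loss_3_6``: loss of 3-6 lines;
    ``p_loss_gt6``: loss of >6 lines.  Mutually exclusive outcomes.
    """

    p_gain: float
    p_loss_3_6: float
    p_loss_gt6: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_gain, self.p_loss_3_6, self.p_loss_gt6)


@dataclass(frozen=True)
class RiskRatioSet:
    """Risk ratios applied multiplicatively to cumulative probabilities."""

    rr_gain: float
    rr_loss_3_6: float
    rr_loss_gt6: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rr_gain, self.rr_loss_3_6, self.rr_loss_gt6)


@dataclass(frozen=True)
class SAEEntry:
    """One serious adverse event: annual probability and annual mean cost."""

    annual_prob: ValueRange
    annual_mean_cost: ValueRange


@dataclass(frozen=True)
class ComorbidityEntry:
    """One low-vision comorbidity (depression, fall, assisted living)."""

    unit_cost: ValueRange
    annual_prob: ValueRange
    annual_mean_cost: ValueRange


@dataclass
class CostInputs:
    """Unit costs (2012 US$), resource frequencies, SAE and comorbidity inputs."""

    unit: dict[str, ValueRange]
    frequencies: dict[str, ValueRange]
    fluorescein_angiography_annual_mean: ValueRange
    sae: dict[str, dict[str, SAEEntry]]            # arm -> event -> entry
    comorbidities: dict[str, ComorbidityEntry]

    def sae_annual_cost(self, strategy: Strategy) -> float:
        entries = self.sae.get(strategy.value, {})
        return sum(e.annual_mean_cost.base for e in entries.values())

    def comorbidity_annual_cost(self) -> float:
        return sum(e.annual_mean_cost.base for e in self.comorbidities.values())


@dataclass
class UtilitySet:
    """Utility weight per VA band; the death state contributes zero."""

    values: tuple[ValueRange, ...]  # length 5, best -> worst

    def utility(self, state: int) -> float:
        if state >= N_VA_STATES:
            return 0.0
        return self.values[state].base

    def as_array(self) -> np.ndarray:
        """Length-6 utility vector (death appended as 0)."""
        return np.array([v.base for v in self.values] + [0.0])


@dataclass
class LifeTable:
    """Annual mortality probability q_x by integer age, contiguous ages."""

    ages: np.ndarray
    qx: np.ndarray

    def annual_q(self, age: int) -> float:
        idx = age - int(self.ages[0])
        if idx < 0 or idx >= len(self.ages):
            raise ParameterError(f"age {age} outside life table range "
                                 f"[{self.ages[0]}, {self.ages[-1]}]")
        return float(self.qx[idx])

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])


@dataclass
class CohortSpec:
    """Cohort and run settings."""

    start_age: float = 73.6
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.full(N_VA_STATES, 1.0 / N_VA_STATES))
    cycle_length_years: float = 0.25
    discount_rate: float = 0.03
    wtp: float = 7480.0
    gdp_per_capita: float = 7480.0
    vision_states: tuple[int, ...] = (0, 1, 2)
    comorbidity_states: tuple[int, ...] = (2, 3, 4)
    sae_years: tuple[int, ...] = (1, 2)
    half_cycle_correction: bool = False
    wtp_grid_max: float = 30000.0
    wtp_grid_step: float = 250.0
    seed: int = 0

    @property
    def cycles_per_year(self) -> int:
        return round(1.0 / self.cycle_length_years)

    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_grid_max + self.wtp_grid_step,
                         self.wtp_grid_step)


@dataclass
class ParameterSet:
    """Validated bundle of every model input."""

    # (strategy, lesion, year) -> VisionOutcomeProbs for trial-observed arms
    trial_outcomes: dict[tuple[Strategy, Lesion, int], VisionOutcomeProbs]
    # comparison name -> lesion -> year -> RiskRatioSet
    risk_ratios: dict[str, dict[Lesion, dict[int, RiskRatioSet]]]
    costs: CostInputs
    utilities: UtilitySet
    life_table: LifeTable
    cohort: CohortSpec

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def rr(self, comparison: str, lesion: Lesion, year: int) -> RiskRatioSet:
        try:
            return self.risk_ratios[comparison][lesion][year]
        except KeyError as exc:
            raise ParameterError(
                f"no risk ratio for {comparison}/{lesion.value}/year {year}") from exc


# ---------------------------------------------------------------------------
# Construction from config mappings


def _require(mapping: Any, key: str, where: str) -> Any:
    if not isinstance(mapping, dict) or key not in mapping:
        raise ParameterError(f"missing required entry '{key}' in {where}")
    return mapping[key]


def _parse_outcomes(m: Any, where: str) -> VisionOutcomeProbs:
    vals = []
    for k in OUTCOME_KEYS:
        v = float(_require(m, k, where))
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{where}/{k}: probability out of [0,1] (got {v})")
        vals.append(v)
    if sum(vals) > 1.0 + 1e-12:
        raise ParameterError(f"{where}: outcome probabilities exceed 1 (sum {sum(vals):.4f})")
    return VisionOutcomeProbs(*vals)


def _parse_rr(m: Any, where: str) -> RiskRatioSet:
    vals = []
    for k in OUTCOME_KEYS:
        v = float(_require(m, k, where))
        if v < 0:
            raise ParameterError(f"{where}/{k}: risk ratio must be >= 0 (got {v})")
        vals.append(v)
    return RiskRatioSet(*vals)


def _parse_trial_outcomes(cfg: dict) -> dict:
    out = {}
    section = _require(cfg, "trial_outcomes", "config")
    for arm, strategy in (("usual_care", Strategy.USUAL_CARE), ("pdt", Strategy.PDT)):
        arm_cfg = _require(section, arm, "trial_outcomes")
        for lesion in Lesion:
            lcfg = _require(arm_cfg, lesion.value, f"trial_outcomes/{arm}")
            for year in (1, 2):
                where = f"trial_outcomes/{arm}/{lesion.value}/year{year}"
                out[(strategy, lesion, year)] = _parse_outcomes(
                    _require(lcfg, f"year{year}", f"trial_outcomes/{arm}/{lesion.value}"),
                    where)
    return out


def _parse_risk_ratios(cfg: dict) -> dict:
    section = _require(cfg, "risk_ratios", "config")
    out: dict[str, dict[Lesion, dict[int, RiskRatioSet]]] = {}

    rvp = _require(section, "ranibizumab_vs_pdt", "risk_ratios")
    pc = _require(rvp, Lesion.PREDOMINANTLY_CLASSIC.value, "risk_ratios/ranibizumab_vs_pdt")
    out["ranibizumab_vs_pdt"] = {Lesion.PREDOMINANTLY_CLASSIC: {
        y: _parse_rr(_require(pc, f"year{y}", "ranibizumab_vs_pdt"),
                     f"risk_ratios/ranibizumab_vs_pdt/year{y}")
        for y in (1, 2)}}

    rvu = _require(section, "ranibizumab_vs_usual_care", "risk_ratios")
    out["ranibizumab_vs_usual_care"] = {}
    for lesion in (Lesion.MINIMALLY_CLASSIC, Lesion.OCCULT):
        lcfg = _require(rvu, lesion.value, "risk_ratios/ranibizumab_vs_usual_care")
        out["ranibizumab_vs_usual_care"][lesion] = {
            y: _parse_rr(_require(lcfg, f"year{y}", lesion.value),
                         f"risk_ratios/ranibizumab_vs_usual_care/{lesion.value}/year{y}")
            for y in (1, 2)}

    bvr = _require(section, "bevacizumab_vs_ranibizumab", "risk_ratios")
    shared = _parse_rr(_require(bvr, "all_lesions", "risk_ratios/bevacizumab_vs_ranibizumab"),
                       "risk_ratios/bevacizumab_vs_ranibizumab")
    # Year-invariant by construction: the same set is installed for both years.
    out["bevacizumab_vs_ranibizumab"] = {
        lesion: {1: shared, 2: shared} for lesion in Lesion}
    return out


def _parse_costs(cfg: dict) -> CostInputs:
    section = _require(cfg, "costs", "config")
    unit_cfg = _require(section, "unit", "costs")
    unit = {k: ValueRange.from_mapping(_require(unit_cfg, k, "costs/unit"), f"costs/unit/{k}")
            for k in ("consultation", "oct", "fluorescein_angiography", "verteporfin",
                      "laser_activation", "intravitreal_injection",
                      "ranibizumab_dose", "bevacizumab_dose")}
    freq_cfg = _require(section, "frequencies", "costs")
    frequencies = {k: ValueRange.from_mapping(_require(freq_cfg, k, "costs/frequencies"),
                                              f"costs/frequencies/{k}")
                   for k in ("consultation_per_year", "oct_per_year", "pdt_year1",
                             "pdt_year2", "injections_year1", "injections_year2")}
    fa = ValueRange.from_mapping(
        _require(section, "fluorescein_angiography_annual_mean", "costs"),
        "costs/fluorescein_angiography_annual_mean")

    sae: dict[str, dict[str, SAEEntry]] = {}
    for arm, events in _require(section, "sae", "costs").items():
        sae[arm] = {}
        for name, e in events.items():
            where = f"costs/sae/{arm}/{name}"
            sae[arm][name] = SAEEntry(
                annual_prob=ValueRange.from_mapping(_require(e, "annual_prob", where),
                                                    f"{where}/annual_prob"),
                annual_mean_cost=ValueRange.from_mapping(
                    _require(e, "annual_mean_cost", where), f"{where}/annual_mean_cost"))

    comorb: dict[str, ComorbidityEntry] = {}
    for name, e in _require(section, "comorbidities", "costs").items():
        where = f"costs/comorbidities/{name}"
        comorb[name] = ComorbidityEntry(
            unit_cost=ValueRange.from_mapping(_require(e, "unit_cost", where),
                                              f"{where}/unit_cost"),
            annual_prob=ValueRange.from_mapping(_require(e, "annual_prob", where),
                                                f"{where}/annual_prob"),
            annual_mean_cost=ValueRange.from_mapping(
                _require(e, "annual_mean_cost", where), f"{where}/annual_mean_cost"))

    return CostInputs(unit=unit, frequencies=frequencies,
                      fluorescein_angiography_annual_mean=fa,
                      sae=sae, comorbidities=comorb)


def _parse_utilities(cfg: dict) -> UtilitySet:
    section = _require(cfg, "utilities", "config")
    vals = []
    for k in UTILITY_KEYS:
        vr = ValueRange.from_mapping(_require(section, k, "utilities"), f"utilities/{k}")
        if not 0.0 <= vr.base <= 1.0:
            raise ParameterError(f"utilities/{k}: utility out of [0,1] (got {vr.base})")
        vals.append(vr)
    return UtilitySet(values=tuple(vals))


def _parse_life_table(cfg: dict, base_dir: str | None) -> LifeTable:
    section = _require(cfg, "life_table", "config")
    if "csv" in section:
        path = section["csv"]
        if base_dir is not None and not os.path.isabs(path):
            path = os.path.join(base_dir, path)
        return read_life_table(path)
    if "synthetic" in section:
        from amdcea.synthetic import GompertzMakehamSpec, generate_life_table
        s = section["synthetic"]
        spec = GompertzMakehamSpec(
            makeham=float(s.get("makeham", 5.0e-4)),
            gompertz_a=float(s.get("gompertz_a", 2.1263e-5)),
            gompertz_b=float(s.get("gompertz_b", 0.10)),
            start_age=int(s.get("start_age", 40)),
            terminal_age=int(s.get("terminal_age", 105)))
        return generate_life_table(spec)
    raise ParameterError("life_table: supply either 'csv' (path) or 'synthetic' (spec)")


def _parse_cohort(cfg: dict) -> CohortSpec:
    section = cfg.get("cohort", {}) or {}
    defaults = CohortSpec()
    init = section.get("initial_distribution",
                       list(defaults.initial_distribution))
    init = np.asarray(init, dtype=float)
    spec = CohortSpec(
        start_age=float(section.get("start_age", defaults.start_age)),
        initial_distribution=init,
        cycle_length_years=float(section.get("cycle_length_years",
                                             defaults.cycle_length_years)),
        discount_rate=float(section.get("discount_rate", defaults.discount_rate)),
        wtp=float(section.get("wtp", defaults.wtp)),
        gdp_per_capita=float(section.get("gdp_per_capita", defaults.gdp_per_capita)),
        vision_states=tuple(section.get("vision_states", defaults.vision_states)),
        comorbidity_states=tuple(section.get("comorbidity_states",
                                             defaults.comorbidity_states)),
        sae_years=tuple(section.get("sae_years", defaults.sae_years)),
        half_cycle_correction=bool(section.get("half_cycle_correction", False)),
        wtp_grid_max=float(section.get("wtp_grid_max", defaults.wtp_grid_max)),
        wtp_grid_step=float(section.get("wtp_grid_step", defaults.wtp_grid_step)),
        seed=int(section.get("seed", defaults.seed)))
    return spec


def parameter_set_from_config(cfg: dict, base_dir: str | None = None) -> ParameterSet:
    """Build and validate a :class:`ParameterSet` from a config mapping."""
    params = ParameterSet(
        trial_outcomes=_parse_trial_outcomes(cfg),
        risk_ratios=_parse_risk_ratios(cfg),
        costs=_parse_costs(cfg),
        utilities=_parse_utilities(cfg),
        life_table=_parse_life_table(cfg, base_dir),
        cohort=_parse_cohort(cfg))
    findings = validate_parameters(params)
    if findings:
        raise ParameterError("; ".join(findings))
    return params


def default_parameter_set() -> ParameterSet:
    """The base case: every published table input plus documented defaults."""
    return parameter_set_from_config(default_config())


def load_parameters(config_path: str | os.PathLike | None = None) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML config file.

    With ``config_path=None`` the packaged base-case defaults are returned.
    The config must supply every table entry; cohort/run settings fall back
    to documented defaults.
    """
    if config_path is None:
        return default_parameter_set()
    path = os.fspath(config_path)
    if not os.path.exists(path):
        raise ParameterError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParameterError(f"config file {path} did not parse to a mapping")
    return parameter_set_from_config(cfg, base_dir=os.path.dirname(os.path.abspath(path)))


# ---------------------------------------------------------------------------
# Validation


def _check_range(vr: ValueRange, name: str, findings: list[str],
                 lo: float | None = 0.0, hi: float | None = None) -> None:
    if not (vr.low <= vr.base <= vr.high):
        findings.append(f"{name}: range violates low <= base <= high "
                        f"({vr.low}, {vr.base}, {vr.high})")
    if lo is not None and vr.low < lo:
        findings.append(f"{name}: value below {lo}")
    if hi is not None and vr.high > hi:
        findings.append(f"{name}: value above {hi}")


def validate_parameters(params: ParameterSet) -> list[str]:
    """Check every invariant; returns one finding per violation (empty = valid)."""
    findings: list[str] = []

    for (strategy, lesion, year), probs in params.trial_outcomes.items():
        where = f"trial_outcomes/{strategy.value}/{lesion.value}/year{year}"
        s = sum(probs.as_tuple())
        for k, v in zip(OUTCOME_KEYS, probs.as_tuple()):
            if not 0.0 <= v <= 1.0:
                findings.append(f"{where}/{k}: probability out of [0,1]")
        if s > 1.0 + 1e-12:
            findings.append(f"{where}: outcome probabilities exceed 1 (sum {s:.4f})")

    for comparison, by_lesion in params.risk_ratios.items():
        for lesion, by_year in by_lesion.items():
            for year, rrset in by_year.items():
                for k, v in zip(OUTCOME_KEYS, rrset.as_tuple()):
                    if v < 0:
                        findings.append(
                            f"risk_ratios/{comparison}/{lesion.value}/year{year}/{k}: "
                            f"negative risk ratio")
    bvr = params.risk_ratios.get("bevacizumab_vs_ranibizumab", {})
    for lesion, by_year in bvr.items():
        if len({rr.as_tuple() for rr in by_year.values()}) > 1:
            findings.append(f"risk_ratios/bevacizumab_vs_ranibizumab/{lesion.value}: "
                            f"must be year-invariant")

    for name, vr in params.costs.unit.items():
        _check_range(vr, f"costs/unit/{name}", findings)
    for name, vr in params.costs.frequencies.items():
        _check_range(vr, f"costs/frequencies/{name}", findings)
    _check_range(params.costs.fluorescein_angiography_annual_mean,
                 "costs/fluorescein_angiography_annual_mean", findings)
    for arm, events in params.costs.sae.items():
        for name, e in events.items():
            _check_range(e.annual_prob, f"costs/sae/{arm}/{name}/annual_prob",
                         findings, lo=0.0, hi=1.0)
            _check_range(e.annual_mean_cost, f"costs/sae/{arm}/{name}/annual_mean_cost",
                         findings)
    for name, e in params.costs.comorbidities.items():
        _check_range(e.unit_cost, f"costs/comorbidities/{name}/unit_cost", findings)
        _check_range(e.annual_prob, f"costs/comorbidities/{name}/annual_prob",
                     findings, lo=0.0, hi=1.0)
        _check_range(e.annual_mean_cost, f"costs/comorbidities/{name}/annual_mean_cost",
                     findings)

    utils = [v.base for v in params.utilities.values]
    for k, vr in zip(UTILITY_KEYS, params.utilities.values):
        _check_range(vr, f"utilities/{k}", findings, lo=0.0, hi=1.0)
    if any(a < b for a, b in zip(utils, utils[1:])):
        findings.append("utilities: not non-increasing from best to worst VA state")

    lt = params.life_table
    if len(lt.ages) == 0:
        findings.append("life_table: empty")
    else:
        if not np.array_equal(np.diff(lt.ages), np.ones(len(lt.ages) - 1)):
            findings.append("life_table: non-contiguous ages")
        if np.any((lt.qx < 0) | (lt.qx > 1)):
            findings.append("life_table: qx out of [0,1]")
        if lt.qx[-1] != 1.0:
            findings.append("life_table: terminal age not absorbing (q_x != 1)")

    c = params.cohort
    if abs(float(c.initial_distribution.sum()) - 1.0) > 1e-9:
        findings.append("cohort: initial distribution does not sum to 1")
    if len(c.initial_distribution) != N_VA_STATES:
        findings.append(f"cohort: initial distribution must have {N_VA_STATES} entries")
    if np.any(c.initial_distribution < 0):
        findings.append("cohort: negative initial occupancy")
    if c.discount_rate < 0:
        findings.append("cohort: negative discount rate")
    if len(lt.ages) and not (lt.ages[0] <= c.start_age <= lt.ages[-1]):
        findings.append("cohort: starting age outside life-table range")
    if c.cycle_length_years <= 0 or not math.isclose(
            c.cycles_per_year * c.cycle_length_years, 1.0, rel_tol=1e-9):
        findings.append("cohort: cycle length must divide one year evenly")

    return findings


# ---------------------------------------------------------------------------
# Life-table I/O and parameter export


def read_life_table(path: str | os.PathLike) -> LifeTable:
    """Read a life table CSV with header columns ``age,qx``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"age", "qx"}.issubset(df.columns):
        raise ParameterError(f"life table {path} must have columns age,qx")
    ages = df["age"].to_numpy(dtype=int)
    qx = df["qx"].to_numpy(dtype=float)
    if len(ages) == 0:
        raise ParameterError(f"life table {path} is empty")
    if not np.array_equal(np.diff(ages), np.ones(len(ages) - 1, dtype=int)):
        raise ParameterError(f"life table {path}: non-contiguous ages")
    if np.any((qx < 0) | (qx > 1)):
        raise ParameterError(f"life table {path}: qx out of [0,1]")
    return LifeTable(ages=ages, qx=qx)


def write_life_table(lt: LifeTable, path: str | os.PathLike) -> None:
    """Write a life table as CSV (age,qx), round-trippable via read_life_table."""
    # repr gives the shortest representation that parses back bit-identically
    pd.DataFrame({"age": lt.ages, "qx": lt.qx}).to_csv(
        path, index=False, float_format=lambda v: repr(float(v)))


def write_config(cfg: dict, path: str | os.PathLike) -> None:
    """Dump a config mapping to YAML (e.g. the defaults, for user editing)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def export_parameters_csv(params: ParameterSet, path: str | os.PathLike) -> None:
    """Long-format CSV of all scalar inputs (table, name, base, low, high)."""
    rows: list[dict] = []
    for (strategy, lesion, year), probs in sorted(
            params.trial_outcomes.items(), key=lambda kv: (kv[0][0].value,
                                                           kv[0][1].value, kv[0][2])):
        for k, v in zip(OUTCOME_KEYS, probs.as_tuple()):
            rows.append({"table": "vision_outcomes",
                         "name": f"{strategy.value}/{lesion.value}/year{year}/{k}",
                         "base": v, "low": "", "high": ""})
    for comparison, by_lesion in params.risk_ratios.items():
        for lesion, by_year in sorted(by_lesion.items(), key=lambda kv: kv[0].value):
            for year, rrset in sorted(by_year.items()):
                for k, v in zip(OUTCOME_KEYS, rrset.as_tuple()):
                    rows.append({"table": "risk_ratios",
                                 "name": f"{comparison}/{lesion.value}/year{year}/{k}",
                                 "base": v, "low": "", "high": ""})
    for name, vr in params.costs.unit.items():
        rows.append({"table": "costs", "name": f"unit/{name}",
                     "base": vr.base, "low": vr.low, "high": vr.high})
    for name, vr in params.costs.frequencies.items():
        rows.append({"table": "costs", "name": f"frequencies/{name}",
                     "base": vr.base, "low": vr.low, "high": vr.high})
    fa = params.costs.fluorescein_angiography_annual_mean
    rows.append({"table": "costs", "name": "fluorescein_angiography_annual_mean",
                 "base": fa.base, "low": fa.low, "high": fa.high})
    for arm, events in params.costs.sae.items():
        for name, e in events.items():
            rows.append({"table": "costs", "name": f"sae/{arm}/{name}/annual_prob",
                         "base": e.annual_prob.base, "low": e.annual_prob.low,
                         "high": e.annual_prob.high})
            rows.append({"table": "costs", "name": f"sae/{arm}/{name}/annual_mean_cost",
                         "base": e.annual_mean_cost.base, "low": e.annual_mean_cost.low,
                         "high": e.annual_mean_cost.high})
    for name, e in params.costs.comorbidities.items():
        rows.append({"table": "costs", "name": f"comorbidities/{name}/annual_mean_cost",
                     "base": e.annual_mean_cost.base, "low": e.annual_mean_cost.low,
                     "high": e.annual_mean_cost.high})
    for k, vr in zip(UTILITY_KEYS, params.utilities.values):
        rows.append({"table": "utilities", "name": k,
                     "base": vr.base, "low": vr.low, "high": vr.high})
    pd.DataFrame(rows).to_csv(path, index=False)
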