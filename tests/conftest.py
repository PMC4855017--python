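import numpy as np
import pytest

from amdcea._defaults import default_config
from amdcea.parameters import default_parameter_set, parameter_set_from_config


@pytest.fixture
def params():
    """Fresh base-case parameter set (tests may mutate their copy)."""
    return default_parameter_set()


@pytest.fixture(scope="session")
def base_params():
    """Shared read-only base case for expensive session-level computations."""
    return default_parameter_set()


def make_params(*, zero_mortality=False, zero_transitions=False,
                utilities=None, discount_rate=None, initial_distribution=None,
                start_age=None, zero_costs=False):
    """Parameter sets with pieces switched off, for closed-form checks."""
    cfg = default_config()
    if zero_mortality:
        cfg["life_table"]["synthetic"]["makeham"] = 0.0
        cfg["life_table"]["synthetic"]["gompertz_a"] = 0.0
    if zero_transitions:
        for arm in cfg["trial_outcomes"].values():
            for lesion in arm.values():
                for year in lesion.values():
                    year.update(gain=0.0, loss_3_6=0.0, loss_gt6=0.0)
        for comparison in cfg["risk_ratios"].values():
            for node in comparison.values():
                for entry in (node.values()
                              if "gain" not in node else [node]):
                    entry.update(gain=0.0, loss_3_6=0.0, loss_gt6=0.0)
    if utilities is not None:
        for key in cfg["utilities"]:
            u = float(utilities)
            cfg["utilities"][key] = {"base": u, "low": u, "high": u}
    if discount_rate is not None:
        cfg["cohort"]["discount_rate"] = float(discount_rate)
    if initial_distribution is not None:
        cfg["cohort"]["initial_distribution"] = list(initial_distribution)
    if start_age is not None:
        cfg["cohort"]["start_age"] = float(start_age)
    if zero_costs:
        for name in cfg["costs"]["unit"]:
            cfg["costs"]["unit"][name] = {"base": 0.0, "low": 0.0, "high": 0.0}
        cfg["costs"]["fluorescein_angiography_annual_mean"] = {
            "base": 0.0, "low": 0.0, "high": 0.0}
        for arm in cfg["costs"]["sae"].values():
            for event in arm.values():
                event["annual_mean_cost"] = {"base": 0.0, "low": 0.0, "high": 0.0}
        for entry in cfg["costs"]["comorbidities"].values():
            entry["annual_mean_cost"] = {"base": 0.0, "low": 0.0, "high": 0.0}
    return parameter_set_from_config(cfg)


@pytest.fixture
def degenerate_best_state():
    return np.array([1.0, 0.0, 0.0, 0.0, 0.0])
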