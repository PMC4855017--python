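"""Base-case model inputs.

Every number here is a published base-case input: cumulative one- and
two-year probabilities of vision change under usual care and PDT by lesion
subtype (from the TAP/VIP placebo and verteporfin arms), risk ratios for the
indirect comparison (ranibizumab vs PDT from ANCHOR, ranibizumab vs usual
care from MARINA, bevacizumab vs ranibizumab from CATT), Chinese unit costs
and resource frequencies in 2012 US$, and time-tradeoff utilities per
visual-acuity band.  Ranges in (base, low, high) triplets drive the one-way
sensitivity analysis; entries without a published range default to +/-20%
of base at load time.

The default life table is synthetic: a Gompertz-Makeham hazard calibrated so
that life expectancy at the base-case starting age (73.6 years) is about 12
years, standing in for a national 2011 period life table.  Drop in a real
table as CSV (columns age,qx) to override.
"""

from __future__ import annotations

import copy
from typing import Any


def _pm20(base: float) -> dict:
    """Range defaulting: +/-20% of the base value."""
    return {"base": base, "low": round(base * 0.8, 6), "high": round(base * 1.2, 6)}


DEFAULT_CONFIG: dict[str, Any] = {
    # Cumulative probability of vision change per trial year (not per cycle).
    "trial_outcomes": {
        "usual_care": {
            "predominantly_classic": {
                "year1": {"gain": 0.0241, "loss_3_6": 0.2310, "loss_gt6": 0.2914},
                "year2": {"gain": 0.0148, "loss_3_6": 0.0633, "loss_gt6": 0.0421},
            },
            "minimally_classic": {
                "year1": {"gain": 0.0192, "loss_3_6": 0.2885, "loss_gt6": 0.1635},
                "year2": {"gain": 0.0289, "loss_3_6": 0.0633, "loss_gt6": 0.1057},
            },
            "occult": {
                "year1": {"gain": 0.0217, "loss_3_6": 0.2283, "loss_gt6": 0.3261},
                "year2": {"gain": 0.0171, "loss_3_6": 0.0633, "loss_gt6": 0.1413},
            },
        },
        "pdt": {
            "predominantly_classic": {
                "year1": {"gain": 0.0566, "loss_3_6": 0.2651, "loss_gt6": 0.1346},
                "year2": {"gain": 0.0175, "loss_3_6": 0.0635, "loss_gt6": 0.0300},
            },
            "minimally_classic": {
                "year1": {"gain": 0.0644, "loss_3_6": 0.2723, "loss_gt6": 0.1683},
                "year2": {"gain": 0.0198, "loss_3_6": 0.0544, "loss_gt6": 0.0297},
            },
            "occult": {
                "year1": {"gain": 0.0301, "loss_3_6": 0.2892, "loss_gt6": 0.2229},
                "year2": {"gain": 0.0181, "loss_3_6": 0.0816, "loss_gt6": 0.0663},
            },
        },
    },
    # Risk ratios for the indirect comparison.  Ranibizumab is anchored on
    # PDT for predominantly classic lesions and on usual care otherwise;
    # bevacizumab is chained onto the derived ranibizumab probabilities.
    "risk_ratios": {
        "ranibizumab_vs_pdt": {
            "predominantly_classic": {
                "year1": {"gain": 7.2, "loss_3_6": 0.1, "loss_gt6": 0.0},
                "year2": {"gain": 0.49, "loss_3_6": 4.35, "loss_gt6": 0.06},
            },
        },
        "ranibizumab_vs_usual_care": {
            "minimally_classic": {
                "year1": {"gain": 6.69, "loss_3_6": 0.17, "loss_gt6": 0.09},
                "year2": {"gain": 0.42, "loss_3_6": 3.78, "loss_gt6": 0.14},
            },
            "occult": {
                "year1": {"gain": 6.69, "loss_3_6": 0.17, "loss_gt6": 0.09},
                "year2": {"gain": 0.42, "loss_3_6": 3.78, "loss_gt6": 0.14},
            },
        },
        # Year-invariant (same RR applies in years 1 and 2), all lesions.
        "bevacizumab_vs_ranibizumab": {
            "all_lesions": {"gain": 0.92, "loss_3_6": 1.07, "loss_gt6": 1.07},
        },
    },
    "costs": {
        # Unit costs, 2012 US$.
        "unit": {
            "consultation": {"base": 3.2, "low": 0.8, "high": 47.6},
            "oct": {"base": 31.7, "low": 23.8, "high": 39.7},
            "fluorescein_angiography": {"base": 58.7, "low": 44.0, "high": 73.4},
            "verteporfin": {"base": 2539.7, "low": 1904.8, "high": 3174.6},
            "laser_activation": {"base": 238.1, "low": 158.7, "high": 317.5},
            "intravitreal_injection": {"base": 41.3, "low": 31.0, "high": 51.6},
            "ranibizumab_dose": {"base": 1523.8, "low": 1142.9, "high": 1904.8},
            "bevacizumab_dose": {"base": 10.5, "low": 7.9, "high": 13.1},
        },
        # Resource frequencies.  Consultation and OCT are once per cycle
        # (4/year); fluorescein angiography carries a published annual mean
        # total (234.8) that is taken as authoritative over its printed
        # "2 times per year" frequency.
        "frequencies": {
            "consultation_per_year": _pm20(4.0),
            "oct_per_year": _pm20(4.0),
            "pdt_year1": {"base": 2.05, "low": 1.5375, "high": 2.5625},
            "pdt_year2": {"base": 1.54, "low": 1.155, "high": 1.925},
            "injections_year1": {"base": 8.0, "low": 6.0, "high": 12.0},
            "injections_year2": {"base": 6.0, "low": 4.5, "high": 12.0},
        },
        "fluorescein_angiography_annual_mean": _pm20(234.8),
        # Serious adverse events: annual probability and annual mean cost,
        # by active injection arm, applied during active treatment years.
        "sae": {
            "ranibizumab": {
                "endophthalmitis": {
                    "annual_prob": {"base": 0.014, "low": 0.0105, "high": 0.0175},
                    "annual_mean_cost": _pm20(22.2),
                },
                "lens_damage": {
                    "annual_prob": {"base": 0.004, "low": 0.003, "high": 0.005},
                    "annual_mean_cost": _pm20(6.3),
                },
                "retinal_detachment": {
                    "annual_prob": {"base": 0.003, "low": 0.0023, "high": 0.0038},
                    "annual_mean_cost": _pm20(5.7),
                },
            },
            "bevacizumab": {
                "endophthalmitis": {
                    "annual_prob": {"base": 0.028, "low": 0.021, "high": 0.035},
                    "annual_mean_cost": _pm20(44.4),
                },
                "lens_damage": {
                    "annual_prob": {"base": 0.004, "low": 0.003, "high": 0.005},
                    "annual_mean_cost": _pm20(6.3),
                },
                "retinal_detachment": {
                    "annual_prob": {"base": 0.003, "low": 0.0023, "high": 0.0038},
                    "annual_mean_cost": _pm20(5.7),
                },
            },
        },
        # Comorbidities of low vision.  The published annual mean totals are
        # taken as authoritative (the printed unit-cost x probability
        # products do not reproduce them consistently).
        "comorbidities": {
            "depression": {
                "unit_cost": {"base": 130.6, "low": 111.2, "high": 156.4},
                "annual_prob": {"base": 0.022, "low": 0.0165, "high": 0.0275},
                "annual_mean_cost": _pm20(3.0),
            },
            "fall": {
                "unit_cost": {"base": 1093.9, "low": 364.6, "high": 1823.2},
                "annual_prob": {"base": 0.18, "low": 0.145, "high": 0.286},
                "annual_mean_cost": _pm20(23.0),
            },
            "assisted_living": {
                "unit_cost": {"base": 432.7, "low": 324.5, "high": 540.8},
                "annual_prob": {"base": 0.021, "low": 0.0158, "high": 0.0263},
                "annual_mean_cost": _pm20(77.9),
            },
        },
    },
    # Time-tradeoff utilities per VA band; death has utility 0.
    "utilities": {
        "va_better_20_40": {"base": 0.89, "low": 0.82, "high": 0.96},
        "va_20_40_to_20_80": {"base": 0.81, "low": 0.73, "high": 0.89},
        "va_20_80_to_20_200": {"base": 0.57, "low": 0.47, "high": 0.67},
        "va_20_200_to_20_400": {"base": 0.52, "low": 0.38, "high": 0.66},
        "va_20_400_or_worse": {"base": 0.40, "low": 0.29, "high": 0.50},
    },
    "life_table": {
        "synthetic": {
            "makeham": 5.0e-4,
            "gompertz_a": 2.1263e-5,
            "gompertz_b": 0.10,
            "start_age": 40,
            "terminal_age": 105,
        },
    },
    "cohort": {
        "start_age": 73.6,
        # The source initial VA distribution is unpublished; uniform over the
        # five VA bands is the documented default, overridable per scenario.
        "initial_distribution": [0.2, 0.2, 0.2, 0.2, 0.2],
        "cycle_length_years": 0.25,
        "discount_rate": 0.03,
        "wtp": 7480.0,                 # 1x per-capita GDP, $/QALY
        "gdp_per_capita": 7480.0,
        "vision_states": [0, 1, 2],    # "vision-years" counts VA better than 20/200
        "comorbidity_states": [2, 3, 4],
        "sae_years": [1, 2],
        "half_cycle_correction": False,
        "wtp_grid_max": 30000.0,
        "wtp_grid_step": 250.0,
        "seed": 0,
    },
}


def default_config() -> dict[str, Any]:
    """A deep copy of the base-case configuration mapping."""
    return copy.deepcopy(DEFAULT_CONFIG)
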