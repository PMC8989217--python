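"""Expected-value cohort engine for the one-year IBD decision tree.

Each strategy sends a homogeneous cohort (mixed ulcerative colitis / Crohn's
disease) through a single-cycle probability tree: outpatient care →
IBD-related hospitalization → surgery → in-hospital death.  Pandemic-related
healthcare avoidance scales the hospitalization probability by a
population-averaged relative risk and reduces outpatient-visit cost in the
avoider subgroup; telemonitoring scales hospitalization down in the
compliant subgroup, adds the program cost for everyone enrolled, and
increases non-invasive diagnostic use among the compliant.

Cost assembly convention: outpatient visits, medications and non-invasive
imaging accrue to the whole cohort; endoscopy, hospitalization, surgery and
in-hospital-death costs accrue to the hospitalized fraction only.  Decedents
accrue zero QALYs for the year; survivors accrue their single health-state
utility for the full year.  No discounting (one-year horizon).

All arithmetic is elementwise, so parameter values may be scalars or numpy
arrays of draws (the PSA engine exploits this).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "StrategyConfig",
    "CohortOutcome",
    "SC_NO_AVOIDANCE",
    "SC",
    "SC_TM",
    "STRATEGIES",
    "hospitalization_multiplier",
    "telemonitoring_multiplier",
    "tm_program_cost",
    "disease_branch_outcome",
    "expected_outcomes",
]


@dataclass(frozen=True)
class StrategyConfig:
    """Flags selecting which multipliers and costs apply to a strategy."""

    label: str
    avoidance_enabled: bool = False
    telemonitoring_enabled: bool = False

    def __post_init__(self) -> None:
        # telemonitoring is evaluated during the pandemic, i.e. on top of
        # avoidance — a TM arm without avoidance has no comparator in the model
        if self.telemonitoring_enabled and not self.avoidance_enabled:
            raise ValueError(
                "telemonitoring_enabled requires avoidance_enabled "
                "(the telemonitoring arm is a pandemic-era strategy)"
            )


#: standard care before the pandemic (no healthcare avoidance)
SC_NO_AVOIDANCE = StrategyConfig("SC without avoidance", avoidance_enabled=False)
#: standard care during the pandemic (with healthcare avoidance)
SC = StrategyConfig("SC", avoidance_enabled=True)
#: standard care plus telemonitoring during the pandemic
SC_TM = StrategyConfig("SC-TM", avoidance_enabled=True, telemonitoring_enabled=True)

STRATEGIES: dict[str, StrategyConfig] = {
    "sc_no_avoidance": SC_NO_AVOIDANCE,
    "sc": SC,
    "sc_tm": SC_TM,
}


@dataclass(frozen=True)
class CohortOutcome:
    """Per-strategy expected outcomes, per patient-year."""

    hosp_per100py: float
    mort_per100py: float
    cost: float
    qalys: float


def hospitalization_multiplier(p_avoid, rr_avoid):
    """Population-average hospitalization scaling from healthcare avoidance.

    The relative risk applies to the avoider subgroup only, then is
    averaged over the cohort: ``p_avoid * rr_avoid + (1 - p_avoid)``.
    """
    return p_avoid * rr_avoid + (1.0 - p_avoid)


def telemonitoring_multiplier(p_comply, rr_tm):
    """Compliance-weighted hospitalization scaling from telemonitoring.

    Only patients meeting the weekly self-assessment requirement receive the
    risk reduction: ``p_comply * rr_tm + (1 - p_comply)``.
    """
    return p_comply * rr_tm + (1.0 - p_comply)


def tm_program_cost(maintenance, encounters, hours, wage):
    """Telemonitoring program cost per patient-year (USD).

    Annual maintenance fee plus staff time for the excess
    electronic/telephone encounters mediated by the program.
    """
    return maintenance + encounters * hours * wage


def _branch(values: Mapping[str, object], disease: str, hosp_factor, strategy):
    """Tree outcomes for one disease branch; elementwise over draws.

    Returns ``(hosp, mort, cost, qalys)`` per patient-year (probability scale).
    """
    d = disease.lower()
    if d not in ("uc", "cd"):
        raise ValueError(f"unknown disease {disease!r} (expected 'UC' or 'CD')")
    h = values[f"h_{d}"] * hosp_factor
    if np.any(np.asarray(h) > 1.0):
        raise ValueError("effective hospitalization probability exceeds 1")
    s = values[f"s_{d}"]
    m = values[f"m_{d}"]
    u_out, u_hosp, u_surg = values["u_out"], values["u_hosp"], values["u_surg"]

    qalys = (
        (1.0 - h) * u_out
        + h * (1.0 - s) * (1.0 - m) * u_hosp
        + h * s * (1.0 - m) * u_surg
    )

    avoider_scale = (
        values["p_avoid"] * values["visit_reduction"]
        if strategy.avoidance_enabled
        else 0.0
    )
    imaging_scale = (
        1.0 + values["p_comply"] * (values["rr_imaging_tm"] - 1.0)
        if strategy.telemonitoring_enabled
        else 1.0
    )
    tm_cost = (
        tm_program_cost(
            values["tm_maintenance"],
            values["tm_encounters"],
            values["tm_encounter_hours"],
            values["tm_wage"],
        )
        if strategy.telemonitoring_enabled
        else 0.0
    )
    cost = (
        values[f"cost_visit_{d}"] * (1.0 - avoider_scale)
        + values[f"cost_meds_{d}"]
        + values[f"cost_imaging_{d}"] * imaging_scale
        + h
        * (
            values[f"cost_endoscopy_{d}"]
            + values[f"cost_hosp_{d}"]
            + s * values[f"cost_surgery_{d}"]
            + m * values[f"cost_death_{d}"]
        )
        + tm_cost
    )
    return h, h * m, cost, qalys


def hosp_factor_for(values: Mapping[str, object], strategy: StrategyConfig):
    """Combined hospitalization multiplier implied by a strategy's flags."""
    factor = 1.0
    if strategy.avoidance_enabled:
        factor = factor * hospitalization_multiplier(
            values["p_avoid"], values["rr_avoid"]
        )
    if strategy.telemonitoring_enabled:
        factor = factor * telemonitoring_multiplier(
            values["p_comply"], values["rr_tm"]
        )
    return factor


def outcomes_from_values(values: Mapping[str, object], strategy: StrategyConfig):
    """Disease-mix-weighted expected outcomes from raw parameter values.

    ``values`` maps parameter names to scalars or aligned numpy arrays;
    returns ``(hosp, mort, cost, qalys)`` elementwise (rates on the
    probability scale, not per 100).
    """
    factor = hosp_factor_for(values, strategy)
    w_uc = values["p_uc"]
    out = None
    for w, disease in ((w_uc, "uc"), (1.0 - w_uc, "cd")):
        fields = _branch(values, disease, factor, strategy)
        contrib = tuple(w * f for f in fields)
        out = contrib if out is None else tuple(a + b for a, b in zip(out, contrib))
    return out


def disease_branch_outcome(
    disease: str,
    hosp_factor: float,
    params: ModelParameters,
    strategy: StrategyConfig,
) -> CohortOutcome:
    """Expected outcomes for a single disease branch at base-case values."""
    h, mort, cost, qalys = _branch(
        params.base_values(), disease, hosp_factor, strategy
    )
    return CohortOutcome(100.0 * h, 100.0 * mort, float(cost), float(qalys))


def expected_outcomes(
    params: ModelParameters, strategy: StrategyConfig
) -> CohortOutcome:
    """Expected cohort outcomes for one strategy at base-case values.

    Rates are reported per 100 patient-years; cost in USD and QALYs per
    patient-year, at full floating precision (rounding is a display concern).
    """
    h, mort, cost, qalys = outcomes_from_values(params.base_values(), strategy)
    return CohortOutcome(100.0 * h, 100.0 * mort, float(cost), float(qalys))
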