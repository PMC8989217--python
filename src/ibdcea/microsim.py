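"""Patient-level microsimulation: brute-force oracle for the cohort engine.

Simulates individual trajectories through the one-year tree — disease type,
avoider/compliant status, hospitalization, surgery, death — as independent
Bernoulli draws, accruing cost and QALYs per patient with exactly the cohort
engine's assembly rules.  Sample means converge to the analytic
expected-value results, which makes this module both the synthetic-data
generator and the primary cross-validation of the cost-assembly convention.

Relative risks act per patient as multiplicative scaling of the
hospitalization probability given that patient's drawn avoider/compliant
flags, so the population-averaged hospitalization probability matches the
cohort engine's multiplier construction exactly in expectation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortOutcome, StrategyConfig, tm_program_cost
from .parameters import ModelParameters, write_parameters

__all__ = ["simulate_cohort", "write_fixture"]

PATIENT_COLUMNS = [
    "disease",
    "avoider",
    "compliant",
    "hospitalized",
    "surgical",
    "died",
    "cost",
    "qalys",
]


def simulate_cohort(
    params: ModelParameters,
    strategy: StrategyConfig,
    n_patients: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, CohortOutcome]:
    """Simulate ``n_patients`` one-year trajectories under one strategy.

    Returns the patient-level table (one row per patient) and the aggregate
    outcome (means; rates per 100 patient-years).  Identical seeds yield
    identical tables.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    v = params.base_values()
    rng = np.random.default_rng(seed)
    n = n_patients

    is_uc = rng.random(n) < v["p_uc"]
    avoider = (
        rng.random(n) < v["p_avoid"]
        if strategy.avoidance_enabled
        else np.zeros(n, dtype=bool)
    )
    compliant = (
        rng.random(n) < v["p_comply"]
        if strategy.telemonitoring_enabled
        else np.zeros(n, dtype=bool)
    )

    def by_disease(name: str) -> np.ndarray:
        return np.where(is_uc, v[f"{name}_uc"], v[f"{name}_cd"])

    p_hosp = by_disease("h")
    rr = np.ones(n)
    rr = np.where(avoider, rr * v["rr_avoid"], rr)
    rr = np.where(compliant, rr * v["rr_tm"], rr)
    p_hosp = p_hosp * rr
    if np.any(p_hosp > 1.0):
        raise ValueError("per-patient effective hospitalization probability > 1")

    hospitalized = rng.random(n) < p_hosp
    surgical = hospitalized & (rng.random(n) < by_disease("s"))
    died = hospitalized & (rng.random(n) < by_disease("m"))

    qalys = np.where(
        died,
        0.0,
        np.where(
            surgical,
            v["u_surg"],
            np.where(hospitalized, v["u_hosp"], v["u_out"]),
        ),
    )

    visit = by_disease("cost_visit") * np.where(
        avoider, 1.0 - v["visit_reduction"], 1.0
    )
    imaging = by_disease("cost_imaging") * np.where(
        compliant, v["rr_imaging_tm"], 1.0
    )
    cost = visit + by_disease("cost_meds") + imaging
    cost = cost + hospitalized * (
        by_disease("cost_endoscopy")
        + by_disease("cost_hosp")
        + surgical * by_disease("cost_surgery")
        + died * by_disease("cost_death")
    )
    if strategy.telemonitoring_enabled:
        cost = cost + tm_program_cost(
            v["tm_maintenance"],
            v["tm_encounters"],
            v["tm_encounter_hours"],
            v["tm_wage"],
        )

    records = pd.DataFrame(
        {
            "disease": np.where(is_uc, "UC", "CD"),
            "avoider": avoider,
            "compliant": compliant,
            "hospitalized": hospitalized,
            "surgical": surgical,
            "died": died,
            "cost": cost,
            "qalys": qalys,
        }
    )
    aggregate = CohortOutcome(
        hosp_per100py=100.0 * float(np.mean(hospitalized)),
        mort_per100py=100.0 * float(np.mean(died)),
        cost=float(np.mean(cost)),
        qalys=float(np.mean(qalys)),
    )
    return records, aggregate


def write_fixture(params: ModelParameters, destination: str | Path) -> list[Path]:
    """Emit the canonical parameter file plus low/high perturbed variants.

    Writes ``canonical.csv`` and, for every non-point parameter,
    ``<name>_low.csv`` / ``<name>_high.csv`` with that parameter's base value
    moved to its range bound (all other rows untouched).  Returns the paths.
    """
    if not params.estimates:
        raise ValueError("empty parameter set")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = [write_parameters(params, dest / "canonical.csv")]
    for est in params:
        if est.family == "point":
            continue
        for bound in ("low", "high"):
            variant = params.with_base(est.name, getattr(est, bound))
            paths.append(
                write_parameters(variant, dest / f"{est.name}_{bound}.csv")
            )
    return paths
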