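"""Typed parameter model and file I/O for the decision-analytic inputs.

The model is driven by a flat table of parameter estimates — one row per
model input, each carrying a base-case value, a low/high range used by the
deterministic and probabilistic sensitivity analyses, and a distribution
family for Monte Carlo resampling.  The canonical set (Hong Kong IBD cohort,
costs in 2021 USD) ships with the package and is the fixture every analysis
and test runs on.

Parameter naming convention: disease-specific entries carry a ``_uc``
(ulcerative colitis) or ``_cd`` (Crohn's disease) suffix; ``h``/``s``/``m``
are the hospitalization, surgery-per-hospitalization and in-hospital
mortality probabilities; ``rr_*`` are relative risks; ``u_*`` utilities.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "ParameterEstimate",
    "ModelParameters",
    "ParameterValidationError",
    "PARAMETER_ORDER",
    "load_parameters",
    "write_parameters",
    "canonical_parameters",
]

FAMILIES = frozenset({"beta", "gamma", "lognormal", "normal", "point"})

#: role of each parameter, used for domain validation ("probability" and
#: "utility" must lie in [0, 1]; "cost"/"count" must be non-negative;
#: "rr" must be positive; "scalar" is unconstrained metadata).
PARAMETER_ROLES: dict[str, str] = {
    "p_uc": "probability",
    "h_uc": "probability",
    "s_uc": "probability",
    "m_uc": "probability",
    "h_cd": "probability",
    "s_cd": "probability",
    "m_cd": "probability",
    "p_avoid": "probability",
    "rr_avoid": "rr",
    "p_comply": "probability",
    "rr_tm": "rr",
    "cost_visit_uc": "cost",
    "cost_meds_uc": "cost",
    "cost_imaging_uc": "cost",
    "cost_endoscopy_uc": "cost",
    "cost_hosp_uc": "cost",
    "cost_surgery_uc": "cost",
    "cost_death_uc": "cost",
    "cost_visit_cd": "cost",
    "cost_meds_cd": "cost",
    "cost_imaging_cd": "cost",
    "cost_endoscopy_cd": "cost",
    "cost_hosp_cd": "cost",
    "cost_surgery_cd": "cost",
    "cost_death_cd": "cost",
    "visit_reduction": "probability",
    "tm_maintenance": "cost",
    "tm_encounters": "count",
    "tm_encounter_hours": "count",
    "tm_wage": "cost",
    "rr_imaging_tm": "rr",
    "u_out": "utility",
    "u_hosp": "utility",
    "u_surg": "utility",
    "wtp": "cost",
    "horizon": "count",
    "usd_to_hkd": "scalar",
}

#: canonical ordering of the parameter table; also the documented, fixed
#: order in which the PSA engine draws each parameter.
PARAMETER_ORDER: tuple[str, ...] = tuple(PARAMETER_ROLES)


class ParameterValidationError(ValueError):
    """Raised when a parameter file or estimate violates the data model."""


@dataclass(frozen=True)
class ParameterEstimate:
    """One model input: base-case value plus its sensitivity range.

    ``low``/``high`` bound the one-way sensitivity sweep and parameterize
    the PSA distribution (the range is read as a 95% interval there).
    ``family`` names the resampling distribution; ``point`` marks scalars
    the analyses never vary.
    """

    name: str
    base: float
    low: float
    high: float
    family: str
    units: str = ""

    def __post_init__(self) -> None:
        errs = []
        if self.family not in FAMILIES:
            errs.append(f"unknown distribution family {self.family!r}")
        if not (self.low <= self.base <= self.high):
            errs.append(
                f"range violation: low <= base <= high fails "
                f"({self.low} <= {self.base} <= {self.high})"
            )
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            errs.append("beta-distributed parameter out of [0, 1]")
        if self.family == "gamma" and self.low < 0.0:
            errs.append("gamma-distributed parameter with negative low")
        if self.family == "point" and not (self.low == self.base == self.high):
            errs.append("point parameter must have low = base = high")
        role = PARAMETER_ROLES.get(self.name)
        if role in ("probability", "utility") and not (
            0.0 <= self.low and self.high <= 1.0
        ):
            errs.append(f"{role} out of [0,1]")
        if role == "cost" and self.low < 0.0:
            errs.append("cost must be >= 0")
        if role == "rr" and self.low <= 0.0:
            errs.append("relative risk must be > 0")
        if errs:
            raise ParameterValidationError(
                f"parameter {self.name!r}: " + "; ".join(errs)
            )

    @property
    def is_point(self) -> bool:
        """True when nothing varies: family ``point`` or a zero-width range."""
        return self.family == "point" or self.low == self.high


@dataclass(frozen=True)
class ModelParameters:
    """The complete validated parameter set (all entries of the input table).

    Behaves as an ordered, immutable mapping from parameter name to
    :class:`ParameterEstimate`; attribute access (``params.p_uc``) returns
    the estimate, ``params.value("p_uc")`` its base value.
    """

    estimates: Mapping[str, ParameterEstimate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = set(self.estimates)
        required = set(PARAMETER_ORDER)
        unknown = sorted(names - required)
        if unknown:
            raise ParameterValidationError(f"unknown parameter names: {unknown}")
        missing = sorted(required - names)
        if missing:
            raise ParameterValidationError(f"missing parameters: {missing}")
        # cross-parameter invariant: the CD share is 1 - p_uc by construction,
        # so p_uc alone must be a valid proportion (checked per-estimate);
        # nothing else couples across rows.
        ordered = {n: self.estimates[n] for n in PARAMETER_ORDER}
        object.__setattr__(self, "estimates", ordered)

    def __getattr__(self, name: str) -> ParameterEstimate:
        try:
            return self.estimates[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> ParameterEstimate:
        return self.estimates[name]

    def __iter__(self) -> Iterator[ParameterEstimate]:
        return iter(self.estimates.values())

    def __contains__(self, name: str) -> bool:
        return name in self.estimates

    def value(self, name: str) -> float:
        """Base-case value of parameter ``name``."""
        return self.estimates[name].base

    def base_values(self) -> dict[str, float]:
        """All base-case values, in canonical order."""
        return {n: e.base for n, e in self.estimates.items()}

    def with_base(self, name: str, base: float) -> "ModelParameters":
        """Copy with one parameter's base value replaced.

        Used by the sensitivity analyses; the estimate's range is widened if
        needed so extended sweeps beyond the printed range stay valid.
        """
        est = self.estimates[name]
        new = replace(
            est, base=base, low=min(est.low, base), high=max(est.high, base)
        )
        d = dict(self.estimates)
        d[name] = new
        return ModelParameters(d)

    def to_frame(self) -> pd.DataFrame:
        """Parameter table as a DataFrame (name/base/low/high/family/units)."""
        return pd.DataFrame(
            [
                {
                    "name": e.name,
                    "base": e.base,
                    "low": e.low,
                    "high": e.high,
                    "family": e.family,
                    "units": e.units,
                }
                for e in self
            ]
        )


def _from_records(records: list[dict]) -> ModelParameters:
    estimates = {}
    errors = []
    for rec in records:
        try:
            est = ParameterEstimate(
                name=str(rec["name"]),
                base=float(rec["base"]),
                low=float(rec["low"]),
                high=float(rec["high"]),
                family=str(rec["family"]),
                units=str(rec.get("units", "") or ""),
            )
        except ParameterValidationError as exc:
            errors.append(str(exc))
            continue
        estimates[est.name] = est
    if errors:
        raise ParameterValidationError("; ".join(errors))
    return ModelParameters(estimates)


def load_parameters(source: str | Path) -> ModelParameters:
    """Load and validate a parameter table from CSV/TSV, YAML or JSON.

    The file must contain exactly one record per required parameter name;
    missing names are reported collectively, unknown names rejected.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv", ".txt"):
        sep = "\t" if suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, comment="#")
        records = df.to_dict("records")
    elif suffix in (".yaml", ".yml", ".json"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if isinstance(doc, dict) and "parameters" in doc:
            doc = doc["parameters"]
        if not isinstance(doc, list):
            raise ParameterValidationError(
                f"{path}: expected a list of parameter records"
            )
        records = doc
    else:
        raise ParameterValidationError(f"unsupported parameter file format: {path}")
    return _from_records(records)


def write_parameters(params: ModelParameters, destination: str | Path) -> Path:
    """Write a parameter table; format chosen by extension (CSV/TSV/YAML/JSON).

    Floats are written with full repr precision so a load/write round-trip
    is bit-for-bit.
    """
    path = Path(destination)
    df = params.to_frame()
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv", ".txt"):
        sep = "\t" if suffix == ".tsv" else ","
        df.to_csv(path, sep=sep, index=False, float_format=None)
    elif suffix in (".yaml", ".yml", ".json"):
        with open(path, "w") as fh:
            yaml.safe_dump({"parameters": df.to_dict("records")}, fh, sort_keys=False)
    else:
        raise ParameterValidationError(f"unsupported parameter file format: {path}")
    return path


def canonical_file() -> Path:
    """Path to the bundled canonical parameter table."""
    return Path(importlib.resources.files("ibdcea") / "data" / "table1.csv")


def canonical_parameters() -> ModelParameters:
    """The built-in base-case parameter set shipped with the package."""
    return load_parameters(canonical_file())
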