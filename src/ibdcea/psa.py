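"""Probabilistic sensitivity analysis (Monte Carlo over parameter uncertainty).

Each uncertain input is given a parametric distribution from its base value
and printed sensitivity range, the range being read as a 95% interval
(sd = range/3.92 — the standard health-economics convention when source
variances are unreported):

* beta and gamma — method of moments to (mean = base, sd);
* normal — mean = base, the sd above;
* lognormal — natural-scale median anchored at base (relative-risk point
  estimates are geometric means), log-scale sd = (ln high − ln low)/3.92;
* point — degenerate.

By default every draw is constrained to the parameter's printed range by
rejection resampling, so the simulated uncertainty matches the bounds the
deterministic sensitivity analysis declares plausible; ``truncate=False``
samples the unbounded fitted distributions instead.

All strategies are evaluated on the *same* draw (common random parameters),
so per-draw incremental comparisons — cost-effectiveness-plane quadrant
proportions — are paired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import StrategyConfig, hosp_factor_for, outcomes_from_values
from .economics import DEFAULT_WTP
from .parameters import PARAMETER_ORDER, ModelParameters, ParameterEstimate

__all__ = [
    "FittedDistribution",
    "PSAResult",
    "fit_distribution",
    "run_psa",
    "ce_plane_export",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile
RANGE_TO_SD = 2.0 * Z95  # ~3.92: width of a 95% interval in sd units

_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class FittedDistribution:
    """Sampling distribution for one parameter.

    ``args`` holds the family-specific shape descriptors; ``range_low`` /
    ``range_high`` are the printed sensitivity bounds used for truncation.
    """

    parameter: str
    family: str
    args: dict[str, float]
    base: float
    range_low: float
    range_high: float

    @property
    def support(self) -> tuple[float, float]:
        return {
            "beta": (0.0, 1.0),
            "gamma": (0.0, math.inf),
            "lognormal": (0.0, math.inf),
            "normal": (-math.inf, math.inf),
            "point": (self.base, self.base),
        }[self.family]

    def mean(self) -> float:
        """Analytic mean of the (untruncated) fitted distribution."""
        a = self.args
        if self.family == "beta":
            return a["a"] / (a["a"] + a["b"])
        if self.family == "gamma":
            return a["shape"] * a["scale"]
        if self.family == "lognormal":
            return math.exp(a["mu"] + a["sigma"] ** 2 / 2.0)
        if self.family == "normal":
            return a["mean"]
        return self.base

    def median(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.args["mu"])
        if self.family == "normal":
            return self.args["mean"]
        return self.base  # beta/gamma medians not needed analytically

    def _draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a = self.args
        if self.family == "beta":
            return rng.beta(a["a"], a["b"], size)
        if self.family == "gamma":
            return rng.gamma(a["shape"], a["scale"], size)
        if self.family == "lognormal":
            return rng.lognormal(a["mu"], a["sigma"], size)
        if self.family == "normal":
            return rng.normal(a["mean"], a["sd"], size)
        return np.full(size, self.base)

    def sample(
        self, rng: np.random.Generator, size: int, truncate: bool = True
    ) -> np.ndarray:
        """Draw ``size`` values; optionally rejection-truncated to the range."""
        x = self._draw(rng, size)
        if truncate and self.family != "point":
            lo, hi = self.range_low, self.range_high
            for _ in range(_MAX_REJECTION_ROUNDS):
                bad = (x < lo) | (x > hi)
                if not bad.any():
                    break
                x[bad] = self._draw(rng, int(bad.sum()))
            else:  # pragma: no cover - ranges are ~2 sd, never this unlikely
                raise RuntimeError(
                    f"truncated sampling for {self.parameter!r} did not converge"
                )
        return x


def fit_distribution(estimate: ParameterEstimate) -> FittedDistribution:
    """Parameterize a sampling distribution from base value and range.

    Zero-width ranges degenerate to a point mass regardless of family.
    Raises ``ValueError`` when a beta method-of-moments fit is infeasible
    (sd² ≥ mean·(1 − mean)).
    """
    name, base, lo, hi = estimate.name, estimate.base, estimate.low, estimate.high
    if estimate.is_point:
        return FittedDistribution(name, "point", {"value": base}, base, base, base)
    sd = (hi - lo) / RANGE_TO_SD
    fam = estimate.family
    if fam == "beta":
        v = sd * sd
        m = base
        if v >= m * (1.0 - m):
            raise ValueError(
                f"beta moment fit infeasible for {name!r}: "
                f"sd^2={v:.3g} >= mean(1-mean)={m * (1 - m):.3g}"
            )
        k = m * (1.0 - m) / v - 1.0
        args = {"a": m * k, "b": (1.0 - m) * k}
    elif fam == "gamma":
        v = sd * sd
        args = {"shape": base * base / v, "scale": v / base}
    elif fam == "lognormal":
        args = {
            "mu": math.log(base),
            "sigma": (math.log(hi) - math.log(lo)) / RANGE_TO_SD,
        }
    elif fam == "normal":
        args = {"mean": base, "sd": sd}
    else:  # pragma: no cover - families validated upstream
        raise ValueError(f"cannot fit family {fam!r} for {name!r}")
    return FittedDistribution(name, fam, args, base, lo, hi)


@dataclass
class PSAResult:
    """Full Monte Carlo output: per-draw records plus summary statistics."""

    n_draws: int
    seed: int
    wtp: float
    truncate: bool
    #: parameter draws, one array of length n_draws per sampled parameter
    parameter_draws: dict[str, np.ndarray]
    #: per-strategy per-draw (cost, qalys) arrays, keyed by strategy label
    strategy_draws: dict[str, dict[str, np.ndarray]]
    #: per-comparison per-draw (delta_cost, delta_qalys), keyed
    #: "comparator vs reference"
    comparison_draws: dict[str, dict[str, np.ndarray]]
    #: summary statistics per comparison
    summaries: pd.DataFrame
    n_rejected: int = 0
    strategy_labels: list[str] = field(default_factory=list)


def _summarize(label: str, dc: np.ndarray, dq: np.ndarray, wtp: float) -> dict:
    n = dc.size
    out: dict[str, float | str] = {"comparison": label, "n_draws": n}
    for name, x in (("delta_cost", dc), ("delta_qalys", dq)):
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        half = Z95 * sd / math.sqrt(n)
        out[f"{name}_mean"] = mean
        out[f"{name}_sd"] = sd
        out[f"{name}_ci_low"] = mean - half
        out[f"{name}_ci_high"] = mean + half
    # CE-plane quadrants (paired draws); boundary draws fold into the
    # adjacent weak-dominance quadrant so proportions always sum to 1
    gain = dq > 0.0
    costlier = dc > 0.0
    out["prop_dominant"] = float(np.mean(gain & ~costlier))
    out["prop_trade_off_ne"] = float(np.mean(gain & costlier))
    out["prop_dominated"] = float(np.mean(~gain & costlier))
    out["prop_trade_off_sw"] = float(np.mean(~gain & ~costlier))
    out["prop_qaly_loss"] = float(np.mean(dq < 0.0))
    out["prop_costlier"] = float(np.mean(costlier))
    nmb = wtp * dq - dc
    out["prop_cost_effective"] = float(np.mean(nmb > 0.0))
    return out


def run_psa(
    params: ModelParameters,
    strategies: list[StrategyConfig],
    n_draws: int = 10_000,
    seed: int = 0,
    wtp: float = DEFAULT_WTP,
    truncate: bool = True,
) -> PSAResult:
    """Monte Carlo resampling of all uncertain inputs, paired across arms.

    Parameters are drawn independently, one vector per parameter, in the
    canonical table order (fixed, documented).  Draws that put an effective
    hospitalization probability above 1 for any evaluated strategy are
    rejected and redrawn; the count is recorded.  Consecutive strategies in
    ``strategies`` form the reported comparisons.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not strategies:
        raise ValueError("at least one strategy required")
    rng = np.random.default_rng(seed)
    dists = {
        name: fit_distribution(params[name])
        for name in PARAMETER_ORDER
        if not params[name].is_point
    }

    values: dict[str, np.ndarray | float] = {
        name: params[name].base for name in PARAMETER_ORDER
    }
    for name, dist in dists.items():  # canonical order, one vector each
        values[name] = dist.sample(rng, n_draws, truncate=truncate)

    # reject draws whose composite hospitalization probability leaves [0, 1]
    n_rejected = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        bad = np.zeros(n_draws, dtype=bool)
        for strat in strategies:
            factor = np.asarray(hosp_factor_for(values, strat))
            for d in ("uc", "cd"):
                bad |= np.asarray(values[f"h_{d}"] * factor) > 1.0
        if not bad.any():
            break
        n_rejected += int(bad.sum())
        for name, dist in dists.items():
            col = np.asarray(values[name]).copy()
            col[bad] = dist.sample(rng, int(bad.sum()), truncate=truncate)
            values[name] = col
    else:  # pragma: no cover
        raise RuntimeError("rejection resampling did not converge")

    strategy_draws: dict[str, dict[str, np.ndarray]] = {}
    for strat in strategies:
        hosp, mort, cost, qalys = (
            np.broadcast_to(np.asarray(x, dtype=float), (n_draws,)).copy()
            for x in outcomes_from_values(values, strat)
        )
        strategy_draws[strat.label] = {
            "hosp": hosp,
            "mort": mort,
            "cost": cost,
            "qalys": qalys,
        }

    comparison_draws: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for ref, comp in zip(strategies, strategies[1:]):
        label = f"{comp.label} vs {ref.label}"
        dc = strategy_draws[comp.label]["cost"] - strategy_draws[ref.label]["cost"]
        dq = strategy_draws[comp.label]["qalys"] - strategy_draws[ref.label]["qalys"]
        comparison_draws[label] = {"delta_cost": dc, "delta_qalys": dq}
        rows.append(_summarize(label, dc, dq, wtp))

    return PSAResult(
        n_draws=n_draws,
        seed=seed,
        wtp=wtp,
        truncate=truncate,
        parameter_draws={n: np.asarray(values[n]) for n in dists},
        strategy_draws=strategy_draws,
        comparison_draws=comparison_draws,
        summaries=pd.DataFrame(rows),
        n_rejected=n_rejected,
        strategy_labels=[s.label for s in strategies],
    )


def ce_plane_export(result: PSAResult, comparison: str) -> pd.DataFrame:
    """Cost-effectiveness-plane scatter table for one comparison.

    One row per draw with (delta_qalys, delta_cost); the WTP line slope is
    attached as DataFrame metadata (``attrs['wtp']``).
    """
    if comparison not in result.comparison_draws:
        raise KeyError(
            f"unknown comparison {comparison!r}; "
            f"available: {sorted(result.comparison_draws)}"
        )
    draws = result.comparison_draws[comparison]
    df = pd.DataFrame(
        {
            "draw": np.arange(result.n_draws),
            "delta_qalys": draws["delta_qalys"],
            "delta_cost": draws["delta_cost"],
        }
    )
    df.attrs["wtp"] = result.wtp
    df.attrs["comparison"] = comparison
    df.attrs["seed"] = result.seed
    return df
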