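"""One-way deterministic sensitivity analysis, threshold finding, tornado.

Every model input is varied one at a time over its printed sensitivity
range while all others stay at base case; incremental cost and QALYs of a
strategy pair are re-evaluated at each grid point.  Threshold (root)
finding locates the parameter value at which a chosen incremental quantity
crosses zero — e.g. the avoidance relative risk below which pandemic-era
standard care becomes cheaper than pre-pandemic care.  The tornado ranking
orders parameters by the span of an incremental quantity across their
low/high bounds.

Incremental quantities are monotone (mostly affine) in each single input
here, so plain bisection is used: unconditionally robust, tolerance 1e-6 on
the parameter axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import bisect

from .cohort import StrategyConfig, expected_outcomes
from .economics import DEFAULT_WTP, compare
from .parameters import ModelParameters

__all__ = ["SweepResult", "TornadoEntry", "sweep", "find_threshold", "tornado"]

#: incremental quantities understood by the sweep/threshold/tornado drivers
QUANTITIES = ("delta_cost", "delta_qalys", "icer_minus_wtp", "nmb")

ROOT_XTOL = 1e-6
ROOT_MAXITER = 200


def _quantity(
    params: ModelParameters,
    pair: tuple[StrategyConfig, StrategyConfig],
    quantity: str,
    wtp: float,
) -> float:
    ref, comp = pair
    res = compare(
        expected_outcomes(params, ref), expected_outcomes(params, comp), wtp=wtp
    )
    if quantity == "delta_cost":
        return res.delta_cost
    if quantity == "delta_qalys":
        return res.delta_qalys
    if quantity == "nmb":
        return res.nmb
    if quantity == "icer_minus_wtp":
        if res.delta_qalys == 0.0:
            raise ValueError("ICER undefined: delta_qalys is zero")
        return res.delta_cost / res.delta_qalys - wtp
    raise ValueError(f"unknown quantity {quantity!r} (expected one of {QUANTITIES})")


def incremental_quantity(
    parameter: str,
    value: float,
    pair: tuple[StrategyConfig, StrategyConfig],
    params: ModelParameters,
    quantity: str = "delta_cost",
    wtp: float = DEFAULT_WTP,
) -> float:
    """Incremental ``quantity`` with one parameter moved to ``value``."""
    return _quantity(params.with_base(parameter, value), pair, quantity, wtp)


@dataclass(frozen=True)
class SweepResult:
    """One-way sweep of one parameter: aligned incremental curves."""

    parameter: str
    grid: np.ndarray
    delta_cost_curve: np.ndarray
    delta_qalys_curve: np.ndarray
    thresholds: dict[str, list[float]] = field(default_factory=dict)


def sweep(
    parameter: str,
    pair: tuple[StrategyConfig, StrategyConfig],
    params: ModelParameters,
    n_grid: int = 101,
    wtp: float = DEFAULT_WTP,
) -> SweepResult:
    """Evaluate incremental cost/QALY curves over a parameter's range.

    The grid spans the parameter's printed [low, high] with ``n_grid``
    evenly spaced points; zero crossings of either curve are refined by
    bisection and reported as thresholds.
    """
    if parameter not in params:
        raise KeyError(f"unknown parameter {parameter!r}")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    est = params[parameter]
    grid = np.linspace(est.low, est.high, n_grid)
    dc = np.empty(n_grid)
    dq = np.empty(n_grid)
    ref, comp = pair
    for i, x in enumerate(grid):
        p = params.with_base(parameter, float(x))
        res = compare(
            expected_outcomes(p, ref), expected_outcomes(p, comp), wtp=wtp
        )
        dc[i] = res.delta_cost
        dq[i] = res.delta_qalys
    thresholds: dict[str, list[float]] = {}
    for name, curve in (("delta_cost", dc), ("delta_qalys", dq)):
        roots = []
        for i in range(n_grid - 1):
            if np.sign(curve[i]) * np.sign(curve[i + 1]) < 0:
                root = find_threshold(
                    parameter,
                    name,
                    pair,
                    params,
                    (float(grid[i]), float(grid[i + 1])),
                    wtp=wtp,
                )
                if root is not None:
                    roots.append(root)
        if roots:
            thresholds[name] = roots
    return SweepResult(parameter, grid, dc, dq, thresholds)


def find_threshold(
    parameter: str,
    quantity: str,
    pair: tuple[StrategyConfig, StrategyConfig],
    params: ModelParameters,
    search_interval: tuple[float, float],
    wtp: float = DEFAULT_WTP,
) -> float | None:
    """Parameter value at which an incremental quantity crosses zero.

    Bisection on ``search_interval`` (which may extend beyond the printed
    sensitivity range); returns ``None`` when the quantity has the same
    sign at both endpoints.
    """
    if parameter not in params:
        raise KeyError(f"unknown parameter {parameter!r}")
    lo, hi = search_interval
    if not (lo < hi):
        raise ValueError("search_interval must satisfy lo < hi")

    def g(x: float) -> float:
        return incremental_quantity(parameter, x, pair, params, quantity, wtp)

    g_lo, g_hi = g(lo), g(hi)
    if not (np.isfinite(g_lo) and np.isfinite(g_hi)):
        raise ValueError(
            f"{quantity} non-finite at a search endpoint for {parameter!r}"
        )
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if np.sign(g_lo) == np.sign(g_hi):
        return None
    return float(bisect(g, lo, hi, xtol=ROOT_XTOL, maxiter=ROOT_MAXITER))


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of a tornado diagram."""

    parameter: str
    at_low: float
    at_high: float
    span: float


def tornado(
    parameters: list[str],
    pair: tuple[StrategyConfig, StrategyConfig],
    params: ModelParameters,
    quantity: str = "nmb",
    wtp: float = DEFAULT_WTP,
) -> list[TornadoEntry]:
    """Rank parameters by influence on an incremental quantity.

    Each parameter is set to its printed low and high bound (others at
    base); entries are sorted by descending span.  The default quantity is
    net monetary benefit: with a dominant base case the ICER is undefined
    along much of each bar, and NMB is its well-defined monotone analogue.
    """
    if not parameters:
        raise ValueError("at least one parameter required")
    entries = []
    for name in parameters:
        est = params[name]
        lo_val = incremental_quantity(name, est.low, pair, params, quantity, wtp)
        hi_val = incremental_quantity(name, est.high, pair, params, quantity, wtp)
        entries.append(
            TornadoEntry(name, lo_val, hi_val, abs(hi_val - lo_val))
        )
    return sorted(entries, key=lambda e: e.span, reverse=True)
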