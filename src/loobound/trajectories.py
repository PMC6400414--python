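"""Null-model weight as a function of sample size: curves, shapes, extrema.

For a two-model comparison the LOO weight of the null is the logistic of
Δelpd_loo, w0(n) = 1/(1 + exp(-Δelpd(n))).  These trajectories reproduce the
published weight-versus-n curves for the standard prior grids:

* induction — Beta(1,5), Beta(5,5), Beta(2,2), Beta(1,1), Beta(0.5,0.5);
  asymptotes logistic(b), so the curves order by b even at n = ∞.
* chance    — the same five Beta priors; one shared asymptote e/(1+e).
* normal    — N(0,3²), N(0,1.5²), N(0,1), N(0,0.5²); shared asymptote
  e/(1+e).

The interesting qualitative behaviours are classified from the discrete
curve (monotone increasing / decreasing / nonmonotone) and, for the
continuous-n closed forms, located exactly: some priors (Jeffreys
Beta(0.5, 0.5); wide normal priors) make the weight *decrease* as perfectly
null-consistent data accumulate, and others (Beta(1,5) in the chance
example, N(0, 2.035²)) produce an interior maximum — support that first
rises, then falls toward the bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .closed_forms import EXAMPLE_IDS, delta_elpd, limits
from .loo import BetaPrior, NormalMeanPrior

__all__ = [
    "Trajectory",
    "FIGURE_PRIORS",
    "default_n_grid",
    "weight_trajectory",
    "classify_shape",
    "find_interior_extremum",
    "figure_data",
]


@dataclass(frozen=True)
class Trajectory:
    """w0 over a grid of sample sizes, with shape label and analytic asymptote."""

    example_id: str
    prior: object
    n_grid: tuple[float, ...]
    w0_values: tuple[float, ...]
    asymptote: float
    shape: str


# Prior grids of the three published figures, keyed by figure number.
FIGURE_PRIORS = {
    1: [("a", BetaPrior(1, 5)), ("b", BetaPrior(5, 5)), ("c", BetaPrior(2, 2)),
        ("d", BetaPrior(1, 1)), ("e", BetaPrior(0.5, 0.5))],
    2: [("a", BetaPrior(1, 5)), ("b", BetaPrior(5, 5)), ("c", BetaPrior(2, 2)),
        ("d", BetaPrior(1, 1)), ("e", BetaPrior(0.5, 0.5))],
    3: [("a", NormalMeanPrior(9.0)), ("b", NormalMeanPrior(2.25)),
        ("c", NormalMeanPrior(1.0)), ("d", NormalMeanPrior(0.25))],
}
_FIGURE_EXAMPLE = {1: "induction", 2: "chance", 3: "normal_mean"}


def default_n_grid(example_id: str, n_max: float = 1e6) -> tuple[float, ...]:
    """Dense small-n grid plus a geometric tail out to ``n_max``.

    induction: 1..200 then geometric; chance: even 2..400 then geometric
    rounded to even; normal: 2..200 then geometric.  The dense part covers
    the visual range of the published curves, the tail probes the asymptote.
    """
    if example_id == "induction":
        dense = np.arange(1, 201)
    elif example_id == "chance":
        dense = np.arange(2, 401, 2)
    elif example_id == "normal_mean":
        dense = np.arange(2, 201)
    else:
        raise ValueError(f"unknown example {example_id!r}; expected one of {EXAMPLE_IDS}")
    start = dense[-1]
    tail = np.geomspace(start, n_max, 80)
    tail = np.unique(np.round(tail).astype(np.int64))
    if example_id == "chance":
        tail = np.unique((np.round(tail / 2) * 2).astype(np.int64))
        tail = tail[tail >= 2]
    grid = np.unique(np.concatenate([dense, tail]))
    grid = grid[grid <= n_max]
    return tuple(float(v) for v in grid)


def weight_trajectory(
    example_id: str,
    prior,
    n_grid: Optional[Sequence[float]] = None,
    *,
    tolerance: float = 1e-12,
) -> Trajectory:
    """Compute w0(n) = logistic(Δelpd(n)) over a grid and classify its shape."""
    if n_grid is None:
        n_grid = default_n_grid(example_id)
    grid = tuple(float(v) for v in n_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("n_grid must be strictly increasing")
    w0 = tuple(_logistic(delta_elpd(example_id, prior, n)) for n in grid)
    return Trajectory(
        example_id=example_id,
        prior=prior,
        n_grid=grid,
        w0_values=w0,
        asymptote=limits(example_id, prior).w0_limit,
        shape=classify_shape(w0, tolerance=tolerance),
    )


def classify_shape(w0_values: Sequence[float], tolerance: float = 1e-12) -> str:
    """Label a curve monotone_increasing / monotone_decreasing / nonmonotone.

    Differences within ±tolerance count as flat; a monotone label requires
    every difference on the right side of the tolerance band and at least
    one strictly beyond it.
    """
    v = np.asarray(w0_values, dtype=float)
    if v.size < 3:
        raise ValueError("shape classification needs at least 3 points")
    d = np.diff(v)
    if np.all(d >= -tolerance) and np.any(d > tolerance):
        return "monotone_increasing"
    if np.all(d <= tolerance) and np.any(d < -tolerance):
        return "monotone_decreasing"
    return "nonmonotone"


def find_interior_extremum(
    example_id: str,
    prior,
    n_range: tuple[float, float] = (2.0, 1e6),
    *,
    scan_points: int = 400,
) -> Optional[float]:
    """Locate a stationary point of Δelpd(n) in the open range, if any.

    Scans a geometric grid for a sign change of the central-difference
    derivative (step h = max(1e-4 n, 1e-3)), then refines the crossing by
    bisection.  Returns the continuous n* of the first interior extremum, or
    None when Δelpd is monotone over the range.  The closed forms are smooth
    in real n, so non-integer n* is meaningful.
    """
    lo, hi = float(n_range[0]), float(n_range[1])
    if not lo < hi:
        raise ValueError("n_range must be an increasing pair")

    def deriv(n: float) -> float:
        h = max(1e-4 * n, 1e-3)
        return (
            delta_elpd(example_id, prior, n + h)
            - delta_elpd(example_id, prior, n - h)
        ) / (2.0 * h)

    # keep n - h valid at the left edge
    left = max(lo, (1.0 if example_id == "induction" else 2.0) + 1e-2)
    grid = np.geomspace(left, hi, scan_points)
    vals = [deriv(float(n)) for n in grid]
    for (n1, d1), (n2, d2) in zip(zip(grid, vals), zip(grid[1:], vals[1:])):
        if d1 == 0.0:
            return float(n1) if n1 > left else None
        if d1 * d2 < 0:
            return float(brentq(deriv, float(n1), float(n2), xtol=1e-6, rtol=1e-10))
    return None


def figure_data(figure_id: int, n_max: float = 1e6) -> pd.DataFrame:
    """Curve data for one of the three published weight-vs-n figures.

    Returns a tidy frame with columns ``case``, ``prior``, ``n``, ``w0``,
    ``asymptote`` — one row per (case, n) — suitable for plotting each case
    with a dotted horizontal line at its asymptote.
    """
    if figure_id not in FIGURE_PRIORS:
        raise ValueError(f"unknown figure id {figure_id!r}; expected 1, 2 or 3")
    example_id = _FIGURE_EXAMPLE[figure_id]
    rows = []
    for label, prior in FIGURE_PRIORS[figure_id]:
        traj = weight_trajectory(example_id, prior, default_n_grid(example_id, n_max))
        for n, w0 in zip(traj.n_grid, traj.w0_values):
            rows.append(
                {
                    "case": label,
                    "prior": _prior_label(prior),
                    "n": n,
                    "w0": w0,
                    "asymptote": traj.asymptote,
                }
            )
    return pd.DataFrame(rows)


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _prior_label(prior) -> str:
    if isinstance(prior, BetaPrior):
        return f"Beta({prior.a:g},{prior.b:g})"
    return f"N(0,{prior.sigma0_sq:g})"
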