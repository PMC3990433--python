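"""One-at-a-time replacement screening.

Each candidate variable is individually replaced by a constant fitted by
minimising the weighted RSS, constrained to the range the variable takes in
the run of the full (unreduced) model.  Switch variables are pinned to their
documented off value without optimisation.  The resulting RSS ratios
(reduced / full) rank variables and pick the candidate set for the
multi-factorial stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import SimulationError
from .model_core import ModelSpec, ReplacementState, list_replaceable, simulate
from .skill_metrics import ObservationSet, weighted_rss

__all__ = [
    "ScreeningRow",
    "CandidateSet",
    "fit_replacement_constant",
    "screen_all",
    "select_candidates",
    "screening_frame",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.1
DEFAULT_GRID_POINTS = 25


@dataclass(frozen=True)
class ScreeningRow:
    """Outcome of replacing one variable with its best constant."""

    variable: str
    constant: float
    bounds: tuple[float, float]
    rss_reduced: float
    rss_ratio: float
    included: bool
    note: str = ""


@dataclass(frozen=True)
class CandidateSet:
    """Ordered candidate variables and their frozen replacement constants."""

    names: tuple[str, ...]
    constants: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate candidate names")
        missing = set(self.names) - set(self.constants)
        if missing:
            raise ValueError(f"no constant for candidate(s): {sorted(missing)}")

    def __len__(self):
        return len(self.names)


def _rss_at_constant(spec, drivers, obs, name, value) -> float:
    """RSS with only `name` replaced; simulation failure counts as +inf."""
    try:
        traj = simulate(spec, drivers, ReplacementState({name: float(value)}))
    except SimulationError:
        return math.inf
    return weighted_rss(obs, traj)


def fit_replacement_constant(
    spec: ModelSpec,
    drivers,
    obs: ObservationSet,
    name: str,
    full_traj=None,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> tuple[float, float]:
    """Best in-range constant for one variable and the resulting RSS.

    A coarse grid over the variable's full-model range is refined with a
    bounded scalar search around the best grid point; the objective can be
    non-smooth because the constant threads through conditionals, so the
    grid stage guards against local minima.  Ties break toward the smallest
    constant.  Switch variables skip optimisation: their constant is the
    documented off value.
    """
    var = spec.variable(name)
    if full_traj is None:
        full_traj = simulate(spec, drivers, ReplacementState.empty())
    if var.is_switch:
        const = float(var.off_value)
        return const, _rss_at_constant(spec, drivers, obs, name, const)
    lo, hi = full_traj.variable_range(name)
    if lo == hi:
        return lo, _rss_at_constant(spec, drivers, obs, name, lo)
    grid = np.linspace(lo, hi, grid_points)
    scores = np.array(
        [_rss_at_constant(spec, drivers, obs, name, c) for c in grid]
    )
    if not np.isfinite(scores).any():
        return lo, math.inf
    best_score = scores.min()
    # tie-break toward the smallest constant within a relative tolerance
    tol = 1e-9 * max(1.0, abs(best_score))
    best_idx = int(np.flatnonzero(scores <= best_score + tol)[0])
    best_c, best_rss = float(grid[best_idx]), float(scores[best_idx])
    # bounded refinement in the bracket around the best grid point
    lo_b = float(grid[max(best_idx - 1, 0)])
    hi_b = float(grid[min(best_idx + 1, len(grid) - 1)])
    if hi_b > lo_b:
        res = minimize_scalar(
            lambda c: _rss_at_constant(spec, drivers, obs, name, c),
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": 1e-8 * (hi - lo)},
        )
        if np.isfinite(res.fun) and res.fun < best_rss - tol:
            best_c, best_rss = float(res.x), float(res.fun)
    return best_c, best_rss


def screen_all(
    spec: ModelSpec,
    drivers,
    obs: ObservationSet,
    exclusions=(),
    threshold: float = DEFAULT_THRESHOLD,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> list[ScreeningRow]:
    """Screen every replaceable, non-excluded variable one at a time."""
    full_traj = simulate(spec, drivers, ReplacementState.empty())
    rss_full = weighted_rss(obs, full_traj)
    names = list_replaceable(spec, exclusions)
    log.info("screening %d variables (rss_full=%.4g)", len(names), rss_full)
    rows = []
    for name in names:
        var = spec.variable(name)
        if var.is_switch:
            bounds = (float(var.off_value), float(var.off_value))
        else:
            bounds = full_traj.variable_range(name)
        const, rss_reduced = fit_replacement_constant(
            spec, drivers, obs, name, full_traj=full_traj, grid_points=grid_points
        )
        if math.isfinite(rss_reduced):
            ratio = rss_reduced / rss_full
            note = "switch: constant pinned to off value" if var.is_switch else ""
            included = ratio <= threshold
        else:
            ratio = math.inf
            note = "simulation failed for every trial constant"
            included = False
        rows.append(
            ScreeningRow(
                variable=name,
                constant=const,
                bounds=bounds,
                rss_reduced=rss_reduced,
                rss_ratio=ratio,
                included=included,
                note=note,
            )
        )
        log.debug("screened %s: constant=%.4g ratio=%.4g", name, const, ratio)
    return rows


def select_candidates(rows, threshold: float = DEFAULT_THRESHOLD) -> CandidateSet:
    """Variables whose individual replacement kept RSS within the threshold.

    The fitted constants are carried over unchanged into the factorial
    stage; they are never refitted per combination.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive: {threshold}")
    keep = [r for r in rows if math.isfinite(r.rss_ratio) and r.rss_ratio <= threshold]
    return CandidateSet(
        names=tuple(r.variable for r in keep),
        constants={r.variable: r.constant for r in keep},
    )


def screening_frame(rows) -> pd.DataFrame:
    """Tabular report of the screening stage."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "constant": [r.constant for r in rows],
            "lower": [r.bounds[0] for r in rows],
            "upper": [r.bounds[1] for r in rows],
            "rss_reduced": [r.rss_reduced for r in rows],
            "rss_ratio": [r.rss_ratio for r in rows],
            "included": [r.included for r in rows],
            "note": [r.note for r in rows],
        }
    )
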