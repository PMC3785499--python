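"""Steady states, Jacobian stability and qualitative (bifurcation) conditions.

Steady states solve ``rhs(y*, params, input) = 0``.  For one-variable models
the default finder brackets sign changes of the right-hand side on a dense
grid over a guaranteed search interval and refines each bracket with Brent's
method (exact zeros at grid points are kept as roots directly); for
multi-variable models it runs Newton-Raphson from a regular grid of starting
points.  Stability comes from the eigenvalues of the Jacobian at the root:
all real parts negative means stable, any positive means unstable, and a
maximum real part within ``MARGINAL_BAND`` of zero is labelled marginal.

A :class:`ConditionSpec` declares a bifurcation pattern as a conjunction of
clauses, each requiring exact stable/unstable counts at one input level and
optionally thresholds on the low/high stable branch; :func:`evaluate_condition`
maps it to the 0/1 qualitative fitness value.  Marginal steady states make a
clause fail (conditions demand robust counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from ._kernels import MARGINAL_BAND, N_GRID_1D, NEWTON_TOL
from .models import ConfigurationError, ODEModelSpec, ParameterVector

logger = logging.getLogger(__name__)

__all__ = [
    "SteadyState",
    "ConditionClause",
    "ConditionSpec",
    "find_steady_states",
    "classify_stability",
    "evaluate_condition",
    "toy_condition_B",
    "toy_condition_I",
    "bifurcation_diagram",
]

DEDUP_RADIUS = 1e-6
MAX_NEWTON_ITER = 100


@dataclass
class SteadyState:
    """An equilibrium with its stability label and Jacobian spectrum."""

    state: np.ndarray
    stability: str  # "stable" | "unstable" | "marginal"
    eigenvalues: np.ndarray


# ---------------------------------------------------------------------------
# condition specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdClause:
    """Branch-level output requirement, e.g. low stable branch of C3* <= 1 nM."""

    state_name: str
    branch: str  # "lower" | "higher" (stable branch with min/max value of state)
    comparator: str  # "le" | "ge"
    value: float

    def holds(self, branch_value: float) -> bool:
        if self.comparator == "le":
            return branch_value <= self.value
        if self.comparator == "ge":
            return branch_value >= self.value
        raise ConfigurationError(f"unknown comparator {self.comparator!r}")


@dataclass(frozen=True)
class ConditionClause:
    input_value: float
    n_stable: int
    n_unstable: int
    thresholds: tuple[ThresholdClause, ...] = ()


@dataclass(frozen=True)
class ConditionSpec:
    """Named conjunction of clauses; evaluates to 1 iff every clause holds."""

    name: str
    clauses: tuple[ConditionClause, ...]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "clauses": [
                {
                    "input_value": c.input_value,
                    "n_stable": c.n_stable,
                    "n_unstable": c.n_unstable,
                    "thresholds": [
                        {
                            "state_name": t.state_name,
                            "branch": t.branch,
                            "comparator": t.comparator,
                            "value": t.value,
                        }
                        for t in c.thresholds
                    ],
                }
                for c in self.clauses
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionSpec":
        clauses = []
        for c in d["clauses"]:
            thr = tuple(
                ThresholdClause(
                    t["state_name"], t["branch"], t["comparator"], float(t["value"])
                )
                for t in c.get("thresholds", [])
            )
            clauses.append(
                ConditionClause(
                    float(c["input_value"]), int(c["n_stable"]), int(c["n_unstable"]), thr
                )
            )
        return cls(d["name"], tuple(clauses))


def toy_condition_B() -> ConditionSpec:
    """Bistability of the toy model: saddle-node structure at k_s = 0.2,
    a single stable state at k_s = 0.3 and at k_s = 1.0."""
    return ConditionSpec(
        "B",
        (
            ConditionClause(0.2, 2, 1),
            ConditionClause(0.3, 1, 0),
            ConditionClause(1.0, 1, 0),
        ),
    )


def toy_condition_I() -> ConditionSpec:
    """Irreversibility: bistability plus persistence of the high branch at
    zero input (two stable + one unstable steady state at k_s = 0)."""
    return ConditionSpec(
        "I",
        toy_condition_B().clauses + (ConditionClause(0.0, 2, 1),),
    )


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------


def _jacobian_at(model: ODEModelSpec, params_map, input_value: float, state: np.ndarray) -> np.ndarray:
    if model.jacobian is not None:
        J = np.atleast_2d(np.asarray(model.jacobian(state, params_map, input_value), dtype=float))
    else:
        n = model.n_states
        J = np.empty((n, n))
        for j in range(n):
            h = 1e-6 * max(1.0, abs(state[j]))
            xp = state.copy()
            xm = state.copy()
            xp[j] += h
            xm[j] = max(xm[j] - h, 0.0)
            J[:, j] = (
                np.asarray(model.rhs(xp, params_map, input_value))
                - np.asarray(model.rhs(xm, params_map, input_value))
            ) / (xp[j] - xm[j])
    if not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite Jacobian at steady state")
    return J


def classify_stability(
    model: ODEModelSpec, params, input_value: float, state
) -> SteadyState:
    """Label a verified root via the Jacobian eigenvalue spectrum."""
    state = np.atleast_1d(np.asarray(state, dtype=float))
    p = model.full_params(params)
    J = _jacobian_at(model, p, input_value, state)
    eig = np.linalg.eigvals(J)
    m = float(np.max(eig.real))
    if abs(m) < MARGINAL_BAND:
        label = "marginal"
    elif m < 0:
        label = "stable"
    else:
        label = "unstable"
    return SteadyState(state, label, eig)


# ---------------------------------------------------------------------------
# root finding
# ---------------------------------------------------------------------------


def _resolve_box(model: ODEModelSpec, params_map, input_value, search_box) -> np.ndarray:
    if search_box is not None:
        box = np.atleast_2d(np.asarray(search_box, dtype=float))
    elif model.dynamic_search_box is not None:
        box = np.atleast_2d(model.dynamic_search_box(params_map, input_value))
    elif model.search_box is not None:
        box = np.atleast_2d(model.search_box)
    else:
        raise ConfigurationError(f"model {model.name!r} has no steady-state search box")
    if box.shape != (model.n_states, 2) or not np.all(np.isfinite(box)):
        raise ConfigurationError("search box must be finite with one (lo, hi) per state")
    return box


def _find_1d(model, params_map, input_value, box, n_grid) -> list[float]:
    lo, hi = box[0]
    grid = np.linspace(lo, hi, n_grid)
    if model.rhs_grid_1d is not None:
        f = np.asarray(model.rhs_grid_1d(grid, params_map, input_value), dtype=float)
    else:
        f = np.array(
            [float(model.rhs(np.array([y]), params_map, input_value)[0]) for y in grid]
        )

    def scalar_f(y):
        return float(model.rhs(np.array([y]), params_map, input_value)[0])

    roots: list[float] = []
    for i in range(n_grid):
        if f[i] == 0.0:
            roots.append(float(grid[i]))
        elif i > 0 and f[i - 1] != 0.0 and (f[i - 1] > 0) != (f[i] > 0):
            roots.append(float(brentq(scalar_f, grid[i - 1], grid[i], xtol=1e-14, rtol=1e-15)))
    return roots


def _newton_multistart(model, params_map, input_value, box, n_starts) -> list[np.ndarray]:
    n = model.n_states
    axes = [np.linspace(box[d, 0], box[d, 1], n_starts) for d in range(n)]
    mesh = np.meshgrid(*axes, indexing="ij")
    starts = np.stack([m.ravel() for m in mesh], axis=1)
    roots: list[np.ndarray] = []
    for x0 in starts:
        x = x0.astype(float).copy()
        for _ in range(MAX_NEWTON_ITER):
            try:
                fx = np.atleast_1d(np.asarray(model.rhs(x, params_map, input_value), dtype=float))
                if np.max(np.abs(fx)) <= NEWTON_TOL:
                    break
                J = _jacobian_at(model, params_map, input_value, x)
                step = np.linalg.solve(J, fx)
            except (np.linalg.LinAlgError, FloatingPointError, ValueError):
                x = None
                break
            # project onto the search box (keeps iterates in the rhs domain)
            x = np.clip(x - step, box[:, 0], box[:, 1])
            if not np.all(np.isfinite(x)):
                x = None
                break
        else:
            x = None
        if x is None:
            continue
        fx = np.atleast_1d(np.asarray(model.rhs(x, params_map, input_value), dtype=float))
        if np.max(np.abs(fx)) > NEWTON_TOL:
            continue
        # keep roots inside the search box (small slack for numerics)
        slack = 1e-9 * np.maximum(1.0, np.abs(box).max(axis=1))
        if np.any(x < box[:, 0] - slack) or np.any(x > box[:, 1] + slack):
            continue
        if all(np.max(np.abs(x - r)) > DEDUP_RADIUS for r in roots):
            roots.append(x)
    return roots


def find_steady_states(
    model: ODEModelSpec,
    params,
    input_value: float,
    search_box=None,
    n_starts: int | None = None,
    method: str = "auto",
) -> list[SteadyState]:
    """All steady states at one input level, classified and sorted.

    ``method``: "bracket" (1-D grid sign-change + Brent refinement),
    "newton" (multi-start Newton-Raphson) or "auto" (bracket for 1-D models,
    Newton otherwise).  Returns an empty list when no start converges.
    Results are deduplicated (radius 1e-6), re-verified against the root
    tolerance and sorted by the first state coordinate.
    """
    p = model.full_params(params)
    box = _resolve_box(model, p, input_value, search_box)
    if method == "auto":
        method = "bracket" if model.n_states == 1 else "newton"
    if method == "bracket":
        if model.n_states != 1:
            raise ConfigurationError("bracket method requires a one-variable model")
        n_grid = N_GRID_1D if n_starts is None else int(n_starts)
        raw = [np.array([r]) for r in _find_1d(model, p, input_value, box, n_grid)]
        # dedup (a refined bracket can land on an exact-zero grid point)
        roots: list[np.ndarray] = []
        for x in raw:
            if all(np.max(np.abs(x - r)) > DEDUP_RADIUS for r in roots):
                roots.append(x)
    elif method == "newton":
        ns = 50 if n_starts is None else int(n_starts)
        roots = _newton_multistart(model, p, input_value, box, ns)
    else:
        raise ConfigurationError(f"unknown method {method!r}")

    out = [classify_stability(model, params, input_value, x) for x in roots]
    out.sort(key=lambda s: s.state[0])
    return out


# ---------------------------------------------------------------------------
# condition evaluation
# ---------------------------------------------------------------------------


def evaluate_condition(
    spec: ConditionSpec,
    model: ODEModelSpec,
    params,
    **finder_kwargs,
) -> int:
    """Indicator value I(C(theta)) in {0, 1}.

    1 iff every clause's stable/unstable counts match exactly, no steady
    state is marginal, and all branch thresholds hold.  Numerical failures
    during root finding map to 0 with a logged warning.
    """
    for clause in spec.clauses:
        for t in clause.thresholds:
            model.state_index(t.state_name)  # fail fast on unknown names
        try:
            states = find_steady_states(model, params, clause.input_value, **finder_kwargs)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            logger.warning("condition %s: root finding failed (%s) -> 0", spec.name, exc)
            return 0
        n_stable = sum(1 for s in states if s.stability == "stable")
        n_unstable = sum(1 for s in states if s.stability == "unstable")
        n_marginal = sum(1 for s in states if s.stability == "marginal")
        if n_marginal > 0:
            return 0
        if n_stable != clause.n_stable or n_unstable != clause.n_unstable:
            return 0
        for t in clause.thresholds:
            idx = model.state_index(t.state_name)
            stable_vals = sorted(s.state[idx] for s in states if s.stability == "stable")
            branch_value = stable_vals[0] if t.branch == "lower" else stable_vals[-1]
            if not t.holds(branch_value):
                return 0
    return 1


def bifurcation_diagram(
    model: ODEModelSpec,
    params,
    input_values: Sequence[float],
    **finder_kwargs,
):
    """Sweep the input and tabulate branches: rows (input, branch, states..., stability)."""
    import pandas as pd

    rows = []
    for u in input_values:
        for b, s in enumerate(find_steady_states(model, params, u, **finder_kwargs)):
            rows.append(
                {
                    model.input_name: u,
                    "branch": b,
                    **{n: s.state[i] for i, n in enumerate(model.state_names)},
                    "stability": s.stability,
                }
            )
    return pd.DataFrame(rows)
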