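"""Metropolis-Hastings sampling against a hybrid-fitness target.

The target density over the log10 parameter box is

    w(theta) = prod_j I(C_j(theta)) * prod_i f_quant_i(z_i(theta)) * pi(theta)

with a flat prior pi inside the box (zero outside), indicator-valued
qualitative fitness measures I(C_j) from bifurcation analysis, and
real-valued quantitative fitness measures evaluated on observables z_i of a
single deterministic simulation.  Proposals perturb one uniformly chosen
coordinate on the log10 scale, either uniformly in +-sigma_q or by a
Normal(0, sigma_q) step; both are symmetric, so the acceptance probability
reduces to min(1, w'/w).  Out-of-box proposals are rejected outright, and
the chain never occupies a zero-weight state.

Qualitative indicators are evaluated before any dynamics run (short-circuit:
a failed condition costs no integration); the current weight is cached and
replaced only on acceptance.  Rejected steps repeat the current state in the
thinned record.

For the built-in toy model with histogram fitness on the execution time and
endpoint observables the whole chain runs in a compiled kernel; the generic
pure-Python path handles every other model/fitness combination and is
asserted (in the test suite) to produce identical weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .bifurcation import ConditionSpec, evaluate_condition
from .fitness import (
    HistogramFitness,
    LogNormalFitness,
    endpoint_value,
    execution_time,
    switching_time,
)
from .models import (
    ConfigurationError,
    IntegrationError,
    ODEModelSpec,
    ParameterVector,
    Trajectory,
    integrate_rk4,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "InferenceProblem",
    "Trace",
    "ChainStateError",
    "InitializationError",
    "propose",
    "target_weight",
    "acceptance_probability",
    "run_mcmc_hfm",
    "metropolis_chain",
    "default_extractors",
]


class ChainStateError(RuntimeError):
    """The chain reached a state that violates an invariant (e.g. zero weight)."""


class InitializationError(RuntimeError):
    """No positive-weight initial state found within the configured budget."""


@dataclass
class MCMCConfig:
    """Chain settings: lengths, proposal and seed.

    ``sigma_q`` is the half-width (uniform kind) or standard deviation
    (normal kind) of the single-coordinate log10 proposal.  ``init`` is
    either "reference" (start from the problem's reference vector, falling
    back to prior rejection sampling if it has zero weight) or an explicit
    :class:`ParameterVector`.
    """

    n_steps: int
    burn_in: int = 0
    thin: int = 1
    sigma_q: float = 0.5
    proposal_kind: str = "uniform"  # "uniform" | "normal"
    seed: int = 0
    init: ParameterVector | str = "reference"
    init_budget: int = 100_000

    def __post_init__(self):
        if self.burn_in >= self.n_steps:
            raise ConfigurationError("burn_in must be < n_steps")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.sigma_q <= 0:
            raise ConfigurationError("sigma_q must be > 0")
        if self.proposal_kind not in ("uniform", "normal"):
            raise ConfigurationError("proposal_kind must be 'uniform' or 'normal'")

    @property
    def n_recorded(self) -> int:
        return (self.n_steps - self.burn_in) // self.thin


@dataclass
class InferenceProblem:
    """Everything the target weight needs: model, conditions, fitness, simulation plan.

    ``prior`` carries the parameter names, prior box and reference values.
    ``sim_input`` is the input level of the deterministic run supplying the
    quantitative observables; ``extractors`` maps observable names to
    ``Trajectory -> float`` callables.
    """

    model: ODEModelSpec
    prior: ParameterVector
    conditions: list[ConditionSpec] = field(default_factory=list)
    quantitative: list[HistogramFitness | LogNormalFitness] = field(default_factory=list)
    sim_input: float = 1.0
    y0: np.ndarray | None = None
    t_end: float | None = None
    dt: float | None = None
    extractors: dict[str, Callable[[Trajectory], float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.y0 is None:
            self.y0 = np.zeros(self.model.n_states)
        if self.t_end is None:
            self.t_end = self.model.default_t_end
        if self.dt is None:
            self.dt = self.model.default_dt
        if not self.extractors:
            self.extractors = default_extractors(self.model)
        for f in self.quantitative:
            if f.observable_name not in self.extractors:
                raise ConfigurationError(
                    f"no extractor for observable {f.observable_name!r}"
                )


def default_extractors(model: ODEModelSpec) -> dict[str, Callable[[Trajectory], float]]:
    """Standard observables on the model's output (first) state."""
    out = model.state_names[0]
    return {
        "T_e": lambda tr: execution_time(tr, out, 0.9),
        "T_s": lambda tr: switching_time(tr, out, 0.025, 0.975),
        "Y_end": lambda tr: endpoint_value(tr, out, tr.times[-1]),
    }


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def propose(
    current: ParameterVector,
    sigma_q: float,
    proposal_kind: str,
    rng: np.random.Generator,
) -> tuple[ParameterVector, int]:
    """Perturb one uniformly chosen coordinate on the log10 scale.

    Uniform kind: theta'_j = theta_j + sigma_q*(2r - 1), r ~ U(0,1);
    normal kind: theta'_j = theta_j + sigma_q*eps, eps ~ N(0,1).  Both are
    symmetric.  The candidate may leave the prior box; the caller decides
    what to do with it.
    """
    k = len(current.names)
    j = int(rng.integers(0, k))
    if proposal_kind == "normal":
        delta = sigma_q * rng.normal(0.0, 1.0)
    elif proposal_kind == "uniform":
        delta = sigma_q * (2.0 * rng.uniform(0.0, 1.0) - 1.0)
    else:
        raise ConfigurationError(f"unknown proposal kind {proposal_kind!r}")
    return current.replace_log10(j, current.log10_values[j] + delta), j


def target_weight(
    problem: InferenceProblem, params: ParameterVector
) -> tuple[float, dict]:
    """Hybrid-fitness weight of one parameter vector, with per-term breakdown.

    Out-of-box vectors score 0 without any simulation; qualitative
    indicators are evaluated next (any 0 short-circuits); a single
    deterministic run then supplies every quantitative observable.
    Integration failures score 0 with a logged warning.
    """
    breakdown: dict[str, float] = {}
    if not params.in_bounds():
        return 0.0, {"prior": 0.0}
    for cond in problem.conditions:
        ind = evaluate_condition(cond, problem.model, params)
        breakdown[f"I({cond.name})"] = float(ind)
        if ind == 0:
            return 0.0, breakdown
    w = 1.0
    if problem.quantitative:
        try:
            traj = integrate_rk4(
                problem.model,
                params,
                problem.sim_input,
                problem.y0,
                problem.t_end,
                problem.dt,
            )
        except IntegrationError as exc:
            logger.warning("integration failed (%s) -> weight 0", exc)
            breakdown["integration"] = 0.0
            return 0.0, breakdown
        for f in problem.quantitative:
            z = problem.extractors[f.observable_name](traj)
            fv = f(z)
            breakdown[f"f({f.observable_name})"] = fv
            w *= fv
    return w, breakdown


def acceptance_probability(weight_candidate: float, weight_current: float) -> float:
    """min(1, w'/w); the symmetric proposal and flat prior have cancelled."""
    if weight_current <= 0:
        raise ChainStateError("chain must never occupy a zero-weight state")
    if weight_candidate <= 0:
        return 0.0
    return min(1.0, weight_candidate / weight_current)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """Thinned post-burn-in samples with fitness values and acceptance bookkeeping."""

    names: tuple[str, ...]
    samples: np.ndarray  # (n_recorded, n_params) log10 values
    weights: np.ndarray  # per-sample product of quantitative fitness values
    accept_count: np.ndarray  # per-parameter accepted proposals
    propose_count: np.ndarray  # per-parameter proposals
    config: MCMCConfig
    bounds: np.ndarray

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def acceptance_rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.accept_count / self.propose_count

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def to_csv(self, csv_path) -> None:
        import json

        import pandas as pd

        csv_path = str(csv_path)
        df = pd.DataFrame(self.samples, columns=[f"log10_{n}" for n in self.names])
        df.insert(0, "step", np.arange(len(df)))
        df["weight"] = self.weights
        df.to_csv(csv_path, index=False)
        sidecar = {
            "names": list(self.names),
            "bounds": self.bounds.tolist(),
            "seed": self.config.seed,
            "n_steps": self.config.n_steps,
            "burn_in": self.config.burn_in,
            "thin": self.config.thin,
            "sigma_q": self.config.sigma_q,
            "proposal_kind": self.config.proposal_kind,
            "acceptance_rate": self.acceptance_rate.tolist(),
        }
        with open(csv_path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# chain drivers
# ---------------------------------------------------------------------------


def metropolis_chain(
    weight_fn: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: np.ndarray,
    config: MCMCConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generic single-coordinate Metropolis driver on a box.

    ``weight_fn`` maps a coordinate vector to a non-negative target weight;
    ``x0`` must have positive weight.  Returns (samples, weights,
    accept_count, propose_count).  This is the reference implementation the
    compiled toy kernel mirrors.
    """
    x = np.asarray(x0, dtype=float).copy()
    k = x.size
    lo, hi = bounds[:, 0], bounds[:, 1]
    w_cur = weight_fn(x)
    if w_cur <= 0:
        raise ChainStateError("initial state has zero weight")
    n_rec = config.n_recorded
    samples = np.empty((n_rec, k))
    weights = np.empty(n_rec)
    acc = np.zeros(k, dtype=np.int64)
    prop = np.zeros(k, dtype=np.int64)
    normal = config.proposal_kind == "normal"
    rec = 0
    for t in range(1, config.n_steps + 1):
        j = int(rng.integers(0, k))
        prop[j] += 1
        if normal:
            delta = config.sigma_q * rng.normal(0.0, 1.0)
        else:
            delta = config.sigma_q * (2.0 * rng.uniform(0.0, 1.0) - 1.0)
        cand = x[j] + delta
        if lo[j] <= cand <= hi[j]:
            old = x[j]
            x[j] = cand
            w_cand = weight_fn(x)
            if w_cand > 0.0 and rng.uniform(0.0, 1.0) * w_cur < w_cand:
                acc[j] += 1
                w_cur = w_cand
            else:
                x[j] = old
        if t > config.burn_in and (t - config.burn_in) % config.thin == 0 and rec < n_rec:
            samples[rec] = x
            weights[rec] = w_cur
            rec += 1
    return samples, weights, acc, prop


def _toy_fast_applicable(problem: InferenceProblem) -> bool:
    if problem.model.name != "toy":
        return False
    for cond in problem.conditions:
        if any(c.thresholds for c in cond.clauses):
            return False
    for f in problem.quantitative:
        if not isinstance(f, HistogramFitness):
            return False
        if f.observable_name not in ("T_e", "Y_end"):
            return False
    names = [f.observable_name for f in problem.quantitative]
    return len(names) == len(set(names))


def _initial_state(problem: InferenceProblem, config: MCMCConfig, rng) -> ParameterVector:
    if isinstance(config.init, ParameterVector):
        theta = config.init
    else:
        if config.init != "reference":
            raise ConfigurationError("init must be 'reference' or a ParameterVector")
        ref = problem.model.reference_params
        theta = ref if ref is not None else problem.prior
        theta = problem.prior.with_log10_values(theta.log10_values)
    w, _ = target_weight(problem, theta)
    if w > 0:
        return theta
    logger.info("reference start has zero weight; rejection-sampling the prior")
    lo, hi = problem.prior.bounds[:, 0], problem.prior.bounds[:, 1]
    for _ in range(config.init_budget):
        cand = problem.prior.with_log10_values(rng.uniform(lo, hi))
        w, _ = target_weight(problem, cand)
        if w > 0:
            return cand
    raise InitializationError(
        f"no positive-weight start within {config.init_budget} prior draws"
    )


def run_mcmc_hfm(problem: InferenceProblem, config: MCMCConfig) -> Trace:
    """Run the full hybrid-fitness Metropolis chain and return its trace.

    Every recorded sample lies in the prior box and satisfies all
    qualitative conditions; ``len(trace) == (n_steps - burn_in) // thin``.
    """
    rng = np.random.default_rng(config.seed)
    theta0 = _initial_state(problem, config, rng)

    if _toy_fast_applicable(problem):
        clause_ks, clause_ns, clause_nu, offsets = _pack_conditions(problem.conditions)
        te = next(
            (f for f in problem.quantitative if f.observable_name == "T_e"), None
        )
        ye = next(
            (f for f in problem.quantitative if f.observable_name == "Y_end"), None
        )
        empty_e = np.array([0.0, 1.0])
        empty_f = np.array([1.0])
        samples, weights, acc, prop = _kernels.toy_chain(
            theta0.log10_values,
            problem.prior.bounds[:, 0].copy(),
            problem.prior.bounds[:, 1].copy(),
            float(config.sigma_q),
            config.proposal_kind == "normal",
            int(config.n_steps),
            int(config.burn_in),
            int(config.thin),
            clause_ks,
            clause_ns,
            clause_nu,
            offsets,
            te is not None,
            te.bin_edges if te is not None else empty_e,
            te.frequencies if te is not None else empty_f,
            ye is not None,
            ye.bin_edges if ye is not None else empty_e,
            ye.frequencies if ye is not None else empty_f,
            float(problem.sim_input),
            float(problem.y0[0]),
            float(problem.dt),
            int(round(problem.t_end / problem.dt)),
            0.9,
            rng,
        )
    else:
        template = problem.prior

        def weight_fn(x: np.ndarray) -> float:
            return target_weight(problem, template.with_log10_values(x))[0]

        samples, weights, acc, prop = metropolis_chain(
            weight_fn, theta0.log10_values, problem.prior.bounds, config, rng
        )

    return Trace(
        problem.prior.names,
        samples,
        weights,
        acc,
        prop,
        config,
        problem.prior.bounds.copy(),
    )


def _pack_conditions(conditions: Sequence[ConditionSpec]):
    ks, ns, nu, offsets = [], [], [], [0]
    for cond in conditions:
        for c in cond.clauses:
            ks.append(c.input_value)
            ns.append(c.n_stable)
            nu.append(c.n_unstable)
        offsets.append(len(ks))
    return (
        np.asarray(ks, dtype=float),
        np.asarray(ns, dtype=np.int64),
        np.asarray(nu, dtype=np.int64),
        np.asarray(offsets, dtype=np.int64),
    )
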