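"""ODE model definitions and fixed-step integration.

The package ships two built-in models:

``toy``
    A single-species kinetic model with zero-order synthesis, first-order
    degradation and a cooperative (Hill) positive feedback::

        d[Y]/dt = k_s - k_d [Y] + k_p [Y]^n / (K^n + [Y]^n)

    The synthesis rate ``k_s`` is the scalar input.  With the reference
    parameters (k_d, k_p, K) = (1.0, 1.0, 0.5) and Hill coefficient n = 5
    the system is bistable and irreversible in ``k_s``.

``bistable2d``
    A two-variable positive-feedback fixture (activator ``u`` drives ``v``,
    ``v`` feeds back on ``u`` cooperatively) used to exercise the
    multi-dimensional steady-state and stability machinery::

        du/dt = input + alpha v^2/(1+v^2) - u
        dv/dt = beta u - v

Integration is classical fixed-step fourth-order Runge-Kutta.  Noisy
simulation adds an Euler-Maruyama style diffusion increment after each
deterministic step: ``eps*sqrt(dt)`` with ``eps ~ Normal(0, noise_variance)``,
so that the effective noise intensity does not depend on the step size;
states are clamped at zero after each noisy increment (concentrations).

User models plug in through :class:`ODEModelSpec` and
:func:`register_model`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "ConfigurationError",
    "DomainError",
    "IntegrationError",
    "ParameterVector",
    "ODEModelSpec",
    "Trajectory",
    "toy_rhs",
    "toy_jacobian",
    "fixture_rhs",
    "fixture_jacobian",
    "integrate_rk4",
    "simulate_noisy",
    "get_model",
    "register_model",
    "toy_model",
    "fixture_model",
    "toy_reference_params",
    "write_trajectory",
]

HILL_N = 5  # fixed Hill coefficient of the toy model (a model constant, not inferred)


class ConfigurationError(ValueError):
    """A model/parameter specification is inconsistent or incomplete."""


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration.

    Attributes
    ----------
    step : int
        Index of the first integration step producing a non-finite state.
    """

    def __init__(self, msg: str, step: int):
        super().__init__(msg)
        self.step = step


# ---------------------------------------------------------------------------
# parameter vectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterVector:
    """Named kinetic parameters on a common-log (log10) scale.

    Sampling and proposals act on ``log10_values``; model right-hand sides
    receive the linear values ``10**log10_values``.  ``bounds`` is the prior
    box, one ``(log10_lower, log10_upper)`` pair per parameter.
    """

    names: tuple[str, ...]
    log10_values: np.ndarray
    bounds: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(
            self, "log10_values", np.asarray(self.log10_values, dtype=float).copy()
        )
        object.__setattr__(self, "bounds", np.asarray(self.bounds, dtype=float).copy())
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError(f"duplicate parameter names: {self.names}")
        if self.log10_values.shape != (len(self.names),):
            raise ConfigurationError("log10_values shape does not match names")
        if self.bounds.shape != (len(self.names), 2):
            raise ConfigurationError("bounds must be (n_params, 2)")
        if not np.all(self.bounds[:, 0] < self.bounds[:, 1]):
            raise ConfigurationError("every log10_lower must be < log10_upper")

    @classmethod
    def from_linear(
        cls,
        names: Sequence[str],
        values: Sequence[float],
        fold: float = 10.0,
        bounds: np.ndarray | None = None,
    ) -> "ParameterVector":
        """Build from linear-scale values; default prior box is values/fold .. values*fold."""
        values = np.asarray(values, dtype=float)
        if np.any(values <= 0):
            raise ConfigurationError("linear parameter values must be positive")
        lv = np.log10(values)
        if bounds is None:
            w = np.log10(fold)
            bounds = np.column_stack([lv - w, lv + w])
        return cls(tuple(names), lv, np.asarray(bounds, dtype=float))

    @property
    def linear_values(self) -> np.ndarray:
        return 10.0 ** self.log10_values

    def value(self, name: str) -> float:
        """Linear-scale value of one parameter."""
        return float(10.0 ** self.log10_values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.linear_values)}

    def in_bounds(self) -> bool:
        return bool(
            np.all(self.log10_values >= self.bounds[:, 0])
            and np.all(self.log10_values <= self.bounds[:, 1])
        )

    def replace_log10(self, index: int, value: float) -> "ParameterVector":
        vals = self.log10_values.copy()
        vals[index] = value
        return ParameterVector(self.names, vals, self.bounds)

    def with_log10_values(self, values: np.ndarray) -> "ParameterVector":
        return ParameterVector(self.names, np.asarray(values, dtype=float), self.bounds)


def _param_map(params) -> Mapping[str, float]:
    if isinstance(params, ParameterVector):
        return params.as_dict()
    return params


def _require(params: Mapping[str, float], *names: str) -> list[float]:
    out = []
    for n in names:
        if n not in params:
            raise ConfigurationError(f"missing required parameter {n!r}")
        out.append(float(params[n]))
    return out


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------


@dataclass
class ODEModelSpec:
    """Contract for a model usable by the integrator, bifurcation analysis and sampler.

    ``rhs(state, params, input_value) -> dstate`` and the optional analytic
    ``jacobian`` take the state as a 1-D array and the parameters as a linear-
    scale mapping.  ``fixed_params`` are constants merged into the mapping
    before each call (e.g. the Hill coefficient).  ``reference_params`` is the
    model's canonical parameter vector, used as the default chain start.
    ``search_box`` is the default per-state bracket for steady-state searches.
    """

    name: str
    state_names: tuple[str, ...]
    input_name: str
    rhs: Callable[[np.ndarray, Mapping[str, float], float], np.ndarray]
    jacobian: Callable[[np.ndarray, Mapping[str, float], float], np.ndarray] | None = None
    fixed_params: dict[str, float] = field(default_factory=dict)
    reference_params: ParameterVector | None = None
    search_box: np.ndarray | None = None  # (n_states, 2)
    default_dt: float = 0.01
    default_t_end: float = 100.0
    # optional hooks: parameter-dependent steady-state bracket, and a
    # vectorized 1-D rhs evaluated on a whole grid at once
    dynamic_search_box: Callable[[Mapping[str, float], float], np.ndarray] | None = None
    rhs_grid_1d: Callable[[np.ndarray, Mapping[str, float], float], np.ndarray] | None = None

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def state_index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown state name {name!r}") from None

    def full_params(self, params) -> dict[str, float]:
        d = dict(self.fixed_params)
        d.update(_param_map(params))
        return d


# ---------------------------------------------------------------------------
# built-in right-hand sides
# ---------------------------------------------------------------------------


def toy_rhs(y: float, params, k_s: float) -> float:
    """d[Y]/dt of the toy positive-feedback model at concentration ``y``.

    ``k_s - k_d*y + k_p*y^n/(K^n + y^n)`` with n = 5.
    """
    if y < 0:
        raise DomainError(f"concentration must be non-negative, got {y}")
    p = _param_map(params)
    k_d, k_p, K = _require(p, "k_d", "k_p", "K")
    n = int(p.get("n", HILL_N))
    yn = y**n
    return float(k_s - k_d * y + k_p * yn / (K**n + yn))


def toy_jacobian(y: float, params, k_s: float) -> float:
    """d/dy of the toy right-hand side (scalar Jacobian)."""
    p = _param_map(params)
    k_d, k_p, K = _require(p, "k_d", "k_p", "K")
    n = int(p.get("n", HILL_N))
    Kn = K**n
    yn = y**n
    return float(-k_d + k_p * n * Kn * y ** (n - 1) / (Kn + yn) ** 2)


def fixture_rhs(state: np.ndarray, params, input_value: float) -> np.ndarray:
    """Two-variable cooperative positive-feedback fixture.

    du/dt = input + alpha*v^2/(1+v^2) - u;  dv/dt = beta*u - v.
    Bistable at input = 0, alpha = 3, beta = 1 (fixed points v = 0 and
    v = (3 +- sqrt(5))/2).
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise DomainError("state components must be non-negative")
    p = _param_map(params)
    alpha, beta = _require(p, "alpha", "beta")
    u, v = state
    return np.array(
        [input_value + alpha * v * v / (1.0 + v * v) - u, beta * u - v]
    )


def fixture_jacobian(state: np.ndarray, params, input_value: float) -> np.ndarray:
    p = _param_map(params)
    alpha, beta = _require(p, "alpha", "beta")
    _, v = np.asarray(state, dtype=float)
    return np.array(
        [
            [-1.0, alpha * 2.0 * v / (1.0 + v * v) ** 2],
            [beta, -1.0],
        ]
    )


def _toy_rhs_vec(state, params, input_value):
    return np.array([toy_rhs(float(state[0]), params, input_value)])


def _toy_jac_vec(state, params, input_value):
    return np.array([[toy_jacobian(float(state[0]), params, input_value)]])


def toy_reference_params() -> ParameterVector:
    """The toy model's reference vector (k_d, k_p, K) = (1.0, 1.0, 0.5), prior box x10 / /10."""
    return ParameterVector.from_linear(("k_d", "k_p", "K"), (1.0, 1.0, 0.5))


def _toy_search_box(params: Mapping[str, float], k_s: float) -> np.ndarray:
    # every steady state obeys k_d*y = k_s + k_p*h(y) <= k_s + k_p
    hi = 1.05 * max(5.0, (k_s + params["k_p"]) / params["k_d"])
    return np.array([[0.0, hi]])


def _toy_rhs_grid(y: np.ndarray, params: Mapping[str, float], k_s: float) -> np.ndarray:
    # same arithmetic (multiplication chain) as the compiled kernel
    k_d, k_p, K = params["k_d"], params["k_p"], params["K"]
    y2 = y * y
    y4 = y2 * y2
    y5 = y4 * y
    K2 = K * K
    K5 = K2 * K2 * K
    return k_s - k_d * y + k_p * y5 / (K5 + y5)


def toy_model() -> ODEModelSpec:
    return ODEModelSpec(
        name="toy",
        state_names=("Y",),
        input_name="k_s",
        rhs=_toy_rhs_vec,
        jacobian=_toy_jac_vec,
        fixed_params={"n": HILL_N},
        reference_params=toy_reference_params(),
        search_box=np.array([[0.0, 5.0]]),
        default_dt=0.01,
        default_t_end=100.0,
        dynamic_search_box=_toy_search_box,
        rhs_grid_1d=_toy_rhs_grid,
    )


def fixture_model() -> ODEModelSpec:
    return ODEModelSpec(
        name="bistable2d",
        state_names=("u", "v"),
        input_name="input",
        rhs=fixture_rhs,
        jacobian=fixture_jacobian,
        reference_params=ParameterVector.from_linear(("alpha", "beta"), (3.0, 1.0)),
        search_box=np.array([[0.0, 6.0], [0.0, 6.0]]),
        default_dt=0.01,
        default_t_end=100.0,
    )


_REGISTRY: dict[str, Callable[[], ODEModelSpec]] = {
    "toy": toy_model,
    "bistable2d": fixture_model,
}


def register_model(key: str, factory: Callable[[], ODEModelSpec]) -> None:
    """Register a user model factory under a string key usable from configs."""
    _REGISTRY[key] = factory


def get_model(key: str) -> ODEModelSpec:
    if key not in _REGISTRY:
        raise ConfigurationError(
            f"unknown model key {key!r}; known: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[key]()


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time grid plus per-time state vectors, with provenance metadata."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    state_names: tuple[str, ...]
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim == 1:
            self.states = self.states[:, None]
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("times must start at 0 and strictly increase")
        if self.states.shape[0] != self.times.shape[0]:
            raise ConfigurationError("states/times length mismatch")

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]


def write_trajectory(traj: Trajectory, csv_path) -> None:
    """CSV export (``time,<state names>``) with a JSON sidecar of the metadata."""
    import pandas as pd

    csv_path = str(csv_path)
    df = pd.DataFrame(traj.states, columns=list(traj.state_names))
    df.insert(0, "time", traj.times)
    df.to_csv(csv_path, index=False)
    sidecar = {"seed": traj.seed, **traj.meta}
    with open(csv_path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _n_steps(t_end: float, dt: float) -> int:
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    n = round(t_end / dt)
    if n < 1 or abs(n * dt - t_end) > 1e-9 * max(1.0, t_end):
        raise ConfigurationError(f"t_end={t_end} must be a positive multiple of dt={dt}")
    return int(n)


def _is_toy(model: ODEModelSpec) -> bool:
    return model.name == "toy" and model.state_names == ("Y",)


def _toy_linear(model: ODEModelSpec, params) -> tuple[float, float, float]:
    p = model.full_params(params)
    k_d, k_p, K = _require(p, "k_d", "k_p", "K")
    if int(p.get("n", HILL_N)) != HILL_N:
        raise ConfigurationError("toy fast path supports n = 5 only")
    return k_d, k_p, K


def integrate_rk4(
    model: ODEModelSpec,
    params,
    input_value: float,
    y0,
    t_end: float | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Classical fourth-order Runge-Kutta on a fixed grid.

    Defaults ``dt`` and ``t_end`` come from the model spec (toy: dt=0.01,
    t_end=100).  Raises :class:`IntegrationError` (with the step index) if a
    non-finite state appears.
    """
    dt = model.default_dt if dt is None else float(dt)
    t_end = model.default_t_end if t_end is None else float(t_end)
    n = _n_steps(t_end, dt)
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    if y0.shape != (model.n_states,):
        raise ConfigurationError("y0 shape does not match model states")
    if not np.all(np.isfinite(y0)):
        raise ConfigurationError("y0 must be finite")

    meta = {"dt": dt, "t_end": t_end, "input": input_value, "noise": None}
    times = np.arange(n + 1) * dt

    if _is_toy(model):
        k_d, k_p, K = _toy_linear(model, params)
        y, bad = _kernels.toy_rk4(k_d, k_p, K, float(input_value), float(y0[0]), dt, n)
        if bad >= 0:
            raise IntegrationError(f"non-finite state at step {bad}", bad)
        return Trajectory(times, y, model.state_names, None, meta)

    p = model.full_params(params)
    states = np.empty((n + 1, model.n_states))
    states[0] = y0
    y = y0.copy()
    for i in range(n):
        k1 = model.rhs(y, p, input_value)
        k2 = model.rhs(y + 0.5 * dt * k1, p, input_value)
        k3 = model.rhs(y + 0.5 * dt * k2, p, input_value)
        k4 = model.rhs(y + dt * k3, p, input_value)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at step {i}", i)
        states[i + 1] = y
    return Trajectory(times, states, model.state_names, None, meta)


def simulate_noisy(
    model: ODEModelSpec,
    params,
    input_value: float,
    y0,
    t_end: float | None = None,
    dt: float | None = None,
    noise_variance: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """RK4 drift plus additive Gaussian diffusion, clamped at zero.

    After each deterministic step the increment ``eps*sqrt(dt)`` with
    ``eps ~ Normal(0, noise_variance)`` is added to every state and negative
    components are clamped to 0.  ``noise_variance = 0`` reproduces
    :func:`integrate_rk4` bitwise.  Exactly one of ``seed``/``rng`` supplies
    the randomness.
    """
    if noise_variance < 0:
        raise ConfigurationError("noise_variance must be >= 0")
    if noise_variance == 0:
        traj = integrate_rk4(model, params, input_value, y0, t_end, dt)
        traj.seed = seed
        return traj
    if rng is None:
        if seed is None:
            raise ConfigurationError("a seed (or rng) is required for noisy simulation")
        rng = np.random.default_rng(seed)

    dt = model.default_dt if dt is None else float(dt)
    t_end = model.default_t_end if t_end is None else float(t_end)
    n = _n_steps(t_end, dt)
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    times = np.arange(n + 1) * dt
    meta = {
        "dt": dt,
        "t_end": t_end,
        "input": input_value,
        "noise": {
            "rule": "post-step additive eps*sqrt(dt), eps~N(0,variance), clamped at 0",
            "variance": noise_variance,
        },
    }

    sd = float(np.sqrt(noise_variance))
    if _is_toy(model):
        k_d, k_p, K = _toy_linear(model, params)
        y, bad = _kernels.toy_rk4_noisy(
            k_d, k_p, K, float(input_value), float(y0[0]), dt, n, sd, rng
        )
        if bad >= 0:
            raise IntegrationError(f"non-finite state at step {bad}", bad)
        return Trajectory(times, y, model.state_names, seed, meta)

    p = model.full_params(params)
    states = np.empty((n + 1, model.n_states))
    states[0] = y0
    y = y0.copy()
    sqdt = np.sqrt(dt)
    for i in range(n):
        k1 = model.rhs(y, p, input_value)
        k2 = model.rhs(y + 0.5 * dt * k1, p, input_value)
        k3 = model.rhs(y + 0.5 * dt * k2, p, input_value)
        k4 = model.rhs(y + dt * k3, p, input_value)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        y = y + sd * sqdt * rng.normal(0.0, 1.0, size=y.shape)
        np.clip(y, 0.0, None, out=y)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at step {i}", i)
        states[i + 1] = y
    return Trajectory(times, states, model.state_names, seed, meta)
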