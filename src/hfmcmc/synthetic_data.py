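"""Synthetic quantitative fitness measures and end-to-end recovery experiments.

The generator emulates how population-level experimental histograms arise:
an ensemble of noisy simulations at a known "true" parameter vector, each
replicate summarized by scalar observables, and the observable values
histogrammed.  The default setting is the toy-model study: 10000 replicates
at input k_s = 1.0 with additive Gaussian noise, observables T_e (execution
time) and Y_end (concentration at the final time, t = 100), 50 equal-width
bins spanning the replicate range.

Threshold observables of noisy replicates are referenced to the noise-free
trajectory maximum (the bifurcation high branch), so the histograms measure
the rise of the underlying signal rather than extreme-value noise
excursions; see the methods note.

:func:`recovery_experiment` chains generator -> sampler -> posterior
summaries into a machine-readable report of how well the generating values
are recovered from a chosen subset of fitness measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .bifurcation import ConditionSpec, toy_condition_B, toy_condition_I
from .fitness import HistogramFitness, endpoint_value, execution_time, switching_time
from .models import (
    ConfigurationError,
    ODEModelSpec,
    ParameterVector,
    get_model,
    integrate_rk4,
    simulate_noisy,
    toy_reference_params,
)
from .posterior import DEFAULT_N_BINS, MarginalSummary, marginal_summary
from .sampler import InferenceProblem, MCMCConfig, Trace, run_mcmc_hfm

__all__ = [
    "GeneratorSpec",
    "GenerationError",
    "generate_fitness_histograms",
    "RecoveryReport",
    "recovery_experiment",
    "toy_problem",
]


class GenerationError(RuntimeError):
    """Too many replicates failed during histogram generation."""


@dataclass
class GeneratorSpec:
    """Ensemble settings for histogram generation.

    ``observables`` pairs an observable name with an extractor id from
    {"execution_time", "switching_time", "endpoint"}.
    """

    model_key: str = "toy"
    true_params: ParameterVector | None = None
    input_value: float = 1.0
    n_replicates: int = 10_000
    noise_variance: float = 1.0
    observables: tuple[tuple[str, str], ...] = (
        ("T_e", "execution_time"),
        ("Y_end", "endpoint"),
    )
    n_bins: int = DEFAULT_N_BINS
    seed: int = 0
    y0: np.ndarray | None = None
    t_end: float | None = None
    dt: float | None = None
    max_drop_fraction: float = 0.01

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not self.observables:
            raise ConfigurationError("observables must be non-empty")
        if self.true_params is None:
            ref = get_model(self.model_key).reference_params
            if ref is None:
                raise ConfigurationError("true_params required for this model")
            self.true_params = ref


def _extractor(extractor_id: str, state_name: str, reference_max: float):
    if extractor_id == "execution_time":
        return lambda tr: execution_time(tr, state_name, 0.9, reference_max=reference_max)
    if extractor_id == "switching_time":
        return lambda tr: switching_time(tr, state_name, reference_max=reference_max)
    if extractor_id == "endpoint":
        return lambda tr: endpoint_value(tr, state_name, tr.times[-1])
    raise ConfigurationError(f"unknown extractor id {extractor_id!r}")


def generate_fitness_histograms(spec: GeneratorSpec) -> list[HistogramFitness]:
    """Seeded noisy ensemble -> one equal-width histogram per observable.

    Replicates with non-finite trajectories are dropped (the drop count is
    recorded in the histogram metadata); more than ``max_drop_fraction``
    drops raise :class:`GenerationError`.
    """
    model = get_model(spec.model_key)
    out_state = model.state_names[0]
    y0 = np.zeros(model.n_states) if spec.y0 is None else np.asarray(spec.y0, float)
    t_end = model.default_t_end if spec.t_end is None else spec.t_end
    dt = model.default_dt if spec.dt is None else spec.dt
    rng = np.random.default_rng(spec.seed)

    det = integrate_rk4(model, spec.true_params, spec.input_value, y0, t_end, dt)
    reference_max = float(np.max(det.state(out_state)))

    ids = dict(spec.observables)
    toy_fast = (
        model.name == "toy"
        and set(ids.values()) <= {"execution_time", "endpoint"}
    )
    values: dict[str, np.ndarray] = {}
    if toy_fast:
        p = model.full_params(spec.true_params)
        te, yend = _kernels.toy_noisy_observables(
            p["k_d"], p["k_p"], p["K"],
            float(spec.input_value), float(y0[0]), float(dt),
            int(round(t_end / dt)),
            float(np.sqrt(spec.noise_variance)),
            int(spec.n_replicates),
            0.9,
            reference_max,
            rng,
        )
        for name, ex in spec.observables:
            values[name] = te if ex == "execution_time" else yend
    else:
        cols = {name: np.empty(spec.n_replicates) for name, _ in spec.observables}
        extractors = {
            name: _extractor(ex, out_state, reference_max)
            for name, ex in spec.observables
        }
        for r in range(spec.n_replicates):
            try:
                traj = simulate_noisy(
                    model, spec.true_params, spec.input_value, y0, t_end, dt,
                    noise_variance=spec.noise_variance, rng=rng,
                )
                for name in cols:
                    cols[name][r] = extractors[name](traj)
            except Exception:
                for name in cols:
                    cols[name][r] = np.nan
        values = cols

    hists = []
    for name, _ in spec.observables:
        v = values[name]
        ok = v[np.isfinite(v)]
        dropped = spec.n_replicates - len(ok)
        if dropped > spec.max_drop_fraction * spec.n_replicates:
            raise GenerationError(
                f"{dropped}/{spec.n_replicates} replicates failed for {name!r}"
            )
        counts, edges = np.histogram(ok, bins=spec.n_bins)
        hists.append(
            HistogramFitness(
                name,
                edges,
                counts.astype(float),
                meta={
                    "seed": spec.seed,
                    "n_replicates": spec.n_replicates,
                    "noise_variance": spec.noise_variance,
                    "dropped": dropped,
                    "model": spec.model_key,
                    "input_value": spec.input_value,
                    "reference_max": reference_max,
                },
            )
        )
    return hists


# ---------------------------------------------------------------------------
# end-to-end recovery
# ---------------------------------------------------------------------------

TOY_SUBSET_NAMES = ("B", "I", "T_e", "Y_end")


def toy_problem(
    fitness_subset=("B", "I", "T_e", "Y_end"),
    histograms: list[HistogramFitness] | None = None,
) -> InferenceProblem:
    """The toy-model inference problem restricted to a subset of fitness measures.

    ``fitness_subset`` draws from {"B", "I"} (qualitative: bistability,
    irreversibility) and {"T_e", "Y_end"} (quantitative; requires the
    matching generated histograms).
    """
    subset = list(fitness_subset)
    unknown = set(subset) - set(TOY_SUBSET_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown fitness names {sorted(unknown)}")
    conditions: list[ConditionSpec] = []
    if "B" in subset:
        conditions.append(toy_condition_B())
    if "I" in subset:
        conditions.append(toy_condition_I())
    quant = []
    by_name = {h.observable_name: h for h in (histograms or [])}
    for q in ("T_e", "Y_end"):
        if q in subset:
            if q not in by_name:
                raise ConfigurationError(f"subset includes {q!r} but no histogram given")
            quant.append(by_name[q])
    return InferenceProblem(
        model=get_model("toy"),
        prior=toy_reference_params(),
        conditions=conditions,
        quantitative=quant,
        sim_input=1.0,
    )


@dataclass
class RecoveryReport:
    """Per-parameter recovery outcome of one generate -> sample -> analyze run."""

    fitness_subset: tuple[str, ...]
    noise_variance: float
    seed: int
    truth_log10: dict[str, float]
    summaries: dict[str, MarginalSummary]
    acceptance_rate: dict[str, float]
    trace: Trace | None = None

    @property
    def mode_abs_error_log10(self) -> dict[str, float]:
        return {
            n: abs(s.mode - self.truth_log10[n]) for n, s in self.summaries.items()
        }

    @property
    def ci_log10_width(self) -> dict[str, float]:
        return {n: s.log10_width for n, s in self.summaries.items()}


def recovery_experiment(
    noise_variance: float = 0.01,
    fitness_subset=("B", "I", "T_e", "Y_end"),
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    n_replicates: int = 10_000,
    n_bins: int = DEFAULT_N_BINS,
    keep_trace: bool = False,
) -> RecoveryReport:
    """Generate histograms at the toy truth, run the chain, summarize recovery.

    Seeds are derived deterministically from ``seed`` (one stream for the
    generator, one for the chain), so the whole experiment is reproducible
    bit for bit.  The default chain is a scaled-down run: 3.3e5 steps with
    3e4 burn-in, thinning 3.
    """
    if not fitness_subset:
        raise ConfigurationError("fitness_subset must be non-empty")
    gen_seed, chain_seed = [
        int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(2)
    ]
    if mcmc is None:
        mcmc = MCMCConfig(n_steps=330_000, burn_in=30_000, thin=3, sigma_q=0.5)
    mcmc = replace(mcmc, seed=chain_seed)

    need_hists = [q for q in ("T_e", "Y_end") if q in fitness_subset]
    hists: list[HistogramFitness] = []
    if need_hists:
        spec = GeneratorSpec(
            model_key="toy",
            noise_variance=noise_variance,
            n_replicates=n_replicates,
            n_bins=n_bins,
            seed=gen_seed,
            observables=tuple(
                (n, "execution_time" if n == "T_e" else "endpoint") for n in need_hists
            ),
        )
        hists = generate_fitness_histograms(spec)

    problem = toy_problem(fitness_subset, hists)
    trace = run_mcmc_hfm(problem, mcmc)
    truth = {
        n: float(v)
        for n, v in zip(problem.prior.names, toy_reference_params().log10_values)
    }
    summaries = {n: marginal_summary(trace, n, n_bins) for n in problem.prior.names}
    rates = {
        n: float(r) for n, r in zip(problem.prior.names, trace.acceptance_rate)
    }
    return RecoveryReport(
        fitness_subset=tuple(fitness_subset),
        noise_variance=noise_variance,
        seed=seed,
        truth_log10=truth,
        summaries=summaries,
        acceptance_rate=rates,
        trace=trace if keep_trace else None,
    )
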