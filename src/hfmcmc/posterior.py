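"""Trace summaries: marginal histograms, modes, credible intervals, correlations.

The representative inferred value of a parameter is the mode of its
discretized marginal (the center of the maximum-probability bin, leftmost on
ties, with bins spanning the prior box on the log10 scale).  The 95%
credible interval excludes 2.5% of the samples on each side; bounds are
nearest-rank empirical quantiles computed on the linear scale, and the
interval width is reported as log10(upper/lower) — a full prior box of
tenfold-up/tenfold-down corresponds to width 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .models import ConfigurationError
from .sampler import InferenceProblem, Trace

__all__ = [
    "MarginalSummary",
    "marginal_summary",
    "correlation_matrix",
    "joint_histogram",
    "observable_histogram",
]

DEFAULT_N_BINS = 50


@dataclass
class MarginalSummary:
    parameter: str
    bin_edges: np.ndarray  # log10 scale, over the prior range
    probabilities: np.ndarray  # sums to 1
    mode: float  # log10 bin center of maximal probability
    ci95: tuple[float, float]  # linear scale
    log10_width: float  # log10(upper/lower)


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    n = len(sorted_vals)
    idx = max(int(np.ceil(q * n)) - 1, 0)
    return float(sorted_vals[idx])


def marginal_summary(trace: Trace, parameter: str, n_bins: int = DEFAULT_N_BINS) -> MarginalSummary:
    """Discretized marginal over the prior range plus mode and 95% CI."""
    if len(trace) == 0:
        raise ConfigurationError("trace is empty")
    if parameter not in trace.names:
        raise KeyError(parameter)
    j = trace.names.index(parameter)
    lo, hi = trace.bounds[j]
    x = trace.samples[:, j]
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    probs = counts / counts.sum()
    mode_bin = int(np.argmax(probs))  # argmax returns the leftmost maximum
    mode = 0.5 * (edges[mode_bin] + edges[mode_bin + 1])
    linear = np.sort(10.0**x)
    lower = _nearest_rank(linear, 0.025)
    upper = _nearest_rank(linear, 0.975)
    return MarginalSummary(
        parameter=parameter,
        bin_edges=edges,
        probabilities=probs,
        mode=float(mode),
        ci95=(lower, upper),
        log10_width=float(np.log10(upper / lower)),
    )


def correlation_matrix(trace: Trace):
    """Pearson correlation of the log10 samples (pandas DataFrame, unit diagonal)."""
    import pandas as pd

    if len(trace) < 2:
        raise ConfigurationError("need at least 2 samples")
    X = trace.samples
    sd = X.std(axis=0)
    degenerate = [n for n, s in zip(trace.names, sd) if s == 0]
    if degenerate:
        import warnings

        warnings.warn(f"zero-variance parameters {degenerate}: correlations undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(r, index=list(trace.names), columns=list(trace.names))


def joint_histogram(
    trace: Trace, param_a: str, param_b: str, n_bins: int = DEFAULT_N_BINS
):
    """Normalized 2-D probability table over the prior ranges (log10 scale).

    Returns (table, edges_a, edges_b); marginalizing either axis reproduces
    the corresponding :func:`marginal_summary` probabilities exactly.
    """
    ja, jb = trace.names.index(param_a), trace.names.index(param_b)
    ra, rb = trace.bounds[ja], trace.bounds[jb]
    H, ea, eb = np.histogram2d(
        trace.samples[:, ja],
        trace.samples[:, jb],
        bins=n_bins,
        range=(tuple(ra), tuple(rb)),
    )
    return H / H.sum(), ea, eb


def observable_histogram(
    trace: Trace,
    problem: InferenceProblem,
    observable: str,
    n_bins: int = DEFAULT_N_BINS,
    n_subsample: int = 10_000,
    seed: int = 0,
    bin_edges: np.ndarray | None = None,
):
    """Posterior-predictive histogram of a deterministic observable.

    Re-simulates the noise-free dynamics for a uniform subsample of retained
    parameter vectors and histograms the observable (over its own range, or
    over explicit ``bin_edges``).  Returns (probabilities, bin_edges).
    """
    if observable not in problem.extractors:
        raise ConfigurationError(f"no extractor for observable {observable!r}")
    rng = np.random.default_rng(seed)
    n = len(trace)
    if n_subsample < n:
        idx = rng.choice(n, size=n_subsample, replace=False)
    else:
        idx = np.arange(n)
    sub = trace.samples[idx]

    if problem.model.name == "toy" and observable in ("T_e", "Y_end"):
        te, yend = _kernels.toy_det_observables_batch(
            np.ascontiguousarray(sub),
            float(problem.sim_input),
            float(problem.y0[0]),
            float(problem.dt),
            int(round(problem.t_end / problem.dt)),
            0.9,
        )
        vals = te if observable == "T_e" else yend
        vals = vals[np.isfinite(vals)]
    else:
        from .models import integrate_rk4

        vals = []
        for row in sub:
            params = problem.prior.with_log10_values(row)
            traj = integrate_rk4(
                problem.model, params, problem.sim_input, problem.y0, problem.t_end, problem.dt
            )
            vals.append(problem.extractors[observable](traj))
        vals = np.asarray(vals)

    counts, edges = np.histogram(vals, bins=bin_edges if bin_edges is not None else n_bins)
    return counts / counts.sum(), edges
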