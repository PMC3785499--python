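"""Trajectory observables and quantitative fitness measures.

Observables are scalar summaries of a simulated time course:

* execution time ``T_e`` — first grid time at which the state reaches 90%
  of its maximum value (rise-time of a switch-like output);
* switching time ``T_s`` — duration between the first crossings of 2.5%
  and 97.5% of the maximum (sharpness of the switch);
* endpoint value — the state at a fixed time (default t = 100).

Thresholds use first-crossing semantics on the discrete grid, no
interpolation.  By default "maximum value" is the maximum over the
trajectory grid; for noisy ensembles a ``reference_max`` (typically the
noise-free trajectory maximum, which equals the bifurcation high branch for
the monotone cases in scope) can be supplied so that the observable measures
the rise of the underlying signal rather than noise excursions.

A quantitative fitness measure maps an observable value to a non-negative
weight: either the raw frequency of the bin containing the value in an
empirical histogram, or a log-normal density parameterized by the desired
mean and standard deviation on the natural scale.  Histogram frequencies are
deliberately not normalized — only weight ratios enter the Metropolis
acceptance probability, so normalization cancels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import ConfigurationError, DomainError, Trajectory

__all__ = [
    "execution_time",
    "switching_time",
    "endpoint_value",
    "HistogramFitness",
    "LogNormalFitness",
    "lognormal_from_moments",
    "read_histogram",
    "write_histogram",
]


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


def _first_crossing_time(traj: Trajectory, y: np.ndarray, threshold: float) -> float:
    idx = np.argmax(y >= threshold)
    if not y[idx] >= threshold:
        raise DomainError("trajectory never reaches threshold")
    return float(traj.times[idx])


def execution_time(
    traj: Trajectory,
    state_name: str,
    fraction: float = 0.9,
    reference_max: float | None = None,
) -> float:
    """First grid time at which ``state >= fraction * max``.

    A constant (or all-zero) trajectory returns 0: the threshold is met at
    t = 0.
    """
    if not 0 < fraction < 1:
        raise ConfigurationError("fraction must be in (0, 1)")
    y = traj.state(state_name)
    m = float(np.max(y)) if reference_max is None else float(reference_max)
    return _first_crossing_time(traj, y, fraction * m)


def switching_time(
    traj: Trajectory,
    state_name: str,
    lo: float = 0.025,
    hi: float = 0.975,
    reference_max: float | None = None,
) -> float:
    """Duration between the first crossings of ``lo*max`` and ``hi*max`` (>= 0)."""
    if not 0 < lo < hi < 1:
        raise ConfigurationError("need 0 < lo < hi < 1")
    y = traj.state(state_name)
    m = float(np.max(y)) if reference_max is None else float(reference_max)
    t_lo = _first_crossing_time(traj, y, lo * m)
    t_hi = _first_crossing_time(traj, y, hi * m)
    return t_hi - t_lo


def endpoint_value(traj: Trajectory, state_name: str, t: float = 100.0) -> float:
    """State value at grid time ``t`` (must lie on the grid)."""
    idx = np.searchsorted(traj.times, t)
    if idx >= len(traj.times) or abs(traj.times[idx] - t) > 1e-9 * max(1.0, abs(t)):
        raise DomainError(f"t={t} is not on the trajectory grid")
    return float(traj.state(state_name)[idx])


# ---------------------------------------------------------------------------
# quantitative fitness measures
# ---------------------------------------------------------------------------


@dataclass
class HistogramFitness:
    """Histogram-valued fitness: the frequency of the bin containing z.

    Bins are half-open ``[edge_i, edge_{i+1})`` with the last bin closed on
    the right; values outside the edge range score 0.
    """

    observable_name: str
    bin_edges: np.ndarray
    frequencies: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) != len(self.bin_edges) - 1:
            raise ConfigurationError("need len(frequencies) == len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ConfigurationError("bin edges must strictly increase")
        if np.any(self.frequencies < 0) or not np.any(self.frequencies > 0):
            raise ConfigurationError("frequencies must be >= 0 with at least one > 0")

    def __call__(self, z: float) -> float:
        if z == self.bin_edges[-1]:
            return float(self.frequencies[-1])
        i = int(np.searchsorted(self.bin_edges, z, side="right")) - 1
        if i < 0 or i >= len(self.frequencies):
            return 0.0
        return float(self.frequencies[i])


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the log-normal with given natural-scale mean/SD.

    sigma^2 = ln(1 + sd^2/mean^2);  mu = ln(mean) - sigma^2/2.
    """
    if mean <= 0 or sd <= 0:
        raise DomainError("mean and sd must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


@dataclass
class LogNormalFitness:
    """Log-normal density fitness over a positive observable (e.g. minutes).

    Parameterized by the natural-scale mean and standard deviation; the
    log-scale (mu, sigma) are derived by moment inversion.
    """

    observable_name: str
    mean: float
    sd: float
    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self):
        self.mu, self.sigma = lognormal_from_moments(self.mean, self.sd)

    def __call__(self, z: float) -> float:
        if z <= 0:
            return 0.0
        return float(stats.lognorm.pdf(z, s=self.sigma, scale=np.exp(self.mu)))

    @property
    def mode(self) -> float:
        return float(np.exp(self.mu - self.sigma**2))


# ---------------------------------------------------------------------------
# histogram file round trip
# ---------------------------------------------------------------------------


def write_histogram(h: HistogramFitness, csv_path) -> None:
    """CSV (bin_left,bin_right,frequency) plus a JSON sidecar with metadata."""
    import pandas as pd

    csv_path = str(csv_path)
    pd.DataFrame(
        {
            "bin_left": h.bin_edges[:-1],
            "bin_right": h.bin_edges[1:],
            "frequency": h.frequencies,
        }
    ).to_csv(csv_path, index=False)
    with open(csv_path + ".json", "w") as fh:
        json.dump({"observable_name": h.observable_name, **h.meta}, fh, indent=1, default=float)


def read_histogram(csv_path) -> HistogramFitness:
    import os

    import pandas as pd

    csv_path = str(csv_path)
    df = pd.read_csv(csv_path)
    edges = np.concatenate([df["bin_left"].to_numpy(), df["bin_right"].to_numpy()[-1:]])
    meta = {}
    name = os.path.splitext(os.path.basename(csv_path))[0]
    sidecar = csv_path + ".json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
        name = meta.pop("observable_name", name)
    return HistogramFitness(name, edges, df["frequency"].to_numpy(), meta)
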