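"""Numba-compiled inner loops for the single-variable toy model.

These kernels mirror, operation for operation, the generic Python paths in
``models``/``bifurcation``/``fitness``/``sampler`` so that the two routes
produce identical floating-point results; the test suite asserts that
agreement.  All randomness flows through ``numpy.random.Generator`` objects
passed in from the caller (numba consumes the same underlying bit stream as
NumPy, so Python-side and kernel-side draws are interchangeable).

Hill coefficient is fixed at n = 5 here; the generic path handles anything
else.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# grid resolution of the 1-D steady-state scan (shared with the Python finder)
N_GRID_1D = 4000
NEWTON_TOL = 1e-10
MARGINAL_BAND = 1e-8


@njit(cache=True)
def toy_f(y, k_d, k_p, K, k_s):
    y2 = y * y
    y4 = y2 * y2
    y5 = y4 * y
    K2 = K * K
    K5 = K2 * K2 * K
    return k_s - k_d * y + k_p * y5 / (K5 + y5)


@njit(cache=True)
def toy_df(y, k_d, k_p, K):
    y2 = y * y
    y4 = y2 * y2
    y5 = y4 * y
    K2 = K * K
    K5 = K2 * K2 * K
    d = K5 + y5
    return -k_d + k_p * 5.0 * K5 * y4 / (d * d)


@njit(cache=True)
def toy_search_hi(k_d, k_p, K, k_s):
    """Guaranteed upper bracket: every steady state obeys y <= (k_s + k_p)/k_d."""
    hi = (k_s + k_p) / k_d
    if hi < 5.0:
        hi = 5.0
    return 1.05 * hi


@njit(cache=True)
def toy_count_steady(k_d, k_p, K, k_s):
    """(n_stable, n_unstable, n_marginal) by grid bracketing + bisection.

    Exact zeros at grid points count as roots directly (classified by the
    derivative); strict sign changes between grid points are bisected to
    ~1e-13 relative before classification.
    """
    hi = toy_search_hi(k_d, k_p, K, k_s)
    n = N_GRID_1D
    ns = 0
    nu = 0
    nm = 0
    h = hi / (n - 1)
    fprev = toy_f(0.0, k_d, k_p, K, k_s)
    yprev = 0.0
    for i in range(n):
        yi = i * h
        fi = toy_f(yi, k_d, k_p, K, k_s) if i > 0 else fprev
        if fi == 0.0:
            d = toy_df(yi, k_d, k_p, K)
            if abs(d) < MARGINAL_BAND:
                nm += 1
            elif d < 0.0:
                ns += 1
            else:
                nu += 1
        elif i > 0 and fprev != 0.0 and ((fprev > 0.0) != (fi > 0.0)):
            a = yprev
            b = yi
            fa = fprev
            for _ in range(80):
                m = 0.5 * (a + b)
                fm = toy_f(m, k_d, k_p, K, k_s)
                if fm == 0.0:
                    a = m
                    b = m
                    break
                if (fa > 0.0) == (fm > 0.0):
                    a = m
                    fa = fm
                else:
                    b = m
            r = 0.5 * (a + b)
            d = toy_df(r, k_d, k_p, K)
            if abs(d) < MARGINAL_BAND:
                nm += 1
            elif d < 0.0:
                ns += 1
            else:
                nu += 1
        fprev = fi
        yprev = yi
    return ns, nu, nm


@njit(cache=True)
def toy_rk4(k_d, k_p, K, k_s, y0, dt, n):
    """Deterministic RK4 trajectory; returns (states, first_bad_step or -1)."""
    y = np.empty(n + 1)
    y[0] = y0
    yi = y0
    for i in range(n):
        k1 = toy_f(yi, k_d, k_p, K, k_s)
        k2 = toy_f(yi + 0.5 * dt * k1, k_d, k_p, K, k_s)
        k3 = toy_f(yi + 0.5 * dt * k2, k_d, k_p, K, k_s)
        k4 = toy_f(yi + dt * k3, k_d, k_p, K, k_s)
        yi = yi + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.isfinite(yi):
            return y, i
        y[i + 1] = yi
    return y, -1


@njit(cache=True)
def toy_rk4_noisy(k_d, k_p, K, k_s, y0, dt, n, noise_sd, rng):
    """RK4 drift + additive eps*sqrt(dt) Gaussian increment, clamped at 0."""
    y = np.empty(n + 1)
    y[0] = y0
    yi = y0
    sqdt = np.sqrt(dt)
    for i in range(n):
        k1 = toy_f(yi, k_d, k_p, K, k_s)
        k2 = toy_f(yi + 0.5 * dt * k1, k_d, k_p, K, k_s)
        k3 = toy_f(yi + 0.5 * dt * k2, k_d, k_p, K, k_s)
        k4 = toy_f(yi + dt * k3, k_d, k_p, K, k_s)
        yi = yi + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        yi = yi + noise_sd * sqdt * rng.normal(0.0, 1.0)
        if yi < 0.0:
            yi = 0.0
        if not np.isfinite(yi):
            return y, i
        y[i + 1] = yi
    return y, -1


@njit(cache=True)
def hist_lookup(edges, freqs, z):
    """Frequency of the half-open bin [edge_i, edge_{i+1}) containing z.

    Matches ``np.searchsorted(edges, z, side='right') - 1`` with the last bin
    closed on the right; outside the edge range the value is 0.
    """
    if z == edges[len(edges) - 1]:
        return freqs[len(freqs) - 1]
    lo = 0
    hi = len(edges)
    while lo < hi:
        mid = (lo + hi) // 2
        if z < edges[mid]:
            hi = mid
        else:
            lo = mid + 1
    i = lo - 1
    if i < 0 or i >= len(freqs):
        return 0.0
    return freqs[i]


@njit(cache=True)
def _first_crossing_index(y, threshold):
    for i in range(len(y)):
        if y[i] >= threshold:
            return i
    return -1


@njit(cache=True)
def toy_conditions_ok(
    k_d, k_p, K, clause_ks, clause_ns, clause_nu, cond_offsets
):
    """All conditions (groups of clauses) hold -> 1, else 0.

    Clause c of condition j lives at indices cond_offsets[j]..cond_offsets[j+1].
    Steady-state counts are memoised per distinct input value within the call.
    Any marginal steady state fails the clause (conservative).
    """
    memo_ks = np.empty(32)
    memo_ns = np.empty(32, np.int64)
    memo_nu = np.empty(32, np.int64)
    memo_nm = np.empty(32, np.int64)
    nmemo = 0
    for j in range(len(cond_offsets) - 1):
        for q in range(cond_offsets[j], cond_offsets[j + 1]):
            ks = clause_ks[q]
            idx = -1
            for t in range(nmemo):
                if memo_ks[t] == ks:
                    idx = t
                    break
            if idx < 0:
                ns, nu, nm = toy_count_steady(k_d, k_p, K, ks)
                idx = nmemo
                memo_ks[idx] = ks
                memo_ns[idx] = ns
                memo_nu[idx] = nu
                memo_nm[idx] = nm
                nmemo += 1
            if (
                memo_nm[idx] > 0
                or memo_ns[idx] != clause_ns[q]
                or memo_nu[idx] != clause_nu[q]
            ):
                return 0
    return 1


@njit(cache=True)
def toy_weight(
    log10_kd,
    log10_kp,
    log10_K,
    clause_ks,
    clause_ns,
    clause_nu,
    cond_offsets,
    use_te,
    te_edges,
    te_freqs,
    use_y100,
    y_edges,
    y_freqs,
    sim_ks,
    y0,
    dt,
    n_int,
    te_fraction,
):
    """Hybrid-fitness target weight (flat prior inside the box already assumed).

    Qualitative indicators first (no dynamics run if any fails), then one
    deterministic simulation supplies the execution-time and endpoint
    observables for the histogram lookups.
    """
    k_d = 10.0**log10_kd
    k_p = 10.0**log10_kp
    K = 10.0**log10_K
    if (
        toy_conditions_ok(k_d, k_p, K, clause_ks, clause_ns, clause_nu, cond_offsets)
        == 0
    ):
        return 0.0
    w = 1.0
    if use_te or use_y100:
        y, bad = toy_rk4(k_d, k_p, K, sim_ks, y0, dt, n_int)
        if bad >= 0:
            return 0.0
        if use_te:
            m = y[0]
            for i in range(1, len(y)):
                if y[i] > m:
                    m = y[i]
            idx = _first_crossing_index(y, te_fraction * m)
            te = idx * dt
            w *= hist_lookup(te_edges, te_freqs, te)
        if use_y100:
            w *= hist_lookup(y_edges, y_freqs, y[len(y) - 1])
    return w


@njit(cache=True)
def toy_chain(
    theta0,
    lo,
    hi,
    sigma_q,
    kind_normal,
    n_steps,
    burn_in,
    thin,
    clause_ks,
    clause_ns,
    clause_nu,
    cond_offsets,
    use_te,
    te_edges,
    te_freqs,
    use_y100,
    y_edges,
    y_freqs,
    sim_ks,
    y0,
    dt,
    n_int,
    te_fraction,
    rng,
):
    """Full Metropolis chain for the toy problem.

    Per step: pick one coordinate uniformly, perturb on log10 scale
    (uniform +-sigma_q or Normal(0, sigma_q)), reject out-of-box proposals
    outright, otherwise accept with probability min(1, w'/w).  The current
    weight is cached and only replaced on acceptance.  Returns the thinned
    post-burn-in samples, their weights and per-coordinate accept/propose
    counts.
    """
    k = len(theta0)
    n_rec = (n_steps - burn_in) // thin
    samples = np.empty((n_rec, k))
    weights = np.empty(n_rec)
    acc = np.zeros(k, np.int64)
    prop = np.zeros(k, np.int64)
    theta = theta0.copy()
    w_cur = toy_weight(
        theta[0], theta[1], theta[2],
        clause_ks, clause_ns, clause_nu, cond_offsets,
        use_te, te_edges, te_freqs, use_y100, y_edges, y_freqs,
        sim_ks, y0, dt, n_int, te_fraction,
    )
    rec = 0
    for t in range(1, n_steps + 1):
        j = int(rng.integers(0, k))
        prop[j] += 1
        if kind_normal:
            delta = sigma_q * rng.normal(0.0, 1.0)
        else:
            delta = sigma_q * (2.0 * rng.uniform(0.0, 1.0) - 1.0)
        cand_j = theta[j] + delta
        if lo[j] <= cand_j <= hi[j]:
            old = theta[j]
            theta[j] = cand_j
            w_cand = toy_weight(
                theta[0], theta[1], theta[2],
                clause_ks, clause_ns, clause_nu, cond_offsets,
                use_te, te_edges, te_freqs, use_y100, y_edges, y_freqs,
                sim_ks, y0, dt, n_int, te_fraction,
            )
            if w_cand > 0.0 and rng.uniform(0.0, 1.0) * w_cur < w_cand:
                acc[j] += 1
                w_cur = w_cand
            else:
                theta[j] = old
        if t > burn_in and (t - burn_in) % thin == 0 and rec < n_rec:
            for c in range(k):
                samples[rec, c] = theta[c]
            weights[rec] = w_cur
            rec += 1
    return samples, weights, acc, prop


@njit(cache=True)
def toy_noisy_observables(
    k_d, k_p, K, k_s, y0, dt, n_int, noise_sd, n_replicates, te_fraction,
    reference_max, rng
):
    """Execution time and endpoint value for an ensemble of noisy replicates.

    The execution-time threshold is ``te_fraction * reference_max`` with the
    reference maximum taken from the noise-free dynamics (equivalently the
    bifurcation high branch), so the observable measures rise time rather
    than noise excursions.  Failed (non-finite) replicates return NaN.
    """
    te = np.empty(n_replicates)
    y100 = np.empty(n_replicates)
    thr = te_fraction * reference_max
    for r in range(n_replicates):
        y, bad = toy_rk4_noisy(k_d, k_p, K, k_s, y0, dt, n_int, noise_sd, rng)
        if bad >= 0:
            te[r] = np.nan
            y100[r] = np.nan
            continue
        idx = _first_crossing_index(y, thr)
        te[r] = idx * dt if idx >= 0 else np.nan
        y100[r] = y[len(y) - 1]
    return te, y100


@njit(cache=True)
def toy_det_observables_batch(log10_params, k_s, y0, dt, n_int, te_fraction):
    """Deterministic (T_e, Y_end) for a batch of log10 parameter triples."""
    m = log10_params.shape[0]
    te = np.empty(m)
    yend = np.empty(m)
    for r in range(m):
        k_d = 10.0 ** log10_params[r, 0]
        k_p = 10.0 ** log10_params[r, 1]
        K = 10.0 ** log10_params[r, 2]
        y, bad = toy_rk4(k_d, k_p, K, k_s, y0, dt, n_int)
        if bad >= 0:
            te[r] = np.nan
            yend[r] = np.nan
            continue
        mx = y[0]
        for i in range(1, len(y)):
            if y[i] > mx:
                mx = y[i]
        idx = _first_crossing_index(y, te_fraction * mx)
        te[r] = idx * dt
        yend[r] = y[len(y) - 1]
    return te, yend
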