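import numpy as np
import pytest
from scipy import stats

import hfmcmc as h
from hfmcmc import _kernels
from hfmcmc.fitness import HistogramFitness
from hfmcmc.models import ConfigurationError
from hfmcmc.sampler import (
    ChainStateError,
    InitializationError,
    _pack_conditions,
    metropolis_chain,
)


class StubRng:
    """Deterministic stand-in feeding preset draws to propose()."""

    def __init__(self, j, r):
        self.j, self.r = j, r

    def integers(self, lo, hi):
        return self.j

    def uniform(self, lo=0.0, hi=1.0):
        return self.r

    def normal(self, mu, sd):
        return self.r


class TestPropose:
    def test_uniform_midpoint_leaves_state_unchanged(self, truth):
        cand, j = h.propose(truth, 0.5, "uniform", StubRng(1, 0.5))
        assert j == 1
        np.testing.assert_array_equal(cand.log10_values, truth.log10_values)

    def test_uniform_extreme_shifts_by_sigma(self, truth):
        cand, j = h.propose(truth, 0.5, "uniform", StubRng(2, 1.0))
        assert cand.log10_values[2] == pytest.approx(truth.log10_values[2] + 0.5)
        # exactly one coordinate differs
        assert np.sum(cand.log10_values != truth.log10_values) == 1

    def test_coordinate_choice_uniform(self, truth):
        rng = np.random.default_rng(5)
        n = 100_000
        js = np.array([h.propose(truth, 0.5, "uniform", rng)[1] for _ in range(n)])
        freqs = np.bincount(js, minlength=3) / n
        np.testing.assert_allclose(freqs, 1 / 3, atol=0.01)

    @pytest.mark.parametrize("kind", ["uniform", "normal"])
    def test_proposal_symmetry(self, truth, kind):
        # forward and mirrored jump magnitudes should be indistinguishable
        rng = np.random.default_rng(17)
        deltas = []
        for _ in range(20_000):
            cand, j = h.propose(truth, 0.5, kind, rng)
            deltas.append(cand.log10_values[j] - truth.log10_values[j])
        deltas = np.asarray(deltas)
        edges = np.linspace(0, np.abs(deltas).max() + 1e-9, 11)
        pos, _ = np.histogram(deltas[deltas > 0], bins=edges)
        neg, _ = np.histogram(-deltas[deltas < 0], bins=edges)
        keep = (pos + neg) >= 10
        chi2 = np.sum((pos[keep] - neg[keep]) ** 2 / (pos[keep] + neg[keep]))
        p = 1 - stats.chi2.cdf(chi2, df=keep.sum())
        assert p > 0.01


class TestAcceptanceProbability:
    def test_ratio_cases(self):
        assert h.acceptance_probability(2.0, 2.0) == 1.0
        assert h.acceptance_probability(0.0, 2.0) == 0.0
        assert h.acceptance_probability(1.0, 2.0) == 0.5
        assert h.acceptance_probability(5.0, 2.0) == 1.0

    def test_zero_current_weight_is_an_invariant_violation(self):
        with pytest.raises(ChainStateError):
            h.acceptance_probability(1.0, 0.0)


class TestTargetWeight:
    def test_reference_vector_has_positive_weight(self, full_problem, truth):
        w, breakdown = h.target_weight(full_problem, truth)
        assert w > 0
        assert breakdown["I(B)"] == 1.0
        assert breakdown["I(I)"] == 1.0
        assert w == breakdown["f(T_e)"] * breakdown["f(Y_end)"]

    def test_weak_feedback_rejected_by_conditions_without_simulation(self, full_problem, truth):
        weak = truth.with_log10_values(np.array([0.0, -1.0, np.log10(0.5)]))
        w, breakdown = h.target_weight(full_problem, weak)
        assert w == 0.0
        assert breakdown["I(B)"] == 0.0
        assert "f(T_e)" not in breakdown  # short-circuit: no dynamics run

    def test_out_of_box_scores_zero(self, full_problem, truth):
        outside = truth.replace_log10(0, 1.5)
        assert h.target_weight(full_problem, outside)[0] == 0.0

    def test_observable_outside_histogram_scores_zero(self, hists_weak_noise, truth):
        far = HistogramFitness("T_e", [1000.0, 1001.0], [5.0])
        problem = h.toy_problem(("B", "I", "T_e"), [far])
        assert h.target_weight(problem, truth)[0] == 0.0

    def test_kernel_and_generic_paths_agree_exactly(self, full_problem, truth):
        """The compiled chain kernel and the Python target must give bitwise-equal weights."""
        ck, cns, cnu, off = _pack_conditions(full_problem.conditions)
        te, ye = full_problem.quantitative
        rng = np.random.default_rng(42)
        lo, hi = truth.bounds[:, 0], truth.bounds[:, 1]
        n_pos = 0
        for i in range(60):
            if i < 30:  # global draws (mostly zero weight)
                x = rng.uniform(lo, hi)
            else:  # near the reference vector (positive weight region)
                x = truth.log10_values + rng.uniform(-0.05, 0.05, 3)
            w_py, _ = h.target_weight(full_problem, truth.with_log10_values(x))
            w_k = _kernels.toy_weight(
                x[0], x[1], x[2], ck, cns, cnu, off,
                True, te.bin_edges, te.frequencies,
                True, ye.bin_edges, ye.frequencies,
                1.0, 0.0, 0.01, 10000, 0.9,
            )
            assert w_py == w_k
            n_pos += w_py > 0
        assert n_pos >= 10  # the positive branch was actually exercised


class TestMCMCConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            h.MCMCConfig(n_steps=10, burn_in=10)
        with pytest.raises(ConfigurationError):
            h.MCMCConfig(n_steps=10, thin=0)
        with pytest.raises(ConfigurationError):
            h.MCMCConfig(n_steps=10, sigma_q=0.0)
        with pytest.raises(ConfigurationError):
            h.MCMCConfig(n_steps=10, proposal_kind="cauchy")

    def test_recorded_length(self):
        cfg = h.MCMCConfig(n_steps=3_300_000, burn_in=300_000, thin=3)
        assert cfg.n_recorded == 10**6


class TestRunMCMC:
    def test_trace_invariants_and_constraint_safety(self, short_trace, full_problem):
        cfg = short_trace.config
        assert len(short_trace) == (cfg.n_steps - cfg.burn_in) // cfg.thin
        lo, hi = full_problem.prior.bounds[:, 0], full_problem.prior.bounds[:, 1]
        assert np.all(short_trace.samples >= lo) and np.all(short_trace.samples <= hi)
        assert np.all(short_trace.weights > 0)
        # re-verify a random subsample against the conditions directly
        rng = np.random.default_rng(0)
        idx = rng.choice(len(short_trace), size=60, replace=False)
        for i in idx:
            pv = full_problem.prior.with_log10_values(short_trace.samples[i])
            for cond in full_problem.conditions:
                assert h.evaluate_condition(cond, full_problem.model, pv) == 1

    def test_cached_weights_reproducible(self, short_trace, full_problem):
        rng = np.random.default_rng(1)
        idx = rng.choice(len(short_trace), size=40, replace=False)
        for i in idx:
            pv = full_problem.prior.with_log10_values(short_trace.samples[i])
            w, _ = h.target_weight(full_problem, pv)
            assert w == short_trace.weights[i]

    def test_same_seed_bitwise_reproducible(self, full_problem):
        cfg = h.MCMCConfig(n_steps=3000, burn_in=300, thin=3, seed=21)
        a = h.run_mcmc_hfm(full_problem, cfg)
        b = h.run_mcmc_hfm(full_problem, cfg)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.weights, b.weights)

    def test_generic_driver_matches_kernel_chain(self, hists_weak_noise):
        """Same seed, same problem: compiled and Python chains are identical."""
        problem = h.toy_problem(("B", "I", "T_e", "Y_end"), hists_weak_noise)
        cfg = h.MCMCConfig(n_steps=600, burn_in=100, thin=2, seed=33)
        fast = h.run_mcmc_hfm(problem, cfg)

        template = problem.prior

        def weight_fn(x):
            return h.target_weight(problem, template.with_log10_values(x))[0]

        rng = np.random.default_rng(cfg.seed)
        from hfmcmc.sampler import _initial_state

        theta0 = _initial_state(problem, cfg, rng)
        samples, weights, acc, prop = metropolis_chain(
            weight_fn, theta0.log10_values, problem.prior.bounds, cfg, rng
        )
        np.testing.assert_array_equal(fast.samples, samples)
        np.testing.assert_array_equal(fast.weights, weights)
        np.testing.assert_array_equal(fast.accept_count, acc)

    def test_detailed_balance_surrogate_on_discrete_target(self):
        """Empirical law converges to weight/sum(weight) on a tabulated problem."""
        rng_w = np.random.default_rng(3)
        w = 0.1 + rng_w.random(50)
        bounds = np.array([[0.0, 1.0]])

        def weight_fn(x):
            return w[min(int(x[0] * 50), 49)]

        target = w / w.sum()

        def tv(n_steps, seed):
            cfg = h.MCMCConfig(n_steps=n_steps, burn_in=n_steps // 10, thin=1, sigma_q=0.2, seed=seed)
            samples, _, _, _ = metropolis_chain(
                weight_fn, np.array([0.5]), bounds, cfg, np.random.default_rng(seed)
            )
            emp = np.bincount(
                np.minimum((samples[:, 0] * 50).astype(int), 49), minlength=50
            ) / len(samples)
            return 0.5 * np.abs(emp - target).sum()

        assert tv(200_000, 8) < tv(20_000, 8)
        assert tv(200_000, 8) < 0.05

    def test_initialization_fallback_and_failure(self, toy, truth, hists_weak_noise):
        # a zero-weight explicit start falls back to prior rejection sampling
        weak = truth.with_log10_values(np.array([0.0, -1.0, np.log10(0.5)]))
        problem = h.toy_problem(("B",))
        cfg = h.MCMCConfig(n_steps=200, burn_in=20, seed=5, init=weak)
        trace = h.run_mcmc_hfm(problem, cfg)
        assert np.all(trace.weights > 0)
        # an unsatisfiable target exhausts the budget
        far = HistogramFitness("T_e", [1000.0, 1001.0], [5.0])
        impossible = h.toy_problem(("T_e",), [far])
        with pytest.raises(InitializationError):
            h.run_mcmc_hfm(
                impossible,
                h.MCMCConfig(n_steps=100, burn_in=10, seed=5, init_budget=50),
            )

    def test_trace_csv_round_trip(self, short_trace, tmp_path):
        import json

        import pandas as pd

        path = tmp_path / "trace.csv"
        short_trace.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["step", "log10_k_d", "log10_k_p", "log10_K", "weight"]
        side = json.loads((tmp_path / "trace.csv.json").read_text())
        assert side["names"] == ["k_d", "k_p", "K"]
        assert len(df) == len(short_trace)
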