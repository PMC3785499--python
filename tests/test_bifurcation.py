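import numpy as np
import pytest

import hfmcmc as h
from hfmcmc.bifurcation import (
    ConditionClause,
    ConditionSpec,
    ThresholdClause,
    bifurcation_diagram,
)
from hfmcmc.models import ConfigurationError, ODEModelSpec


def counts(states):
    return (
        sum(s.stability == "stable" for s in states),
        sum(s.stability == "unstable" for s in states),
    )


def brute_force_steady_state_counts(params, k_s, n_grid=10_000):
    """Independent oracle: sign changes of the rhs on a dense grid + bisection.

    Stability from the direction of the sign change (1-D flow: + to - is
    stable, - to + unstable).  Exact zeros at grid points are classified by
    a central finite difference.
    """
    k_d, k_p, K = params["k_d"], params["k_p"], params["K"]

    def f(y):
        return k_s - k_d * y + k_p * y**5 / (K**5 + y**5)

    hi = 1.05 * max(5.0, (k_s + k_p) / k_d)
    g = np.linspace(0.0, hi, n_grid)
    fv = f(g)
    ns = nu = 0
    eps = hi * 1e-9
    for i in range(n_grid):
        if fv[i] == 0.0:
            d = (f(g[i] + eps) - f(max(g[i] - eps, 0.0))) / (g[i] + eps - max(g[i] - eps, 0.0))
            ns, nu = (ns + 1, nu) if d < 0 else (ns, nu + 1)
        elif i > 0 and fv[i - 1] != 0.0 and (fv[i - 1] > 0) != (fv[i] > 0):
            ns, nu = (ns + 1, nu) if fv[i - 1] > 0 else (ns, nu + 1)
    return ns, nu


class TestToySteadyStates:
    @pytest.mark.parametrize(
        "k_s,expected",
        [(0.0, (2, 1)), (0.2, (2, 1)), (0.3, (1, 0)), (1.0, (1, 0))],
    )
    @pytest.mark.parametrize("method", ["bracket", "newton"])
    def test_reference_bifurcation_structure(self, toy, truth, k_s, expected, method):
        states = h.find_steady_states(toy, truth, k_s, method=method)
        assert counts(states) == expected
        assert counts(states) == brute_force_steady_state_counts(truth.as_dict(), k_s)

    def test_saddle_node_roots_at_zero_input(self, toy, truth):
        states = h.find_steady_states(toy, truth, 0.0)
        ys = [float(s.state[0]) for s in states]
        # y*(y^5 - y^4 + K^5) = 0 has roots 0 and 0.5 exactly at K = 0.5
        assert ys[0] == pytest.approx(0.0, abs=1e-10)
        assert ys[1] == pytest.approx(0.5, abs=1e-8)

    def test_oracle_equivalence_on_random_vectors(self, toy, truth):
        rng = np.random.default_rng(123)
        lo, hi = truth.bounds[:, 0], truth.bounds[:, 1]
        for _ in range(200):
            pv = truth.with_log10_values(rng.uniform(lo, hi))
            for k_s in (0.0, 0.2, 0.3, 1.0):
                got = counts(h.find_steady_states(toy, pv, k_s))
                assert got == brute_force_steady_state_counts(pv.as_dict(), k_s)

    def test_count_parity_and_stability_alternation(self, toy, truth):
        rng = np.random.default_rng(7)
        lo, hi = truth.bounds[:, 0], truth.bounds[:, 1]
        for _ in range(100):
            pv = truth.with_log10_values(rng.uniform(lo, hi))
            states = h.find_steady_states(toy, pv, 0.2)
            assert len(states) in (1, 3)
            if len(states) == 3:
                assert [s.stability for s in states] == ["stable", "unstable", "stable"]


class TestFixtureSteadyStates:
    def test_analytic_roots_and_stability(self, fixture2d):
        states = h.find_steady_states(
            fixture2d, fixture2d.reference_params, 0.0, n_starts=15
        )
        vs = sorted(float(s.state[1]) for s in states)
        expected = [0.0, (3 - np.sqrt(5)) / 2, (3 + np.sqrt(5)) / 2]
        np.testing.assert_allclose(vs, expected, atol=1e-8)
        assert [s.stability for s in states] == ["stable", "unstable", "stable"]

    def test_origin_jacobian_spectrum(self, fixture2d):
        ss = h.classify_stability(
            fixture2d, fixture2d.reference_params, 0.0, np.zeros(2)
        )
        # lower-triangular Jacobian [[-1, 0], [1, -1]]
        np.testing.assert_allclose(sorted(ss.eigenvalues.real), [-1.0, -1.0])
        assert ss.stability == "stable"


class TestClassifyStability:
    def test_linear_toy_root_is_stable(self, toy):
        ss = h.classify_stability(toy, {"k_d": 2.0, "k_p": 0.0, "K": 0.5}, 1.0, [0.5])
        assert ss.stability == "stable"
        assert ss.eigenvalues[0].real == pytest.approx(-2.0)

    def test_middle_root_is_unstable(self, toy, truth):
        # at y = K the Hill derivative contributes k_p*5/(4K): -1 + 2.5 = 1.5
        ss = h.classify_stability(toy, truth, 0.0, [0.5])
        assert ss.eigenvalues[0].real == pytest.approx(1.5)
        assert ss.stability == "unstable"

    def test_zero_eigenvalue_is_marginal(self):
        degenerate = ODEModelSpec(
            name="degenerate",
            state_names=("x",),
            input_name="u",
            rhs=lambda s, p, u: -s * s,
            jacobian=lambda s, p, u: np.array([[-2.0 * s[0]]]),
        )
        ss = h.classify_stability(degenerate, {}, 0.0, [0.0])
        assert ss.stability == "marginal"


class TestConditions:
    def test_reference_satisfies_bistability_and_irreversibility(self, toy, truth):
        assert h.evaluate_condition(h.toy_condition_B(), toy, truth) == 1
        assert h.evaluate_condition(h.toy_condition_I(), toy, truth) == 1

    def test_weak_feedback_fails_bistability(self, toy, truth):
        weak = truth.with_log10_values(np.array([0.0, -1.0, np.log10(0.5)]))
        assert h.evaluate_condition(h.toy_condition_B(), toy, weak) == 0

    def test_marginal_steady_state_fails_condition(self):
        degenerate = ODEModelSpec(
            name="degenerate",
            state_names=("x",),
            input_name="u",
            rhs=lambda s, p, u: -s * s,
            jacobian=lambda s, p, u: np.array([[-2.0 * s[0]]]),
            search_box=np.array([[0.0, 1.0]]),
        )
        spec = ConditionSpec("M", (ConditionClause(0.0, 1, 0),))
        assert h.evaluate_condition(spec, degenerate, {}) == 0

    def test_branch_thresholds(self, fixture2d):
        ok = ConditionSpec(
            "T",
            (
                ConditionClause(
                    0.0,
                    2,
                    1,
                    (
                        ThresholdClause("v", "lower", "le", 0.1),
                        ThresholdClause("v", "higher", "ge", 1.0),
                    ),
                ),
            ),
        )
        assert h.evaluate_condition(ok, fixture2d, fixture2d.reference_params, n_starts=15) == 1
        bad = ConditionSpec(
            "T",
            (ConditionClause(0.0, 2, 1, (ThresholdClause("v", "higher", "le", 1.0),)),),
        )
        assert h.evaluate_condition(bad, fixture2d, fixture2d.reference_params, n_starts=15) == 0
        unknown = ConditionSpec(
            "T", (ConditionClause(0.0, 2, 1, (ThresholdClause("w", "lower", "le", 1.0),)),)
        )
        with pytest.raises(ConfigurationError):
            h.evaluate_condition(unknown, fixture2d, fixture2d.reference_params)

    def test_round_trip_serialization(self):
        spec = ConditionSpec(
            "C",
            (ConditionClause(2.0, 2, 1, (ThresholdClause("x", "lower", "le", 1.0),)),),
        )
        assert ConditionSpec.from_dict(spec.to_dict()) == spec


def test_bifurcation_diagram_shape(toy, truth):
    df = bifurcation_diagram(toy, truth, [0.0, 0.2, 0.3, 1.0])
    assert list(df.columns) == ["k_s", "branch", "Y", "stability"]
    assert len(df) == 3 + 3 + 1 + 1
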