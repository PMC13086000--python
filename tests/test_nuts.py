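"""The No-U-Turn engine: leapfrog, step-size search, trees, transitions."""

import numpy as np
import pytest
from scipy import stats

from nuts4pno import (
    NutsOptions,
    adapt_step_size,
    build_tree,
    find_initial_epsilon,
    leapfrog,
    nuts_sample,
    nuts_transition,
    run_block_sampler,
    sample_slice,
)
from nuts4pno.nuts import PhaseState, StepSizeState, _evaluate


def std_normal(x):
    return -0.5 * float(x @ x), -x


def make_state(x, r, fn):
    lp, grad = _evaluate(np.atleast_1d(np.asarray(x, float)), fn)
    return PhaseState(np.atleast_1d(np.asarray(x, float)),
                      np.atleast_1d(np.asarray(r, float)), grad, lp)


class TestLeapfrog:
    def test_zero_gradient_field_is_free_flight(self):
        fn = lambda x: (0.0, np.zeros_like(x))
        s = make_state([1.0, -2.0], [0.5, 0.25], fn)
        out = leapfrog(s, 0.2, fn)
        np.testing.assert_allclose(out.position, s.position + 0.2 * s.momentum)
        np.testing.assert_allclose(out.momentum, s.momentum)

    def test_hand_computed_quadratic_step(self):
        s = make_state([1.0], [0.0], std_normal)
        out = leapfrog(s, 0.1, std_normal)
        assert out.position[0] == pytest.approx(0.995, abs=1e-12)
        assert out.momentum[0] == pytest.approx(-0.09975, abs=1e-12)

    def test_reversibility(self):
        rng = np.random.default_rng(4)
        s = make_state(rng.normal(size=3), rng.normal(size=3), std_normal)
        fwd = s
        for _ in range(25):
            fwd = leapfrog(fwd, 0.1, std_normal)
        back = PhaseState(fwd.position, -fwd.momentum, fwd.grad, fwd.logdens)
        for _ in range(25):
            back = leapfrog(back, 0.1, std_normal)
        np.testing.assert_allclose(back.position, s.position, atol=1e-10)
        np.testing.assert_allclose(-back.momentum, s.momentum, atol=1e-10)

    def test_energy_error_is_second_order_in_step_size(self):
        epsilons = [0.2, 0.1, 0.05, 0.025]
        errs = []
        for eps in epsilons:
            s = make_state([1.0], [0.7], std_normal)
            xi0 = s.xi
            worst = 0.0
            for _ in range(int(round(4.0 / eps))):
                s = leapfrog(s, eps, std_normal)
                worst = max(worst, abs(s.xi - xi0))
            errs.append(worst)
        slope = np.polyfit(np.log(epsilons), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.3)

    def test_divergent_state_flagged_not_raised(self):
        fn = lambda x: (np.nan, np.zeros_like(x))
        s = PhaseState(np.array([0.0]), np.array([1.0]), np.array([0.0]), 0.0)
        out = leapfrog(s, 0.5, fn)
        assert out.logdens == -np.inf


class TestInitialStepSize:
    def test_returned_epsilon_brackets_half_acceptance(self):
        fn = std_normal
        x0 = np.array([0.4])
        step = find_initial_epsilon(x0, fn, np.random.default_rng(0))
        # replay the momentum the search used to evaluate Omega(eps)
        r = np.random.default_rng(0).standard_normal(1)
        s = make_state(x0, r, fn)
        omega = lambda e: np.exp(leapfrog(s, e, fn).xi - s.xi)
        w = omega(step.epsilon)
        rho = 1.0 if omega(1.0) > 0.5 else -1.0
        assert not w ** rho > 2.0 ** (-rho)          # stopping held
        assert omega(step.epsilon / 2.0 ** rho) ** rho > 2.0 ** (-rho)

    def test_peaked_target_halves_step_size(self):
        sigma = 1e-4
        fn = lambda x: (-0.5 * float(x @ x) / sigma ** 2, -x / sigma ** 2)
        step = find_initial_epsilon(np.array([0.0]), fn, np.random.default_rng(2))
        assert step.epsilon <= 2e-3

    def test_well_matched_target_doubles_at_least_once(self):
        # wide target: eps = 1 keeps Omega near 1, so the search must double
        fn = lambda x: (-0.5 * float(x @ x) / 100.0, -x / 100.0)
        step = find_initial_epsilon(np.array([0.0]), fn, np.random.default_rng(3))
        assert step.epsilon >= 2.0
        assert step.iota == pytest.approx(np.log(10 * step.epsilon))
        assert step.epsilon_bar == 1.0 and step.H == 0.0


class TestSliceVariable:
    def test_level_never_exceeds_xi0(self):
        rng = np.random.default_rng(1)
        assert all(sample_slice(2.5, rng) <= 2.5 for _ in range(1000))

    def test_gap_is_unit_exponential(self):
        rng = np.random.default_rng(8)
        gaps = np.array([1.3 - sample_slice(1.3, rng) for _ in range(100_000)])
        assert stats.kstest(gaps, "expon").pvalue > 0.01


def iterative_build_tree(direction, state, u0, xi0, depth, eps, fn, rng,
                         options):
    """Explicit doubling oracle: sequential leaves + post-order merges."""
    leaves = []
    cur = state
    for _ in range(2 ** depth):
        cur = leapfrog(cur, direction * eps, fn)
        leaves.append(cur)

    def leaf_node(leaf):
        xi1 = leaf.xi
        return {
            "minus": leaf, "plus": leaf, "prop": leaf,
            "n": int(u0 < xi1), "stop": (u0 - options.delta_max) >= xi1,
            "lam_a": min(1.0, np.exp(min(xi1 - xi0, 0.0))), "lam_b": 1.0,
            "size": 1,
        }

    stack = []
    for leaf in leaves:
        stack.append(leaf_node(leaf))
        while len(stack) >= 2 and stack[-1]["size"] == stack[-2]["size"]:
            outer = stack.pop()
            inner = stack.pop()
            minus = outer["minus"] if direction == -1 else inner["minus"]
            plus = inner["plus"] if direction == -1 else outer["plus"]
            total = inner["n"] + outer["n"]
            x = rng.random()
            prop = (outer["prop"] if total > 0 and x < outer["n"] / total
                    else inner["prop"])
            span = plus.position - minus.position
            uturn = (span @ minus.momentum) < 0 or (span @ plus.momentum) < 0
            stack.append({
                "minus": minus, "plus": plus, "prop": prop, "n": total,
                "stop": outer["stop"] or uturn,
                "lam_a": inner["lam_a"] + outer["lam_a"],
                "lam_b": inner["lam_b"] + outer["lam_b"],
                "size": inner["size"] * 2,
            })
    assert len(stack) == 1
    return stack[0]


class TestBuildTree:
    def test_depth_zero_accept_and_acceptance_statistic(self):
        fn = std_normal
        s = make_state([0.3, -0.2], [0.4, 0.1], fn)
        opts = NutsOptions()
        u0 = s.xi - 5.0                  # large Exp(1) draw: leaf acceptable
        tree = build_tree(1, s, u0, s.xi, 0, 0.01, fn,
                          np.random.default_rng(0), opts)
        assert tree.n_b == 1 and not tree.stop
        assert tree.lam_a == pytest.approx(1.0, abs=1e-4)  # tiny step: energy kept
        assert tree.lam_b == 1.0

    @pytest.mark.parametrize("direction", [-1, 1])
    def test_depth_three_matches_iterative_doubling_oracle(self, direction):
        fn = std_normal
        opts = NutsOptions()
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        s = make_state([0.5, -1.0], [0.8, 0.6], fn)
        u0 = s.xi - 1.7
        tree = build_tree(direction, s, u0, s.xi, 3, 0.05, fn, rng1, opts)
        oracle = iterative_build_tree(direction, s, u0, s.xi, 3, 0.05, fn,
                                      rng2, opts)
        assert not tree.stop and not oracle["stop"]
        assert tree.n_b == oracle["n"]
        assert tree.lam_a == pytest.approx(oracle["lam_a"], rel=1e-12)
        assert tree.lam_b == oracle["lam_b"]
        for mine, ref in [(tree.minus, oracle["minus"]),
                          (tree.plus, oracle["plus"]),
                          (tree.proposal, oracle["prop"])]:
            np.testing.assert_allclose(mine.position, ref.position, atol=1e-13)
            np.testing.assert_allclose(mine.momentum, ref.momentum, atol=1e-13)


class TestTransition:
    def test_zero_step_size_keeps_position(self):
        fn = lambda x: (0.0, np.zeros_like(x))
        pos, lam_c, info = nuts_transition(
            np.array([1.5]), 0.0, fn, np.random.default_rng(0))
        assert pos[0] == 1.5
        assert 0.0 <= lam_c <= 1.0

    def test_standard_normal_moments(self):
        import arviz
        rng = np.random.default_rng(11)
        draws = np.empty(20_000)
        pos = np.array([0.0])
        for k in range(draws.shape[0]):
            pos, _, _ = nuts_transition(pos, 0.9, std_normal, rng)
            draws[k] = pos[0]
        ess = float(arviz.ess(draws.reshape(1, -1)))
        mcse_mean = draws.std() / np.sqrt(ess)
        assert abs(draws.mean()) < 3 * mcse_mean
        ess2 = float(arviz.ess((draws ** 2).reshape(1, -1)))
        mcse_var = (draws ** 2).std() / np.sqrt(ess2)
        assert abs(draws.var() - 1.0) < 3 * mcse_var

    def test_correlated_normal_recovers_correlation(self):
        rho = 0.9
        prec = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))
        fn = lambda x: (-0.5 * float(x @ prec @ x), -prec @ x)
        rng = np.random.default_rng(21)
        draws = nuts_sample(fn, np.zeros(2), 8000, rng)
        r = np.corrcoef(draws.T)[0, 1]
        assert r == pytest.approx(rho, abs=0.05)


class TestDualAveraging:
    def test_on_target_acceptance_keeps_H_zero(self):
        st0 = StepSizeState(epsilon=0.5, iota=np.log(5.0))
        out = adapt_step_size(st0, 0.8)
        assert out.H == pytest.approx(0.0)
        assert out.epsilon == pytest.approx(np.exp(st0.iota))

    def test_first_iteration_weights(self):
        st0 = StepSizeState(epsilon=0.5, iota=np.log(5.0))
        out = adapt_step_size(st0, 0.3)
        # k=1: eta_a = 1/11, eta_b = 1 so epsilon_bar tracks epsilon exactly
        assert out.H == pytest.approx((0.8 - 0.3) / 11.0)
        assert out.epsilon_bar == pytest.approx(out.epsilon)

    def test_sustained_low_acceptance_shrinks_epsilon(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            st = StepSizeState(epsilon=1.0, iota=np.log(10.0))
            lam_stream = rng.uniform(0.0, 0.5, size=30)
            eps_path = []
            for lam in lam_stream:
                st = adapt_step_size(st, lam)
                eps_path.append(st.epsilon)
            assert all(np.diff(eps_path) < 0)

    def test_out_of_range_statistic_clamped(self):
        st0 = StepSizeState(epsilon=1.0, iota=np.log(10.0))
        assert adapt_step_size(st0, 1.7).H == adapt_step_size(st0, 1.0).H


class TestBlockSampler:
    @staticmethod
    def _bivariate(rho=0.6):
        prec = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))

        def block_lp_grad(b, x_b, positions):
            v = np.array([positions[0][0], positions[1][0]])
            v[b] = x_b[0]
            grad = -(prec @ v)
            return -0.5 * float(v @ prec @ v), np.array([grad[b]])

        return block_lp_grad

    def test_marginals_match_closed_form(self):
        draws = run_block_sampler(self._bivariate(), [[0.0], [0.0]],
                                  n_iter=4000, n_chains=2, seed=10)
        x = np.concatenate([c[0][:, 0] for c in draws])
        assert abs(x.mean()) < 0.08          # sd/sqrt(ess) ~ 0.02
        assert x.var() == pytest.approx(1.0, abs=0.12)

    def test_seeded_run_is_reproducible(self):
        a = run_block_sampler(self._bivariate(), [[0.2], [-0.1]],
                              n_iter=200, n_chains=2, seed=5)
        b = run_block_sampler(self._bivariate(), [[0.2], [-0.1]],
                              n_iter=200, n_chains=2, seed=5)
        for ca, cb in zip(a, b):
            for xa, xb in zip(ca, cb):
                np.testing.assert_array_equal(xa, xb)

    def test_retained_draw_count_is_second_half(self):
        fn = lambda b, x, pos: (-0.5 * float(x @ x), -x)
        draws = run_block_sampler(fn, [[0.0]], n_iter=2000, n_chains=1, seed=0)
        assert draws[0][0].shape == (1000, 1)
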