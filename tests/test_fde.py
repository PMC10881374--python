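"""Solver tests: scheme weights, oracle equivalence, restarts, determinism."""

import math

import numpy as np
import pytest
from scipy.special import erfc

import caputoland as cl
from caputoland.fde import (
    SolverConfig,
    corrector_step,
    corrector_weights,
    initial_weight,
    predictor_step,
    predictor_weights,
)


class TestWeights:
    def test_integer_order_collapse(self):
        """At alpha=1 the scheme is Euler-predict / trapezoid-correct exactly."""
        n = np.arange(1, 1001)
        assert corrector_weights(0, 1.0) == pytest.approx(0.5, abs=1e-12)
        assert np.max(np.abs(corrector_weights(n, 1.0) - 1.0)) < 1e-12
        assert np.max(np.abs(initial_weight(n, 1.0) - 0.5)) < 1e-12
        b = predictor_weights(1.0, 1000)
        assert np.max(np.abs(b[1:] - 1.0)) < 1e-12

    @pytest.mark.parametrize("alpha", [0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    def test_corrector_weights_positive(self, alpha):
        n = np.arange(0, 10001)
        assert np.all(corrector_weights(n, alpha) > 0)

    def test_beta0_value(self):
        assert corrector_weights(0, 1.0) == pytest.approx(1.0 / math.gamma(3.0))

    def test_predictor_single_term(self):
        # n=1: y_P = y0 + h^a f0 / Gamma(a+1)
        for a in (0.4, 1.0, 1.7):
            got = predictor_step([2.0], y0=1.0, h=0.1, alpha=a, n=1)
            assert got == pytest.approx(1.0 + 0.1**a * 2.0 / math.gamma(a + 1.0))

    def test_corrector_heun_hand_value(self):
        """One PECE step of dy=-y at alpha=1, h=0.1 equals Heun's 0.905."""
        y0, h = 1.0, 0.1
        f0 = -y0
        y_pred = predictor_step([f0], y0, h, 1.0, 1)
        assert y_pred == pytest.approx(0.9)
        y1 = corrector_step(y_pred, [f0], y0, h, 1.0, rhs_at_tn=-y_pred)
        assert y1 == pytest.approx(0.905, abs=1e-14)


class TestMittagLeffler:
    def test_at_zero(self):
        for a in (0.3, 1.0, 1.8):
            assert cl.mittag_leffler(a, 0.0) == 1.0

    def test_exponential_identity(self):
        assert cl.mittag_leffler(1.0, -1.0) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_cosine_identity(self):
        assert cl.mittag_leffler(2.0, -1.0) == pytest.approx(math.cos(1.0), rel=1e-12)

    def test_erfc_identity(self):
        assert cl.mittag_leffler(0.5, -1.0) == pytest.approx(math.e * erfc(1.0), rel=1e-10)

    def test_strongly_negative_argument(self):
        # cancellation-heavy case handled by extended precision
        val = cl.mittag_leffler(0.5, -5.0)
        exact = math.exp(25.0) * erfc(5.0)
        assert val == pytest.approx(exact, rel=1e-8)


class TestScalarRelaxation:
    @pytest.mark.parametrize("alpha", [0.5, 0.8, 1.0])
    def test_tracks_mittag_leffler(self, alpha):
        cfg = SolverConfig(h=1e-3, t0=0.0, t_end=1.0)
        traj = cl.solve_multi_order(lambda t, y: -y, [alpha], [1.0], cfg)
        exact = cl.mittag_leffler(alpha, -1.0)
        assert traj.y[-1, 0] == pytest.approx(exact, rel=1e-3)

    def test_zero_rhs_constant_solution(self):
        cfg = SolverConfig(h=1e-2, t0=0.0, t_end=0.5)
        traj = cl.solve_multi_order(lambda t, y: np.zeros_like(y), [0.6, 1.4], [2.0, -1.0], cfg)
        assert np.all(traj.y == [2.0, -1.0])

    def test_corrected_vs_predicted_refinement(self):
        """Corrector error shrinks faster than predictor error under h-refinement."""
        alpha = 0.6
        errs = []
        for h in (4e-3, 1e-3):
            cfg = SolverConfig(h=h, t0=0.0, t_end=1.0)
            traj = cl.solve_multi_order(lambda t, y: -y, [alpha], [1.0], cfg)
            errs.append(abs(traj.y[-1, 0] - cl.mittag_leffler(alpha, -1.0)))
        order = np.log(errs[0] / errs[1]) / np.log(4.0)
        assert order > 1.0 + alpha - 0.2

    def test_two_component_closed_form(self):
        cfg = SolverConfig(h=1e-3, t0=0.0, t_end=1.0)
        traj = cl.solve_multi_order(
            lambda t, y: np.array([-y[0], y[0] - y[1]]), [1.0, 1.0], [1.0, 0.0], cfg
        )
        t = traj.t
        assert np.max(np.abs(traj.y[:, 0] - np.exp(-t))) < 1e-4
        assert np.max(np.abs(traj.y[:, 1] - t * np.exp(-t))) < 1e-4


class TestDivergenceHandling:
    def test_divergent_flagged_not_raised(self):
        cfg = SolverConfig(h=0.1, t0=0.0, t_end=5.0, divergence_bound=100.0)
        traj = cl.solve_multi_order(lambda t, y: 10.0 * y, [1.0], [1.0], cfg)
        assert traj.divergent
        assert traj.t.size < cfg.n_steps + 1

    def test_restart_refused_for_divergent(self):
        cfg = SolverConfig(h=0.1, t0=0.0, t_end=5.0, divergence_bound=100.0)
        traj = cl.solve_multi_order(lambda t, y: 10.0 * y, [1.0], [1.0], cfg)
        with pytest.raises(RuntimeError, match="divergent"):
            cl.restart_segment(traj, SolverConfig(h=0.1, t0=5.0, t_end=6.0))


class TestRestart:
    def test_constant_at_steady_state(self, params):
        from caputoland import land
        from caputoland.protocol import solve_cls_segment

        ss = cl.steady_state(params).as_array()
        f = land.make_rhs(params, lam=params.lambda_0, dlam=0.0, ca=params.Ca_i)
        first = solve_cls_segment(f, np.full(6, 0.8), ss, SolverConfig(h=1e-3, t0=0, t_end=0.2))
        y1, cfg2 = cl.restart_segment(first, SolverConfig(h=1e-3, t0=0.2, t_end=0.4))
        second = solve_cls_segment(f, np.full(6, 0.8), y1, cfg2)
        assert np.max(np.abs(second.y - ss)) < 1e-8

    def test_integer_order_split_equals_unsplit(self):
        rhs = lambda t, y: -y
        full = cl.solve_multi_order(rhs, [1.0], [1.0], SolverConfig(h=1e-3, t0=0, t_end=2.0))
        part1 = cl.solve_multi_order(rhs, [1.0], [1.0], SolverConfig(h=1e-3, t0=0, t_end=1.0))
        y1, cfg2 = cl.restart_segment(part1, SolverConfig(h=1e-3, t0=1.0, t_end=2.0))
        part2 = cl.solve_multi_order(rhs, [1.0], y1, cfg2)
        assert abs(part2.y[-1, 0] - full.y[-1, 0]) < 1e-6

    def test_fractional_split_differs_from_unsplit(self):
        """Memory reset at the restart changes a fractional trajectory (non-locality)."""
        rhs = lambda t, y: -y
        alpha = [0.7]
        full = cl.solve_multi_order(rhs, alpha, [1.0], SolverConfig(h=1e-3, t0=0, t_end=2.0))
        part1 = cl.solve_multi_order(rhs, alpha, [1.0], SolverConfig(h=1e-3, t0=0, t_end=1.0))
        y1, cfg2 = cl.restart_segment(part1, SolverConfig(h=1e-3, t0=1.0, t_end=2.0))
        part2 = cl.solve_multi_order(rhs, alpha, y1, cfg2)
        diff = abs(part2.y[-1, 0] - full.y[-1, 0])
        assert diff > 1e-6  # nonzero by non-locality; magnitude not asserted


class TestReferenceOde:
    def test_constant_input_stays_constant(self, params):
        from caputoland import land

        ss = cl.steady_state(params).as_array()
        f = land.make_rhs(params, lam=params.lambda_0, dlam=0.0, ca=params.Ca_i)
        traj = cl.reference_ode_solve(f, ss, SolverConfig(h=1e-3, t0=0, t_end=1.0))
        assert np.max(np.abs(traj.y - ss)) < 1e-6

    def test_tolerance_convergence(self):
        rhs = lambda t, y: np.array([-y[0]])
        cfg = SolverConfig(h=1e-2, t0=0, t_end=1.0)
        a = cl.reference_ode_solve(rhs, [1.0], cfg, rtol=1e-8, atol=1e-11)
        b = cl.reference_ode_solve(rhs, [1.0], cfg, rtol=5e-9, atol=5e-12)
        assert abs(a.y[-1, 0] - b.y[-1, 0]) < 1e-8


class TestDeterminism:
    def test_bit_identical_trajectories(self, params, protocol_1pct, ci_solver):
        a = cl.simulate_protocol(params, cl.AlphaVector(W=1.3), cl.AlphaVector(B=0.7), protocol_1pct, ci_solver)
        b = cl.simulate_protocol(params, cl.AlphaVector(W=1.3), cl.AlphaVector(B=0.7), protocol_1pct, ci_solver)
        assert np.array_equal(a.tension, b.tension)
        assert np.array_equal(a.time, b.time)


class TestAlphaVector:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            cl.AlphaVector(S=0.0)
        with pytest.raises(ValueError):
            cl.AlphaVector(W=2.5)

    def test_roundtrip(self):
        a = cl.AlphaVector(S=0.9, W=1.4, CaTRPN=1.1, B=0.5, zeta_s=1.0, zeta_w=0.8)
        assert cl.AlphaVector.from_array(a.as_array()) == a


class TestMemoryTruncation:
    def test_truncation_changes_fractional_result(self):
        rhs = lambda t, y: -y
        full = cl.solve_multi_order(rhs, [0.5], [1.0], SolverConfig(h=1e-3, t0=0, t_end=1.0))
        trunc = cl.solve_multi_order(
            rhs, [0.5], [1.0], SolverConfig(h=1e-3, t0=0, t_end=1.0, memory_length=50)
        )
        assert abs(full.y[-1, 0] - trunc.y[-1, 0]) > 1e-6

    def test_longer_memory_reduces_truncation_error(self):
        rhs = lambda t, y: -y
        cfgs = [SolverConfig(h=1e-3, t0=0, t_end=1.0, memory_length=L) for L in (50, 400)]
        full = cl.solve_multi_order(rhs, [0.5], [1.0], SolverConfig(h=1e-3, t0=0, t_end=1.0))
        errs = [
            abs(cl.solve_multi_order(rhs, [0.5], [1.0], c).y[-1, 0] - full.y[-1, 0]) for c in cfgs
        ]
        assert errs[1] < errs[0]
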