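"""Error measures, stability classification, order scans and the GA."""

from dataclasses import replace

import numpy as np
import pytest

import caputoland as cl
from caputoland.calibration import (
    GAConfig,
    StabilityCriteria,
    classify_response,
    default_bounds,
    fractionality,
    ga_fit,
)
from caputoland.protocol import split_segments


def _const_trace(value, n=200, dt=1e-3):
    t = np.arange(n) * dt
    return cl.TensionTrace(t, np.full(n, float(value)))


class TestErrorMeasures:
    def test_identical_traces(self):
        a = _const_trace(1.0)
        assert cl.mse(a, a) == 0.0
        assert cl.max_abs_error(a, a) == 0.0

    def test_constant_offset(self):
        a, b = _const_trace(1.0), _const_trace(1.25)
        assert cl.mse(a, b) == pytest.approx(0.25**2)
        assert cl.max_abs_error(a, b) == pytest.approx(0.25)

    def test_norm_inequality(self, rng):
        t = np.arange(500) * 1e-3
        a = cl.TensionTrace(t, 1 + 0.1 * rng.random(500))
        b = cl.TensionTrace(t, 1 + 0.1 * rng.random(500))
        assert cl.max_abs_error(a, b) >= np.sqrt(cl.mse(a, b))

    def test_common_time_shift_invariance(self):
        t = np.arange(300) * 1e-3
        values = np.sin(t * 3.0)
        a = cl.TensionTrace(t, values)
        b = cl.TensionTrace(t, values + 0.1)
        a2 = cl.TensionTrace(t + 5.0, values)
        b2 = cl.TensionTrace(t + 5.0, values + 0.1)
        assert cl.mse(a, b) == pytest.approx(cl.mse(a2, b2))

    def test_disjoint_traces_rejected(self):
        t = np.arange(100) * 1e-3
        a = cl.TensionTrace(t, np.ones(100))
        b = cl.TensionTrace(t + 10.0, np.ones(100))
        with pytest.raises(ValueError, match="overlap"):
            cl.mse(a, b)


class TestClassifyResponse:
    def test_monotone_decay_stable(self):
        t = np.arange(1000) * 1e-3
        trace = cl.TensionTrace(t, 1.0 + 0.2 * np.exp(-t / 0.05))
        assert classify_response(trace).label == "stable"

    def test_growing_trace_divergent_flag(self):
        t = np.arange(100) * 1e-3
        trace = cl.TensionTrace(t, np.exp(t * 100), meta={"divergent": True})
        assert classify_response(trace).label == "divergent"

    def test_ringing_underdamped(self):
        t = np.arange(1000) * 1e-3
        trace = cl.TensionTrace(t, 1.0 + 0.2 * np.exp(-t / 0.3) * np.cos(t * 60))
        result = classify_response(trace)
        assert result.label == "underdamped"
        assert result.metrics["oscillation_count"] > 2

    def test_sluggish_overdamped(self):
        t = np.arange(1000) * 1e-3
        trace = cl.TensionTrace(t, 1.0 + 0.2 * np.exp(-t / 5.0))
        assert classify_response(trace).label == "overdamped"

    def test_flat_trace_stable(self):
        assert classify_response(_const_trace(1.0)).label == "stable"


class TestAlphaRangeScan:
    def test_default_grid_has_twenty_points(self, params, protocol_1pct, ci_solver):
        res = cl.alpha_range_scan(5, params, protocol_1pct, ci_solver)
        assert res["n_evaluations"] == 20
        assert len(res["labels"]) == 20

    def test_interval_contains_one(self, params, protocol_1pct, ci_solver):
        # the integer-order reference model is stable, so alpha = 1 must be inside
        for idx in (0, 3):
            res = cl.alpha_range_scan(idx, params, protocol_1pct, ci_solver)
            lo, hi = res["interval"]
            assert lo <= 1.0 <= hi

    def test_invalid_grid_rejected(self, params, protocol_1pct, ci_solver):
        with pytest.raises(ValueError, match="grid"):
            cl.alpha_range_scan(0, params, protocol_1pct, ci_solver, grid=[0.0, 1.0])


class TestFractionality:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(0.79, "high"), (1.2, "low"), (1.0, "low"), (1.21, "high"), (0.8, "low")],
    )
    def test_threshold_strict(self, alpha, expected):
        labels = fractionality(np.array([alpha, 1, 1, 1, 1, 1]))
        assert labels["S"] == expected


class TestGAConfig:
    def test_bound_validation(self):
        with pytest.raises(ValueError, match="lower bound"):
            GAConfig(lower_bounds=(1.5,) * 6, upper_bounds=(1.0,) * 6)

    def test_seeded_individual_within_bounds(self):
        with pytest.raises(ValueError, match="seeded"):
            GAConfig(seeded_individuals=((3.0,) * 6,))

    def test_all_ones_inside_both_segment_boxes(self):
        for kind in ("stretch", "release"):
            lb, ub = default_bounds(kind)
            assert np.all(lb <= 1.0) and np.all(1.0 <= ub)


@pytest.fixture(scope="module")
def stretch_segment_data(request):
    """Noiseless integer-order stretch segment used by quick GA checks."""
    params = cl.default_params()
    proto = cl.make_quick_stretch_protocol(0.01, lambda_0=params.lambda_0, rise_time=4e-3)
    cfg = cl.SolverConfig(h=1e-3, t0=0.0, t_end=1.0)
    trace = cl.simulate_protocol(params, cl.AlphaVector.ones(), cl.AlphaVector.ones(), proto, cfg)
    stretch, _ = split_segments(trace, proto)
    return params, proto, cfg, stretch


class TestGaFit:
    def test_tolerance_at_generation_zero(self, stretch_segment_data):
        """Seeded all-ones individual satisfies a loose tolerance immediately."""
        params, proto, cfg, data = stretch_segment_data
        ga = GAConfig(population_size=8, max_generations=10, mse_tolerance=1e-3, rng_seed=0)
        fit = ga_fit(data, "stretch", params, ga.for_segment("stretch"), cfg, proto)
        assert fit.termination_reason == "tolerance"
        assert fit.generations_used == 0
        assert fit.mse < 1e-3
        assert np.allclose(fit.alpha_f.as_array(), 1.0)

    def test_reproducible_with_seed(self, stretch_segment_data):
        params, proto, cfg, data = stretch_segment_data
        ga = replace(
            GAConfig(population_size=6, max_generations=3, mse_tolerance=1e-15, rng_seed=7),
            stall_generations=100,
        )
        fit1 = ga_fit(data, "stretch", params, ga.for_segment("stretch"), cfg, proto)
        fit2 = ga_fit(data, "stretch", params, ga.for_segment("stretch"), cfg, proto)
        assert np.array_equal(fit1.alpha_f.as_array(), fit2.alpha_f.as_array())
        assert fit1.mse == fit2.mse
        assert fit1.best_mse_history == fit2.best_mse_history

    def test_bounds_respected_and_progress_monotone(self, stretch_segment_data):
        params, proto, cfg, data = stretch_segment_data
        ga = GAConfig(population_size=6, max_generations=4, mse_tolerance=1e-15, rng_seed=11)
        fit = ga_fit(data, "stretch", params, ga.for_segment("stretch"), cfg, proto)
        lb, ub = default_bounds("stretch")
        a = fit.alpha_f.as_array()
        assert np.all(a >= lb) and np.all(a <= ub)
        hist = np.array(fit.best_mse_history)
        assert np.all(np.diff(hist) <= 0)

    def test_release_requires_initial_state(self, stretch_segment_data):
        params, proto, cfg, data = stretch_segment_data
        ga = GAConfig(population_size=4, max_generations=2)
        with pytest.raises(ValueError, match="initial_state"):
            ga_fit(data, "release", params, ga.for_segment("release"), cfg, proto)


class TestEnvelope:
    def test_single_trace(self, trace_1pct_ones):
        lo, hi = cl.cls_envelope([trace_1pct_ones])
        assert np.array_equal(lo.tension, trace_1pct_ones.tension)
        assert np.array_equal(hi.tension, trace_1pct_ones.tension)

    def test_bounds_members(self, trace_1pct_ones, params, protocol_1pct, ci_solver):
        other = cl.simulate_protocol(
            params, cl.AlphaVector(W=1.3), cl.AlphaVector(B=0.8), protocol_1pct, ci_solver
        )
        lo, hi = cl.cls_envelope([trace_1pct_ones, other])
        for tr in (trace_1pct_ones, other):
            assert np.all(lo.tension <= tr.tension + 1e-15)
            assert np.all(hi.tension >= tr.tension - 1e-15)

    def test_mixed_protocols_rejected(self, trace_1pct_ones):
        with pytest.raises(ValueError, match="protocol"):
            cl.cls_envelope([trace_1pct_ones, trace_1pct_ones], protocols=[0.01, 0.02])
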