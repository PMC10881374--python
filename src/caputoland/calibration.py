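"""Calibration of per-state fractional orders against tension traces.

The calibration pipeline: screen each state's admissible order range for
mechanical stability, then fit the six-order vector per segment with a
real-coded genetic algorithm whose fitness is the mean-square error between
the simulated and measured normalized tension.  Per-state fractionality is
classified by the distance of the fitted order from 1: ``|alpha - 1| > 0.2``
(strict) marks a state as a significant viscoelastic contributor.

GA internals (the published workflow delegates these to a toolbox's
defaults): tournament selection of size 4, blend crossover with probability
0.8, Gaussian mutation with a decaying sigma of 10% of the bound width, 5%
elitism, and clipping to the per-segment bound box.  A seeded all-ones
individual guarantees the fit can never do worse than the integer-order
reference model (up to solver tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from . import land
from .fde import AlphaVector, SolverConfig
from .protocol import (
    Protocol,
    TensionTrace,
    reference_protocol_solve,
    simulate_protocol,
    solve_cls_segment,
    split_segments,
)

__all__ = [
    "STRETCH_LOWER",
    "STRETCH_UPPER",
    "RELEASE_LOWER",
    "RELEASE_UPPER",
    "GAConfig",
    "FitResult",
    "SubjectReport",
    "StabilityCriteria",
    "StabilityClassification",
    "mse",
    "max_abs_error",
    "classify_response",
    "alpha_range_scan",
    "ga_fit",
    "fractionality",
    "fit_subject",
    "cls_envelope",
    "default_bounds",
]

# Per-segment GA search boxes over (S, W, CaTRPN, B, zeta_s, zeta_w).
STRETCH_LOWER = (0.9, 0.1, 0.8, 0.1, 0.1, 0.1)
STRETCH_UPPER = (1.3, 1.6, 2.0, 2.0, 1.4, 1.3)
RELEASE_LOWER = (0.1, 0.1, 0.8, 0.1, 0.6, 0.5)
RELEASE_UPPER = (1.2, 1.5, 1.8, 1.9, 1.4, 1.3)

FRACTIONALITY_THRESHOLD = 0.2


def default_bounds(segment_kind: str) -> tuple[np.ndarray, np.ndarray]:
    if segment_kind == "stretch":
        return np.array(STRETCH_LOWER), np.array(STRETCH_UPPER)
    if segment_kind == "release":
        return np.array(RELEASE_LOWER), np.array(RELEASE_UPPER)
    raise ValueError(f"segment_kind must be 'stretch' or 'release', got {segment_kind!r}")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (defaults follow the published workflow)."""

    lower_bounds: tuple = STRETCH_LOWER
    upper_bounds: tuple = STRETCH_UPPER
    mse_tolerance: float = 1e-5
    population_size: int = 50
    max_generations: int = 700
    seeded_individuals: tuple = ((1.0, 1.0, 1.0, 1.0, 1.0, 1.0),)
    rng_seed: int = 0
    tournament_size: int = 4
    crossover_prob: float = 0.8
    blend_alpha: float = 0.5
    mutation_prob: float = 1.0 / 6.0
    mutation_sigma_frac: float = 0.10
    mutation_sigma_floor_frac: float = 0.005
    elite_frac: float = 0.05
    stall_generations: int = 50

    def __post_init__(self) -> None:
        lb, ub = np.asarray(self.lower_bounds), np.asarray(self.upper_bounds)
        if lb.shape != (6,) or ub.shape != (6,):
            raise ValueError("GA bounds must be 6-vectors")
        if np.any(lb > ub):
            bad = [land.STATE_NAMES[i] for i in np.nonzero(lb > ub)[0]]
            raise ValueError(f"lower bound exceeds upper bound for state(s) {bad}")
        for seeded in self.seeded_individuals:
            s = np.asarray(seeded)
            if np.any(s < lb) or np.any(s > ub):
                raise ValueError(f"seeded individual {seeded} outside the bound box")

    def for_segment(self, segment_kind: str) -> "GAConfig":
        lb, ub = default_bounds(segment_kind)
        return replace(self, lower_bounds=tuple(lb), upper_bounds=tuple(ub))


@dataclass
class FitResult:
    """Outcome of a single-segment GA fit."""

    alpha_f: AlphaVector
    mse: float
    max_abs_error: float
    generations_used: int
    termination_reason: str  # tolerance | max_generations | stall
    fractionality: dict
    segment_kind: str
    n_evaluations: int = 0
    best_mse_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be non-negative")
        if self.termination_reason not in ("tolerance", "max_generations", "stall"):
            raise ValueError(f"unknown termination reason {self.termination_reason!r}")


@dataclass(frozen=True)
class StabilityCriteria:
    """Operationalization of the under/overdamped screening of scanned orders."""

    max_oscillations: int = 2  # post-peak local extrema allowed
    min_settling: float = 0.5  # minimum fraction of peak-to-plateau recovery
    prominence_frac: float = 0.02  # extrema prominence, fraction of peak deviation


@dataclass
class StabilityClassification:
    label: str  # stable | underdamped | overdamped | divergent
    metrics: dict


# ---------------------------------------------------------------------------
# error measures


def _common_grids(model_trace: TensionTrace, data_trace: TensionTrace) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate the model trace onto the data grid (overlap required)."""
    t = data_trace.time
    lo = max(t[0], model_trace.time[0])
    hi = min(t[-1], model_trace.time[-1])
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    if not mask.any():
        raise ValueError("traces have no overlapping time support")
    tm = t[mask]
    model_on_data = np.interp(tm, model_trace.time, model_trace.tension)
    return model_on_data, data_trace.tension[mask]


def mse(model_trace: TensionTrace, data_trace: TensionTrace) -> float:
    """Mean-square error between normalized tensions on the data grid."""
    a, b = _common_grids(model_trace, data_trace)
    return float(np.mean((a - b) ** 2))


def max_abs_error(model_trace: TensionTrace, data_trace: TensionTrace) -> float:
    """Maximum pointwise absolute tension difference on the data grid."""
    a, b = _common_grids(model_trace, data_trace)
    return float(np.max(np.abs(a - b)))


# ---------------------------------------------------------------------------
# stability screening


def classify_response(trace: TensionTrace, criteria: StabilityCriteria | None = None) -> StabilityClassification:
    """Classify a single-segment response as stable/underdamped/overdamped/divergent.

    The deviation from the segment's starting tension defines the response:
    its largest excursion is the peak; post-peak local extrema beyond the
    allowed count indicate ringing (underdamped); failure to recover at least
    ``min_settling`` of the peak-to-plateau excursion by the segment end
    indicates a sluggish (overdamped) response.
    """
    crit = criteria or StabilityCriteria()
    if trace.divergent or not np.all(np.isfinite(trace.tension)):
        return StabilityClassification("divergent", {"boundedness": False})
    dev = trace.tension - trace.tension[0]
    peak_idx = int(np.argmax(np.abs(dev)))
    peak = float(np.abs(dev[peak_idx]))
    metrics: dict = {"boundedness": True, "peak_deviation": peak}
    if peak == 0.0:
        metrics.update(oscillation_count=0, settling_ratio=1.0, late_drift=0.0)
        return StabilityClassification("stable", metrics)
    tail = dev[peak_idx:]
    prom = crit.prominence_frac * peak
    n_osc = int(len(find_peaks(tail, prominence=prom)[0]) + len(find_peaks(-tail, prominence=prom)[0]))
    settling = float(np.clip(1.0 - abs(dev[-1]) / peak, 0.0, 1.0))
    # a response may legitimately relax to a new plateau (excursion never
    # reverts toward the start); "settled" then means the tail has flattened
    late = dev[int(0.8 * dev.size) :]
    drift = float(abs(late[-1] - late[0]) / peak) if late.size >= 2 else 0.0
    metrics.update(oscillation_count=n_osc, settling_ratio=settling, late_drift=drift)
    if n_osc > crit.max_oscillations:
        return StabilityClassification("underdamped", metrics)
    if settling >= crit.min_settling or drift < 0.05:
        return StabilityClassification("stable", metrics)
    return StabilityClassification("overdamped", metrics)


def alpha_range_scan(
    state_index: int,
    params,
    protocol: Protocol,
    solver_config: SolverConfig,
    grid: Sequence[float] | None = None,
    segment_kind: str = "stretch",
    criteria: StabilityCriteria | None = None,
) -> dict:
    """Screen one state's admissible fractional-order range for stability.

    The state's order sweeps the grid (default 0.1..2.0 in steps of 0.1, 20
    evaluations) while every other order is held at 1; each full protocol is
    simulated and the chosen segment's response classified.  Returns the
    maximal contiguous stable sub-grid, ties broken toward the interval
    containing alpha = 1.
    """
    if grid is None:
        grid = np.round(np.arange(0.1, 2.0001, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid > 2):
        raise ValueError("scan grid must lie in (0, 2]")
    labels = []
    for a_val in grid:
        vec = np.ones(6)
        vec[state_index] = a_val
        alpha = AlphaVector.from_array(vec)
        trace = simulate_protocol(params, alpha, alpha, protocol, solver_config)
        stretch_seg, release_seg = split_segments(trace, protocol) if not trace.divergent else (trace, trace)
        seg = stretch_seg if segment_kind == "stretch" else release_seg
        labels.append(classify_response(seg, criteria).label)
    stable = np.array([lab == "stable" for lab in labels])
    runs: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(stable):
        if ok and start is None:
            start = i
        if (not ok or i == len(stable) - 1) and start is not None:
            end = i if ok else i - 1
            runs.append((start, end))
            start = None
    result = {
        "state": land.STATE_NAMES[state_index],
        "grid": grid,
        "labels": labels,
        "n_evaluations": int(len(grid)),
        "interval": None,
    }
    if not runs:
        return result
    best_len = max(e - s for s, e in runs)
    candidates = [(s, e) for s, e in runs if e - s == best_len]
    one_idx = int(np.argmin(np.abs(grid - 1.0)))
    chosen = next(((s, e) for s, e in candidates if s <= one_idx <= e), candidates[0])
    result["interval"] = (float(grid[chosen[0]]), float(grid[chosen[1]]))
    return result


# ---------------------------------------------------------------------------
# genetic algorithm


def fractionality(alpha_f: "AlphaVector | Sequence[float]") -> dict:
    """Per-state fractionality label: high iff ``|alpha - 1| > 0.2`` (strict)."""
    a = alpha_f.as_array() if isinstance(alpha_f, AlphaVector) else np.asarray(alpha_f, dtype=float)
    return {
        name: ("high" if abs(ai - 1.0) > FRACTIONALITY_THRESHOLD else "low")
        for name, ai in zip(land.STATE_NAMES, a)
    }


def _simulate_segment(
    alpha_vec: np.ndarray,
    segment_kind: str,
    params,
    protocol: Protocol,
    solver_config: SolverConfig,
    initial_state: np.ndarray,
    baseline_tension: float,
    rhs,
) -> TensionTrace:
    """Simulate one fitting segment under a candidate order vector."""
    if segment_kind == "stretch":
        t0, t1 = protocol.t_stretch_on, protocol.t_release
    else:
        t0, t1 = protocol.t_release, protocol.t_end
    cfg = replace(solver_config, t0=t0, t_end=t1)
    traj = solve_cls_segment(rhs, alpha_vec, initial_state, cfg)
    lfac = land.length_factor(protocol.lambda_0, params)
    tension = land.active_tension(traj.y, lfac) / baseline_tension
    return TensionTrace(
        traj.t, tension, segment_kind, baseline_tension, {"divergent": traj.divergent}
    )


def ga_fit(
    data_segment: TensionTrace,
    segment_kind: str,
    params,
    ga_config: GAConfig,
    solver_config: SolverConfig,
    protocol: Protocol,
    initial_state: np.ndarray | None = None,
) -> FitResult:
    """Fit the six fractional orders of one segment by GA-minimized MSE.

    The data segment must be normalized (pre-stretch plateau = 1) and lie on
    or be interpolable to the solver grid.  For a stretch segment the model
    starts from the pre-stretch steady state; for a release segment
    ``initial_state`` must carry the terminal state of the stretch
    simulation (the Caputo memory is reset at the segment boundary).
    Fully reproducible for a fixed ``ga_config.rng_seed``.
    """
    lb = np.asarray(ga_config.lower_bounds, dtype=float)
    ub = np.asarray(ga_config.upper_bounds, dtype=float)
    rng = np.random.default_rng(ga_config.rng_seed)
    ca0 = protocol.ca(protocol.t_stretch_on - 1e-9, params)
    ss = land.steady_state(params, Ca=ca0, lam=protocol.lambda_0)
    if initial_state is None:
        if segment_kind != "stretch":
            raise ValueError("release fits require the stretch terminal state as initial_state")
        initial_state = ss.as_array()
    baseline = float(land.active_tension(ss, land.length_factor(protocol.lambda_0, params)))
    rhs = land.make_rhs(params, lam=protocol.lam, dlam=protocol.dlam, ca=(lambda t: protocol.ca(t, params)))

    n_eval = 0

    def fitness(vec: np.ndarray) -> tuple[float, float]:
        nonlocal n_eval
        n_eval += 1
        trace = _simulate_segment(vec, segment_kind, params, protocol, solver_config, initial_state, baseline, rhs)
        if trace.divergent or trace.time.size < 2:
            return np.inf, np.inf
        return mse(trace, data_segment), max_abs_error(trace, data_segment)

    pop_size = ga_config.population_size
    seeds = [np.clip(np.asarray(s, dtype=float), lb, ub) for s in ga_config.seeded_individuals]
    pop = np.empty((pop_size, 6))
    for i, s in enumerate(seeds[:pop_size]):
        pop[i] = s
    n_random = pop_size - min(len(seeds), pop_size)
    pop[pop_size - n_random :] = lb + rng.random((n_random, 6)) * (ub - lb)

    fits = np.empty(pop_size)
    maxerrs = np.empty(pop_size)
    for i in range(pop_size):
        fits[i], maxerrs[i] = fitness(pop[i])
    if not np.any(np.isfinite(fits)):
        raise RuntimeError(
            "every individual in generation 0 produced a divergent simulation; "
            "review the order bounds for this segment"
        )

    best_idx = int(np.argmin(fits))
    best_vec, best_mse, best_maxerr = pop[best_idx].copy(), float(fits[best_idx]), float(maxerrs[best_idx])
    history = [best_mse]
    n_elite = max(1, int(np.ceil(ga_config.elite_frac * pop_size)))
    sigma0 = ga_config.mutation_sigma_frac * (ub - lb)
    sigma_floor = ga_config.mutation_sigma_floor_frac * (ub - lb)
    reason = "max_generations"
    gen = 0
    if best_mse < ga_config.mse_tolerance:
        reason = "tolerance"
    else:
        stall_anchor = best_mse
        stall_count = 0
        for gen in range(1, ga_config.max_generations + 1):
            order = np.argsort(fits)
            elites = pop[order[:n_elite]].copy()
            elite_fits = fits[order[:n_elite]].copy()
            elite_maxerrs = maxerrs[order[:n_elite]].copy()
            # tournament selection
            def select() -> np.ndarray:
                idx = rng.integers(0, pop_size, size=ga_config.tournament_size)
                return pop[idx[np.argmin(fits[idx])]]

            children = np.empty_like(pop)
            children[:n_elite] = elites
            decay = max(1.0 - gen / ga_config.max_generations, 0.0)
            sigma = sigma_floor + decay * (sigma0 - sigma_floor)
            for i in range(n_elite, pop_size):
                p1, p2 = select(), select()
                if rng.random() < ga_config.crossover_prob:
                    # blend (BLX-alpha) crossover
                    lo = np.minimum(p1, p2)
                    hi = np.maximum(p1, p2)
                    span = hi - lo
                    child = lo - ga_config.blend_alpha * span + rng.random(6) * (1 + 2 * ga_config.blend_alpha) * span
                else:
                    child = p1.copy()
                mut = rng.random(6) < ga_config.mutation_prob
                child = child + mut * rng.normal(0.0, 1.0, size=6) * sigma
                children[i] = np.clip(child, lb, ub)
            pop = children
            fits[:n_elite] = elite_fits
            maxerrs[:n_elite] = elite_maxerrs
            for i in range(n_elite, pop_size):
                fits[i], maxerrs[i] = fitness(pop[i])
            order_f = np.argsort(fits)
            if float(fits[order_f[0]]) < best_mse:
                best_idx = int(order_f[0])
                best_vec, best_mse, best_maxerr = pop[best_idx].copy(), float(fits[best_idx]), float(maxerrs[best_idx])
            history.append(best_mse)
            if best_mse < ga_config.mse_tolerance:
                reason = "tolerance"
                break
            if stall_anchor - best_mse > ga_config.mse_tolerance:
                stall_anchor = best_mse
                stall_count = 0
            else:
                stall_count += 1
                if stall_count >= ga_config.stall_generations:
                    reason = "stall"
                    break

    return FitResult(
        alpha_f=AlphaVector.from_array(best_vec),
        mse=best_mse,
        max_abs_error=best_maxerr,
        generations_used=gen,
        termination_reason=reason,
        fractionality=fractionality(best_vec),
        segment_kind=segment_kind,
        n_evaluations=n_eval,
        best_mse_history=history,
    )


# ---------------------------------------------------------------------------
# subject-level consolidation


@dataclass
class SubjectReport:
    """Consolidated two-segment fit of one sample."""

    stretch: FitResult
    release: FitResult
    cls_trace: TensionTrace
    baseline_trace: TensionTrace
    cls_mse: float
    cls_max_abs_error: float
    baseline_mse: float
    baseline_max_abs_error: float
    boundary_jump: float
    fractionality_stretch: dict
    fractionality_release: dict


def fit_subject(
    sample: "dict | tuple",
    params,
    protocol: Protocol,
    ga_config: GAConfig,
    solver_config: SolverConfig,
    *,
    baseline_rtol: float = 1e-9,
) -> SubjectReport:
    """Fit both segments of one sample and compare with the ODE baseline.

    ``sample`` provides the normalized ``stretch`` and ``release`` data
    segments (dict keys or a 2-tuple).  The stretch fit's terminal simulated
    state seeds the release simulation (memory reset at the boundary).  CLS
    and integer-order baseline errors are computed on the same data grid and
    normalization.
    """
    if isinstance(sample, dict):
        stretch_data, release_data = sample["stretch"], sample["release"]
    else:
        stretch_data, release_data = sample
    ga_s = ga_config.for_segment("stretch")
    ga_r = replace(ga_config.for_segment("release"), rng_seed=ga_config.rng_seed + 1)

    fit_s = ga_fit(stretch_data, "stretch", params, ga_s, solver_config, protocol)
    # terminal state of the best stretch simulation seeds the release segment
    ca0 = protocol.ca(protocol.t_stretch_on - 1e-9, params)
    ss = land.steady_state(params, Ca=ca0, lam=protocol.lambda_0)
    baseline_t = float(land.active_tension(ss, land.length_factor(protocol.lambda_0, params)))
    rhs = land.make_rhs(params, lam=protocol.lam, dlam=protocol.dlam, ca=(lambda t: protocol.ca(t, params)))
    stretch_sim_traj = solve_cls_segment(
        rhs,
        fit_s.alpha_f,
        ss.as_array(),
        replace(solver_config, t0=protocol.t_stretch_on, t_end=protocol.t_release),
    )
    terminal = stretch_sim_traj.terminal_state
    fit_r = ga_fit(release_data, "release", params, ga_r, solver_config, protocol, initial_state=terminal)

    cls_trace = simulate_protocol(params, fit_s.alpha_f, fit_r.alpha_f, protocol, solver_config)
    baseline_trace = reference_protocol_solve(params, protocol, solver_config, rtol=baseline_rtol)
    full_data = TensionTrace(
        np.concatenate([stretch_data.time, release_data.time]),
        np.concatenate([stretch_data.tension, release_data.tension]),
        "full",
        stretch_data.normalization_reference,
    )
    split_idx = int(np.searchsorted(cls_trace.time, protocol.t_release - 1e-12))
    jump = float(abs(cls_trace.tension[split_idx] - cls_trace.tension[split_idx - 1])) if 0 < split_idx < cls_trace.time.size else 0.0
    return SubjectReport(
        stretch=fit_s,
        release=fit_r,
        cls_trace=cls_trace,
        baseline_trace=baseline_trace,
        cls_mse=mse(cls_trace, full_data),
        cls_max_abs_error=max_abs_error(cls_trace, full_data),
        baseline_mse=mse(baseline_trace, full_data),
        baseline_max_abs_error=max_abs_error(baseline_trace, full_data),
        boundary_jump=jump,
        fractionality_stretch=fit_s.fractionality,
        fractionality_release=fit_r.fractionality,
    )


def cls_envelope(traces: Sequence[TensionTrace], protocols: Sequence[float] | None = None) -> tuple[TensionTrace, TensionTrace]:
    """Pointwise min/max tension envelope over fitted traces of one protocol."""
    if len(traces) < 1:
        raise ValueError("envelope requires at least one trace")
    if protocols is not None and len(set(protocols)) > 1:
        raise ValueError(f"envelope requires a single protocol, got {sorted(set(protocols))}")
    t = traces[0].time
    stack = []
    for tr in traces:
        if tr.time.shape != t.shape or not np.allclose(tr.time, t):
            tr = tr.interp_to(t)
        stack.append(tr.tension)
    arr = np.vstack(stack)
    lo = TensionTrace(t.copy(), arr.min(axis=0), traces[0].segment, None, {"envelope": "min"})
    hi = TensionTrace(t.copy(), arr.max(axis=0), traces[0].segment, None, {"envelope": "max"})
    return lo, hi
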