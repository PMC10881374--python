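"""Quick stretch-and-release protocols and tension-trace preprocessing.

A protocol is a piecewise-linear relative-length signal lambda(t): baseline
``lambda_0``, a ramp of duration ``rise_time`` up to
``lambda_0 * (1 + stretch_fraction)`` at stretch onset, a hold, and a
symmetric ramp back at release.  The experimental recordings this emulates
are 2-s activation windows split into a 1-s stretch and a 1-s release
segment (half-open convention: the release segment owns the shared boundary
instant).

Preprocessing operations — clipping to the activation window, splitting into
segments, normalization to the pre-stretch plateau — mirror how measured
tension traces are prepared before model fitting.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import land
from .fde import AlphaVector, SolverConfig, Trajectory, restart_segment, solve_multi_order

__all__ = [
    "Protocol",
    "TensionTrace",
    "make_quick_stretch_protocol",
    "lambda_rate",
    "clip_activation_window",
    "split_segments",
    "normalize_trace",
    "denormalize_trace",
    "simulate_protocol",
    "solve_cls_segment",
    "reference_protocol_solve",
]

STANDARD_STRETCH_FRACTIONS = (0.005, 0.01, 0.02)


@dataclass(frozen=True)
class Protocol:
    """Quick stretch-and-release input definition on the clipped window."""

    stretch_fraction: float
    lambda_0: float = 1.1
    t_stretch_on: float = 0.0
    t_release: float = 1.0
    t_end: float = 2.0
    rise_time: float = 1e-3
    ramp_shape: str = "cosine"  # cosine (C1-smooth) | linear (exact piecewise)
    Ca_input: "float | Callable[[float], float] | None" = None  # None -> params.Ca_i

    def __post_init__(self) -> None:
        if not self.stretch_fraction >= 0:
            raise ValueError("stretch_fraction must be non-negative")
        if not self.rise_time > 0:
            raise ValueError("rise_time must be positive")
        if not self.t_stretch_on < self.t_release < self.t_end:
            raise ValueError("require t_stretch_on < t_release < t_end")
        if self.ramp_shape not in ("cosine", "linear"):
            raise ValueError("ramp_shape must be 'cosine' or 'linear'")

    @property
    def lambda_hold(self) -> float:
        return self.lambda_0 * (1.0 + self.stretch_fraction)

    def breakpoints(self) -> list[float]:
        return [
            self.t_stretch_on,
            self.t_stretch_on + self.rise_time,
            self.t_release,
            self.t_release + self.rise_time,
        ]

    def _ramp(self, tau: float) -> float:
        """Normalized ramp position in [0, 1] for tau in [0, rise_time]."""
        x = tau / self.rise_time
        if self.ramp_shape == "linear":
            return x
        return 0.5 * (1.0 - np.cos(np.pi * x))

    def _ramp_rate(self, tau: float) -> float:
        x = tau / self.rise_time
        if self.ramp_shape == "linear":
            return 1.0 / self.rise_time
        return 0.5 * np.pi * np.sin(np.pi * x) / self.rise_time

    def lam(self, t: float) -> float:
        """Relative sarcomere length at time ``t``."""
        dl = self.lambda_0 * self.stretch_fraction
        if t < self.t_stretch_on:
            return self.lambda_0
        if t < self.t_stretch_on + self.rise_time:
            return self.lambda_0 + dl * self._ramp(t - self.t_stretch_on)
        if t < self.t_release:
            return self.lambda_hold
        if t < self.t_release + self.rise_time:
            return self.lambda_hold - dl * self._ramp(t - self.t_release)
        return self.lambda_0

    def dlam(self, t: float) -> float:
        """Exact derivative d(lambda)/dt of the ramped step."""
        dl = self.lambda_0 * self.stretch_fraction
        if self.t_stretch_on <= t < self.t_stretch_on + self.rise_time:
            return dl * self._ramp_rate(t - self.t_stretch_on)
        if self.t_release <= t < self.t_release + self.rise_time:
            return -dl * self._ramp_rate(t - self.t_release)
        return 0.0

    def ca(self, t: float, params=None) -> float:
        if self.Ca_input is None:
            if params is None:
                raise ValueError("protocol has no Ca_input and no params were given")
            return params.Ca_i
        if callable(self.Ca_input):
            return self.Ca_input(t)
        return float(self.Ca_input)


def make_quick_stretch_protocol(
    stretch_fraction: float,
    lambda_0: float = 1.1,
    t_stretch_on: float = 0.0,
    t_release: float = 1.0,
    duration: float = 2.0,
    rise_time: float = 1e-3,
    ramp_shape: str = "cosine",
    Ca_input: "float | Callable[[float], float] | None" = None,
    solver_h: float | None = None,
) -> Protocol:
    """Build a ramped step protocol; errors if the ramp is shorter than a step."""
    if solver_h is not None and rise_time < solver_h:
        raise ValueError(f"rise_time={rise_time} is shorter than the solver step h={solver_h}")
    return Protocol(
        stretch_fraction=stretch_fraction,
        lambda_0=lambda_0,
        t_stretch_on=t_stretch_on,
        t_release=t_release,
        t_end=t_stretch_on + duration,
        rise_time=rise_time,
        ramp_shape=ramp_shape,
        Ca_input=Ca_input,
    )


def lambda_rate(protocol: Protocol, t: float) -> float:
    """d(lambda)/dt of the protocol at time ``t``."""
    return protocol.dlam(t)


@dataclass
class TensionTrace:
    """Uniformly sampled time/tension series with normalization metadata."""

    time: np.ndarray
    tension: np.ndarray
    segment: str = "full"  # full | stretch | release
    normalization_reference: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.tension = np.asarray(self.tension, dtype=float)
        if self.time.shape != self.tension.shape or self.time.ndim != 1:
            raise ValueError("time and tension must be 1-D arrays of equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def divergent(self) -> bool:
        return bool(self.meta.get("divergent", False))

    def copy(self) -> "TensionTrace":
        return TensionTrace(
            self.time.copy(), self.tension.copy(), self.segment, self.normalization_reference, dict(self.meta)
        )

    def interp_to(self, time: np.ndarray) -> "TensionTrace":
        """Linear interpolation onto another grid (used to compare grids)."""
        time = np.asarray(time, dtype=float)
        if time[0] < self.time[0] - 1e-12 or time[-1] > self.time[-1] + 1e-12:
            raise ValueError("target grid extends beyond the trace extent")
        out = self.copy()
        out.time = time
        out.tension = np.interp(time, self.time, self.tension)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "tension": self.tension})

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# segment: {self.segment}\n")
            if self.normalization_reference is not None:
                fh.write(f"# normalization_reference: {self.normalization_reference!r}\n")
            for key, value in self.meta.items():
                if isinstance(value, (str, int, float, bool)):
                    fh.write(f"# {key}: {value!r}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TensionTrace":
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                body_start = i + 1
                key, _, value = line[1:].partition(":")
                try:
                    meta[key.strip()] = ast.literal_eval(value.strip())
                except (ValueError, SyntaxError):
                    meta[key.strip()] = value.strip()
            else:
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])))
        segment = meta.pop("segment", "full")
        ref = meta.pop("normalization_reference", None)
        return cls(df["time_s"].to_numpy(), df["tension"].to_numpy(), segment, ref, meta)


def clip_activation_window(trace: TensionTrace, window_start: float, duration: float = 2.0) -> TensionTrace:
    """Clip the activation window ``[window_start, window_start + duration)``.

    Times are relabelled to start at zero; the original offset is recorded in
    the metadata.
    """
    t0, t1 = window_start, window_start + duration
    if t0 < trace.time[0] - 1e-12 or t1 > trace.time[-1] + trace.dt + 1e-12:
        raise ValueError(
            f"window [{t0}, {t1}) extends beyond the trace extent "
            f"[{trace.time[0]}, {trace.time[-1]}]"
        )
    mask = (trace.time >= t0 - 1e-12) & (trace.time < t1 - 1e-12)
    out = trace.copy()
    out.time = trace.time[mask] - t0
    out.tension = trace.tension[mask]
    out.meta["clip_offset_s"] = float(out.meta.get("clip_offset_s", 0.0) + t0)
    out.meta["clip_duration_s"] = float(duration)
    return out


def split_segments(trace: TensionTrace, protocol: Protocol) -> tuple[TensionTrace, TensionTrace]:
    """Split a clipped trace at the release instant.

    Half-open convention: the stretch segment covers
    ``[t_stretch_on, t_release)`` and the release segment ``[t_release, end]``
    — the boundary sample belongs to the release segment.
    """
    t_split = protocol.t_release
    if not (trace.time[0] - 1e-12 <= t_split <= trace.time[-1] + 1e-12):
        raise ValueError(f"release time {t_split} outside trace extent")
    idx = int(np.searchsorted(trace.time, t_split - 1e-12))
    stretch = trace.copy()
    stretch.time, stretch.tension, stretch.segment = trace.time[:idx], trace.tension[:idx], "stretch"
    release = trace.copy()
    release.time, release.tension, release.segment = trace.time[idx:], trace.tension[idx:], "release"
    return stretch, release


def normalize_trace(
    trace: TensionTrace,
    protocol: Protocol | None = None,
    reference: float | None = None,
    window_s: float = 0.010,
) -> TensionTrace:
    """Normalize tension to the pre-stretch plateau.

    The default reference is the mean tension over the final ``window_s``
    before stretch onset; if no samples precede the onset (simulated traces
    start at the onset), the first sample is used.  An explicit ``reference``
    overrides the rule.  The reference is stored in the metadata so the
    operation can be inverted and alternative rules compared.
    """
    if reference is None:
        t_on = protocol.t_stretch_on if protocol is not None else trace.time[0]
        mask = (trace.time >= t_on - window_s) & (trace.time < t_on)
        reference = float(trace.tension[mask].mean()) if mask.any() else float(trace.tension[0])
    if not reference > 0:
        raise ValueError(f"normalization reference must be positive, got {reference}")
    out = trace.copy()
    out.tension = trace.tension / reference
    prior = trace.normalization_reference or 1.0
    out.normalization_reference = float(prior * reference)
    return out


def denormalize_trace(trace: TensionTrace) -> TensionTrace:
    """Invert :func:`normalize_trace` using the stored reference."""
    if trace.normalization_reference is None:
        raise ValueError("trace carries no normalization reference")
    out = trace.copy()
    out.tension = trace.tension * trace.normalization_reference
    out.normalization_reference = None
    return out


# ---------------------------------------------------------------------------
# simulation


def _segment_config(base: SolverConfig, t0: float, t_end: float) -> SolverConfig:
    return replace(base, t0=t0, t_end=t_end)


def solve_cls_segment(rhs, alpha, y0, config: SolverConfig) -> Trajectory:
    """Solve one CLS segment with the fractional operator on the ms timescale.

    ``rhs`` and ``config`` are in seconds; the solve happens in units of
    :data:`caputoland.land.FRACTIONAL_TIME_UNIT_S` (identical dynamics at
    alpha = 1, the model's defining convention otherwise).  The returned
    trajectory grid and rhs cache are converted back to seconds.
    """
    unit = land.FRACTIONAL_TIME_UNIT_S
    scale = 1.0 / unit

    def rhs_u(tu: float, y: np.ndarray) -> np.ndarray:
        return rhs(tu * unit, y) * unit

    cfg_u = replace(config, h=config.h * scale, t0=config.t0 * scale, t_end=config.t_end * scale)
    traj = solve_multi_order(rhs_u, alpha, y0, cfg_u)
    traj.t = traj.t * unit
    if traj.f is not None:
        traj.f = traj.f * scale
    traj.config = config
    return traj


def simulate_protocol(
    params,
    alpha_stretch: AlphaVector,
    alpha_release: AlphaVector,
    protocol: Protocol,
    solver_config: SolverConfig,
    *,
    normalized: bool = True,
    w_influx_power_stroke_rate: bool = False,
    return_trajectories: bool = False,
):
    """Simulate the full quick stretch-and-release tension response.

    Workflow: steady-state initialization at the pre-stretch length and
    calcium level; solve the stretch segment under ``alpha_stretch``; restart
    the Caputo operator (memory reset, terminal states as the new initial
    condition) at the release instant; solve the release segment under
    ``alpha_release``; concatenate.  Tension is evaluated at every grid point
    and, by default, normalized to the pre-stretch steady-state plateau.

    A divergent segment yields a truncated trace flagged in the metadata.
    """
    if protocol.rise_time < solver_config.h - 1e-15:
        raise ValueError("protocol rise_time is shorter than the solver step h")
    ca0 = protocol.ca(protocol.t_stretch_on - 1e-9, params)
    y0 = land.steady_state(params, Ca=ca0, lam=protocol.lambda_0, w_influx_power_stroke_rate=w_influx_power_stroke_rate).as_array()
    rhs = land.make_rhs(
        params,
        lam=protocol.lam,
        dlam=protocol.dlam,
        ca=(lambda t: protocol.ca(t, params)),
        w_influx_power_stroke_rate=w_influx_power_stroke_rate,
    )
    lfac = land.length_factor(protocol.lambda_0, params)

    cfg_s = _segment_config(solver_config, protocol.t_stretch_on, protocol.t_release)
    traj_s = solve_cls_segment(rhs, alpha_stretch, y0, cfg_s)
    trajectories = [traj_s]
    if traj_s.divergent:
        tension = land.active_tension(traj_s.y, lfac)
        trace = _assemble_trace(traj_s.t, tension, lfac, y0, normalized, divergent=True)
        return (trace, trajectories) if return_trajectories else trace

    y1, cfg_r = restart_segment(traj_s, _segment_config(solver_config, protocol.t_release, protocol.t_end))
    traj_r = solve_cls_segment(rhs, alpha_release, y1, cfg_r)
    trajectories.append(traj_r)

    t_full = np.concatenate([traj_s.t[:-1], traj_r.t])
    y_full = np.vstack([traj_s.y[:-1], traj_r.y])
    tension = land.active_tension(y_full, lfac)
    trace = _assemble_trace(t_full, tension, lfac, y0, normalized, divergent=traj_r.divergent)
    return (trace, trajectories) if return_trajectories else trace


def _assemble_trace(t, tension, lfac, y0, normalized, divergent):
    baseline = float(land.active_tension(y0, lfac))
    meta = {"divergent": divergent, "baseline_tension_kpa": baseline}
    if normalized:
        trace = TensionTrace(t, tension / baseline, "full", baseline, meta)
    else:
        trace = TensionTrace(t, tension, "full", None, meta)
    return trace


def reference_protocol_solve(
    params,
    protocol: Protocol,
    solver_config: SolverConfig,
    *,
    normalized: bool = True,
    w_influx_power_stroke_rate: bool = False,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> TensionTrace:
    """Classical integer-order ("ODE-Land") solution of the same protocol.

    Integrated piecewise between the ramp corners with an adaptive stiff-aware
    integrator; serves as the reference model in CLS comparisons.
    """
    from .fde import reference_ode_solve

    ca0 = protocol.ca(protocol.t_stretch_on - 1e-9, params)
    y0 = land.steady_state(params, Ca=ca0, lam=protocol.lambda_0, w_influx_power_stroke_rate=w_influx_power_stroke_rate).as_array()
    rhs = land.make_rhs(
        params,
        lam=protocol.lam,
        dlam=protocol.dlam,
        ca=(lambda t: protocol.ca(t, params)),
        w_influx_power_stroke_rate=w_influx_power_stroke_rate,
    )
    cfg = _segment_config(solver_config, protocol.t_stretch_on, protocol.t_end)
    traj = reference_ode_solve(rhs, y0, cfg, breakpoints=protocol.breakpoints(), rtol=rtol, atol=atol)
    lfac = land.length_factor(protocol.lambda_0, params)
    tension = land.active_tension(traj.y, lfac)
    return _assemble_trace(traj.t, tension, lfac, y0, normalized, divergent=False)
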