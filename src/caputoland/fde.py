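"""Multi-order Caputo fractional initial-value solver (PECE scheme).

Each state ``y_i`` evolves under its own fractional order ``alpha_i`` via the
Adams-type predictor-corrector on a uniform grid ``t_j = t0 + j h``:

predictor::

    y_n^P = T(t_n) + h^a * sum_{j=0}^{n-1} ((n-j)^a - (n-j-1)^a) / Gamma(a+1) * f_j

corrector::

    y_n = T(t_n) + h^a * ( a_{n,0} f_0 + sum_{j=1}^{n-1} beta_{n-j} f_j
                           + beta_0 f(t_n, y_n^P) )

with ``beta_0 = 1/Gamma(a+2)``,
``beta_n = ((n-1)^{a+1} - 2 n^{a+1} + (n+1)^{a+1}) / Gamma(a+2)`` and
``a_{n,0} = ((n-1)^{a+1} - n^a (n - a - 1)) / Gamma(a+2)``.

``T(t)`` is the Caputo initial-condition polynomial: ``y0`` for
``alpha <= 1`` and ``y0 + y'(t0) (t - t0)`` for ``alpha in (1, 2]``, where the
initial derivative defaults to the right-hand side at ``t0`` (zero when
starting from a steady state).  At ``alpha = 1`` the scheme collapses exactly
to explicit-Euler prediction with trapezoidal (Heun) correction.

The full history convolution is kept by default (O(N^2) cost); truncation to
a finite memory window is available but changes results and is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import gamma as _gamma
from pathlib import Path
from typing import Callable, Sequence

import mpmath
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .land import STATE_NAMES

__all__ = [
    "AlphaVector",
    "SolverConfig",
    "Trajectory",
    "predictor_weights",
    "predictor_step",
    "corrector_weights",
    "initial_weight",
    "corrector_step",
    "solve_multi_order",
    "restart_segment",
    "mittag_leffler",
    "reference_ode_solve",
]

ALPHA_MIN, ALPHA_MAX = 0.0, 2.0


@dataclass(frozen=True)
class AlphaVector:
    """Per-state fractional orders, each in (0, 2]."""

    S: float = 1.0
    W: float = 1.0
    CaTRPN: float = 1.0
    B: float = 1.0
    zeta_s: float = 1.0
    zeta_w: float = 1.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            a = getattr(self, name)
            if not (ALPHA_MIN < a <= ALPHA_MAX):
                raise ValueError(f"alpha_{name}={a} outside (0, 2]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "AlphaVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (6,):
            raise ValueError(f"expected 6 fractional orders, got shape {a.shape}")
        return cls(**dict(zip(STATE_NAMES, map(float, a))))

    @classmethod
    def ones(cls) -> "AlphaVector":
        return cls()


@dataclass(frozen=True)
class SolverConfig:
    """Configuration of one solver segment on a closed uniform grid."""

    h: float = 5e-5  # step size, s (0.05 ms default)
    t0: float = 0.0
    t_end: float = 1.0
    memory_length: int | None = None  # None = full memory (default)
    divergence_bound: float = 1e3
    corrector_iterations: int = 1
    initial_derivative: str = "rhs"  # "rhs" | "zero", used only for alpha > 1

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError("step size h must be positive")
        if not self.t_end > self.t0:
            raise ValueError("t_end must exceed t0")
        if self.corrector_iterations < 1:
            raise ValueError("at least one corrector iteration is required")
        if self.initial_derivative not in ("rhs", "zero"):
            raise ValueError("initial_derivative must be 'rhs' or 'zero'")

    @property
    def n_steps(self) -> int:
        n = int(round((self.t_end - self.t0) / self.h))
        if abs(self.t0 + n * self.h - self.t_end) > 1e-9 * max(1.0, abs(self.t_end)):
            raise ValueError("segment length is not an integer multiple of h")
        return n

    def grid(self) -> np.ndarray:
        # linspace keeps both endpoints exact (t0 + j*h accumulates error)
        return np.linspace(self.t0, self.t_end, self.n_steps + 1)


@dataclass
class Trajectory:
    """Solution on a uniform grid, with the cached rhs history."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), n_states)
    f: np.ndarray | None = None  # cached rhs values, same shape as y
    divergent: bool = False
    alpha: np.ndarray | None = None
    config: SolverConfig | None = None
    columns: tuple = STATE_NAMES

    def __post_init__(self) -> None:
        if self.y.shape[0] != self.t.shape[0]:
            raise ValueError("time grid and state series lengths differ")
        if self.f is not None and self.f.shape != self.y.shape:
            raise ValueError("rhs cache shape mismatch")

    @property
    def terminal_state(self) -> np.ndarray:
        return self.y[-1]

    def to_frame(self, tension: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.columns[: self.y.shape[1]]))
        df.insert(0, "time", self.t)
        if tension is not None:
            df["tension"] = tension
        return df

    def to_csv(self, path: str | Path, tension: np.ndarray | None = None) -> None:
        self.to_frame(tension).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scheme weights


def predictor_weights(alpha: float, n_max: int) -> np.ndarray:
    """Predictor kernel ``b_m = (m^a - (m-1)^a) / Gamma(a+1)`` for m = 0..n_max.

    The coefficient of ``f_j`` in the step-n predictor is ``b_{n-j}``;
    ``b_0`` is unused and set to zero.
    """
    m = np.arange(n_max + 1, dtype=float)
    b = np.zeros(n_max + 1)
    b[1:] = (m[1:] ** alpha - (m[1:] - 1.0) ** alpha) / _gamma(alpha + 1.0)
    return b


def corrector_weights(n: "int | np.ndarray", alpha: float) -> "float | np.ndarray":
    """Corrector weight ``beta_n`` (see module docstring)."""
    n_arr = np.asarray(n, dtype=float)
    g = _gamma(alpha + 2.0)
    with np.errstate(invalid="ignore"):
        out = np.where(
            n_arr == 0,
            1.0 / g,
            (np.abs(n_arr - 1.0) ** (alpha + 1.0) - 2.0 * n_arr ** (alpha + 1.0) + (n_arr + 1.0) ** (alpha + 1.0)) / g,
        )
    return float(out) if np.isscalar(n) else out


def initial_weight(n: "int | np.ndarray", alpha: float) -> "float | np.ndarray":
    """Corrector initial-point weight ``a_{n,0}`` (n >= 1)."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("a_{n,0} is defined for n >= 1")
    g = _gamma(alpha + 2.0)
    out = ((n_arr - 1.0) ** (alpha + 1.0) - n_arr**alpha * (n_arr - alpha - 1.0)) / g
    return float(out) if np.isscalar(n) else out


def predictor_step(
    history: Sequence[float],
    y0: float,
    h: float,
    alpha: float,
    n: int,
    *,
    dy0: float = 0.0,
) -> float:
    """Scalar predictor value at step ``n`` from the rhs history ``f_0..f_{n-1}``."""
    f_hist = np.asarray(history, dtype=float)
    if n < 1 or f_hist.shape[0] < n:
        raise ValueError("predictor needs the complete history f_0..f_{n-1}")
    b = predictor_weights(alpha, n)
    taylor = y0 + (dy0 * (n * h) if alpha > 1.0 else 0.0)
    return float(taylor + h**alpha * np.dot(b[n:0:-1], f_hist[:n]))


def corrector_step(
    predicted: float,
    history: Sequence[float],
    y0: float,
    h: float,
    alpha: float,
    rhs_at_tn: float,
    *,
    dy0: float = 0.0,
) -> float:
    """Scalar corrected value at step ``n = len(history)``.

    ``rhs_at_tn`` is ``f(t_n, y_n^P)`` evaluated at the predicted value.
    """
    f_hist = np.asarray(history, dtype=float)
    n = f_hist.shape[0]
    if n < 1:
        raise ValueError("corrector needs at least f_0 in the history")
    if not np.isfinite(rhs_at_tn):
        raise FloatingPointError("non-finite rhs at t_n; trajectory is divergent")
    ha = h**alpha
    taylor = y0 + (dy0 * (n * h) if alpha > 1.0 else 0.0)
    acc = initial_weight(n, alpha) * f_hist[0]
    if n > 1:
        acc += float(np.dot(corrector_weights(np.arange(1, n), alpha)[::-1], f_hist[1:n]))
    acc += corrector_weights(0, alpha) * rhs_at_tn
    return float(taylor + ha * acc)


# ---------------------------------------------------------------------------
# multi-order system driver


def solve_multi_order(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    alpha: "AlphaVector | Sequence[float]",
    y0: "Sequence[float]",
    config: SolverConfig,
) -> Trajectory:
    """Advance all components simultaneously, each with its own order.

    At every step each component is predicted with its own alpha-weights, the
    rhs is evaluated once at the predicted vector, each component is
    corrected, and the rhs at the corrected vector is cached as ``f_n``
    (P-E-C-E with one corrector iteration by default).

    Divergence (non-finite values or ``|y| >`` the configured bound) truncates
    the trajectory and flags it; no exception is raised, because order-range
    scans deliberately probe unstable orders.
    """
    a = alpha.as_array() if isinstance(alpha, AlphaVector) else np.asarray(alpha, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    m = y0.shape[0]
    if a.shape != (m,):
        raise ValueError("alpha vector length must match the state dimension")
    if np.any(a <= 0) or np.any(a > 2):
        raise ValueError("all fractional orders must lie in (0, 2]")
    n_steps = config.n_steps
    h = config.h
    t = config.grid()

    ha = h**a
    g1 = np.array([_gamma(ai + 1.0) for ai in a])
    g2 = np.array([_gamma(ai + 2.0) for ai in a])
    k = np.arange(n_steps + 1, dtype=float)
    # per-component kernels, shape (m, n_steps + 1)
    Pb = np.zeros((m, n_steps + 1))
    Cb = np.zeros((m, n_steps + 1))
    A0 = np.zeros((m, n_steps + 1))
    for i in range(m):
        ai = a[i]
        Pb[i, 1:] = (k[1:] ** ai - (k[1:] - 1.0) ** ai) / g1[i]
        Cb[i, 0] = 1.0 / g2[i]
        Cb[i, 1:] = ((k[1:] - 1.0) ** (ai + 1.0) - 2.0 * k[1:] ** (ai + 1.0) + (k[1:] + 1.0) ** (ai + 1.0)) / g2[i]
        A0[i, 1:] = ((k[1:] - 1.0) ** (ai + 1.0) - k[1:] ** ai * (k[1:] - ai - 1.0)) / g2[i]

    Y = np.empty((n_steps + 1, m))
    F = np.empty((m, n_steps + 1))  # transposed for contiguous history rows
    Y[0] = y0
    f0 = np.asarray(rhs(t[0], y0), dtype=float)
    F[:, 0] = f0
    has_high = a > 1.0
    dy0 = np.where(has_high, f0 if config.initial_derivative == "rhs" else 0.0, 0.0)

    bound = config.divergence_bound
    mem = config.memory_length
    divergent = False
    last = n_steps
    for n in range(1, n_steps + 1):
        lo = 0 if mem is None else max(0, n - mem)
        tn = t[n]
        taylor = y0 + dy0 * (tn - t[0])
        # predictor: coefficient of f_j is Pb[n-j], j = lo..n-1
        pred_mem = np.einsum("ij,ij->i", Pb[:, n - lo : 0 : -1], F[:, lo:n])
        y_pred = taylor + ha * pred_mem
        f_pred = np.asarray(rhs(tn, y_pred), dtype=float)
        if not np.all(np.isfinite(f_pred)):
            divergent, last = True, n - 1
            break
        j0 = max(1, lo)
        corr_mem = np.zeros(m)
        if lo == 0:
            corr_mem += A0[:, n] * F[:, 0]
        if n > j0:
            corr_mem += np.einsum("ij,ij->i", Cb[:, n - j0 : 0 : -1], F[:, j0:n])
        y_n = taylor + ha * (corr_mem + Cb[:, 0] * f_pred)
        for _ in range(config.corrector_iterations - 1):
            f_pred = np.asarray(rhs(tn, y_n), dtype=float)
            y_n = taylor + ha * (corr_mem + Cb[:, 0] * f_pred)
        if not (np.all(np.isfinite(y_n)) and np.max(np.abs(y_n)) <= bound):
            Y[n] = y_n
            divergent, last = True, n
            break
        f_n = np.asarray(rhs(tn, y_n), dtype=float)
        if not np.all(np.isfinite(f_n)):
            divergent, last = True, n
            Y[n] = y_n
            break
        Y[n] = y_n
        F[:, n] = f_n

    end = last + 1
    return Trajectory(
        t=t[:end],
        y=Y[:end],
        f=F[:, :end].T.copy() if not divergent else None,
        divergent=divergent,
        alpha=a,
        config=config,
    )


def restart_segment(trajectory: Trajectory, new_config: SolverConfig) -> tuple[np.ndarray, SolverConfig]:
    """Prepare a memory-reset continuation segment.

    The Caputo operator's lower terminal moves to ``new_config.t0`` and the
    prior segment's terminal state becomes the (nonzero) initial condition;
    the prior rhs history is discarded.  Refuses divergent segments.
    """
    if trajectory.divergent:
        raise RuntimeError("cannot restart from a divergent segment")
    cfg = new_config
    if abs(cfg.t0 - trajectory.t[-1]) > 1e-12:
        cfg = replace(new_config, t0=float(trajectory.t[-1]))
    return trajectory.terminal_state.copy(), cfg


# ---------------------------------------------------------------------------
# oracles / baselines


def mittag_leffler(alpha: float, z: float, tol: float = 1e-12, max_terms: int = 100000) -> float:
    """One-parameter Mittag-Leffler function ``E_a(z)`` by series summation.

    The series ``sum_k z^k / Gamma(a k + 1)`` is summed in extended precision
    (the partial sums suffer catastrophic cancellation for strongly negative
    arguments) with adaptive truncation once terms fall below ``tol`` relative
    to the accumulated value.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if z == 0:
        return 1.0
    # enough digits to absorb the peak-term magnitude ~ exp(|z|^(1/a) / a)
    peak = abs(z) ** (1.0 / alpha) / alpha
    dps = 30 + int(peak / 2.302585092994046)
    with mpmath.workdps(dps):
        zm = mpmath.mpf(z)
        total = mpmath.mpf(0)
        term_scale = mpmath.mpf(0)
        k = 0
        small_run = 0
        while k < max_terms:
            term = zm**k / mpmath.gamma(alpha * k + 1)
            total += term
            term_scale = max(term_scale, abs(term))
            if abs(term) < tol * max(abs(total), mpmath.mpf(1e-300)):
                small_run += 1
                if small_run >= 3:
                    return float(total)
            else:
                small_run = 0
            k += 1
    raise RuntimeError(f"Mittag-Leffler series did not converge within {max_terms} terms")


def reference_ode_solve(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: Sequence[float],
    config: SolverConfig,
    breakpoints: Sequence[float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Classical (integer-order) integration of the same rhs on the same grid.

    Used as the "ODE-Land" baseline in every CLS-vs-ODE comparison.  The
    integration is carried out piecewise between ``breakpoints`` (e.g. the
    ramp corners of a stretch protocol) so the adaptive integrator never
    steps across an input discontinuity.
    """
    t_grid = config.grid()
    tol = 1e-9 * config.h
    pts = sorted({config.t0, config.t_end, *(breakpoints or [])})
    pts = [p for p in pts if config.t0 - tol <= p <= config.t_end + tol]
    y0 = np.asarray(y0, dtype=float)
    ys = [y0[None, :]]
    y_cur = y0
    for seg_a, seg_b in zip(pts[:-1], pts[1:]):
        mask = (t_grid > seg_a + tol) & (t_grid <= seg_b + tol)
        t_eval = np.clip(t_grid[mask], seg_a, seg_b)
        sol = solve_ivp(
            rhs,
            (seg_a, seg_b),
            y_cur,
            method="LSODA",
            t_eval=np.r_[t_eval, seg_b] if (t_eval.size == 0 or t_eval[-1] < seg_b - tol) else t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"reference ODE integration failed: {sol.message}")
        take = sol.y.T[: t_eval.size] if sol.t.size > t_eval.size else sol.y.T
        if t_eval.size:
            ys.append(take)
        y_cur = sol.y[:, -1]
    y_all = np.vstack(ys)
    if y_all.shape[0] != t_grid.shape[0]:
        raise RuntimeError("reference integration did not cover the full grid")
    return Trajectory(t=t_grid, y=y_all, f=None, divergent=False, alpha=None, config=config)
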