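"""State equations of the Caputo-Land system (CLS).

Six states describe active tension generation in a cardiomyocyte:

* ``S`` — fraction of strongly bound (post-power-stroke) cross-bridges,
* ``W`` — fraction of weakly bound (pre-power-stroke) cross-bridges,
* ``CaTRPN`` — fraction of Troponin C units with bound calcium,
* ``B`` — fraction of blocked myosin binding sites on actin,
* ``zeta_s``, ``zeta_w`` — post- and pre-power-stroke cross-bridge distortions
  driven by the sarcomere length rate d(lambda)/dt.

A seventh implicit state ``U = 1 - B - S - W`` is the unbound cross-bridge
fraction.  The right-hand sides here are order-agnostic: they define the
integer-order Land model when integrated classically and the CLS when each
state is advanced under its own Caputo fractional order.

Active tension is ``T = L_fac * ((zeta_s + 1) * S + zeta_w * W)`` with a
length factor ``L_fac`` fixed by the sample's initial sarcomere length and the
reference maximal tension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "STATE_NAMES",
    "CLSState",
    "unbound_fraction",
    "gamma_su",
    "gamma_wu",
    "effective_ca50",
    "rhs_cls",
    "make_rhs",
    "steady_state",
    "length_factor",
    "active_tension",
]

#: Canonical state ordering used by every array interface in the package.
STATE_NAMES = ("S", "W", "CaTRPN", "B", "zeta_s", "zeta_w")

#: Reference timescale of the fractional operator, in seconds.  Cross-bridge
#: kinetics play out on milliseconds, and the model's convention is that rate
#: constants keep their numerical per-millisecond values as the orders vary
#: (under a Caputo operator the choice of time unit matters whenever
#: alpha != 1).  All public interfaces still use seconds; segment solvers
#: rescale to this unit internally.
FRACTIONAL_TIME_UNIT_S = 1e-3


@dataclass
class CLSState:
    """The six explicit model states (see module docstring)."""

    S: float
    W: float
    CaTRPN: float
    B: float
    zeta_s: float
    zeta_w: float

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.W, self.CaTRPN, self.B, self.zeta_s, self.zeta_w], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CLSState":
        y = np.asarray(y, dtype=float)
        if y.shape != (6,):
            raise ValueError(f"expected a length-6 state vector, got shape {y.shape}")
        return cls(*map(float, y))

    @property
    def U(self) -> float:
        return unbound_fraction(self)


def unbound_fraction(state: "CLSState | np.ndarray") -> float:
    """Implicit unbound cross-bridge fraction ``U = 1 - B - S - W``.

    May be negative for non-physical states; callers decide physicality.
    """
    if isinstance(state, CLSState):
        return 1.0 - state.B - state.S - state.W
    y = np.asarray(state, dtype=float)
    return float(1.0 - y[3] - y[0] - y[1])


def gamma_su(zeta_s: float, params) -> float:
    """Distortion-dependent unbinding rate of the S state.

    Zero inside the neutral distortion band ``[-1, 0]``; grows linearly with
    the distance outside it (reference-model form).
    """
    if zeta_s < -1.0:
        return params.gamma_s_scale * (-zeta_s - 1.0)
    if zeta_s > 0.0:
        return params.gamma_s_scale * zeta_s
    return 0.0


def gamma_wu(zeta_w: float, params) -> float:
    """Distortion-dependent unbinding rate of the W state, ∝ ``|zeta_w|``."""
    return params.gamma_w_scale * abs(zeta_w)


def effective_ca50(params, lam: float) -> float:
    """Length-dependent calcium half-activation point (uM)."""
    lam_c = min(lam, params.lambda_cap)
    return params.Ca_T50_ref * (1.0 + params.beta_1 * (lam_c - 1.0))


def rhs_cls(
    t: float,
    state: "CLSState | np.ndarray",
    protocol_inputs: dict,
    params,
    *,
    w_influx_power_stroke_rate: bool = False,
) -> np.ndarray:
    """Right-hand sides of the six state equations at time ``t``.

    ``protocol_inputs`` provides ``lambda``, ``dlambda_dt`` and ``Ca`` either
    as floats or callables of ``t``.  The CaTRPN value is clamped at
    ``params.catrpn_floor`` before the negative-exponent blocked-site term;
    with the floor disabled (``catrpn_floor=None``) a non-positive CaTRPN
    raises instead.

    By default the W-state influx is ``k_uw * U`` (the reference-model rate);
    ``w_influx_power_stroke_rate=True`` switches it to ``k_ws * U``.
    """
    y = state.as_array() if isinstance(state, CLSState) else np.asarray(state, dtype=float)
    f = make_rhs(
        params,
        lam=protocol_inputs["lambda"],
        dlam=protocol_inputs["dlambda_dt"],
        ca=protocol_inputs["Ca"],
        w_influx_power_stroke_rate=w_influx_power_stroke_rate,
    )
    return f(t, y)


def make_rhs(
    params,
    lam: "float | Callable[[float], float]",
    dlam: "float | Callable[[float], float]",
    ca: "float | Callable[[float], float]",
    *,
    w_influx_power_stroke_rate: bool = False,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build a fast ``f(t, y) -> dy`` closure for the given inputs.

    This is the form consumed by the fractional and classical integrators.
    """
    k_ws = params.k_ws
    k_su = params.k_su
    k_wu = params.k_wu
    k_in_w = params.k_ws if w_influx_power_stroke_rate else params.k_uw
    a_s, a_w = params.A_s, params.A_w
    c_s, c_w = params.c_s, params.c_w
    k_b, k_u_rate = params.k_b, params.k_u
    n_tm_half = params.n_Tm / 2.0
    k_trpn, n_trpn = params.k_TRPN, params.n_TRPN
    gs, gw = params.gamma_s_scale, params.gamma_w_scale
    floor = params.catrpn_floor
    ca50ref, beta1, lamcap = params.Ca_T50_ref, params.beta_1, params.lambda_cap
    lam_f = lam if callable(lam) else (lambda t, _v=float(lam): _v)
    dlam_f = dlam if callable(dlam) else (lambda t, _v=float(dlam): _v)
    ca_f = ca if callable(ca) else (lambda t, _v=float(ca): _v)

    def f(t: float, y: np.ndarray) -> np.ndarray:
        S, W, CaTRPN, B, zs, zw = (float(v) for v in y)
        U = 1.0 - B - S - W
        lam_t = lam_f(t)
        dlam_t = dlam_f(t)
        ca_t = ca_f(t)
        if zs < -1.0:
            g_su = gs * (-zs - 1.0)
        elif zs > 0.0:
            g_su = gs * zs
        else:
            g_su = 0.0
        g_wu = gw * abs(zw)
        if CaTRPN <= 0.0 and floor is None:
            raise ValueError(
                "CaTRPN <= 0 encountered with the clamp floor disabled; the "
                "blocked-site term CaTRPN**(-n_Tm/2) is singular there. Set "
                "params.catrpn_floor (default 1e-8) to clamp instead."
            )
        c_clip = CaTRPN if floor is None else max(CaTRPN, floor)
        ca50 = ca50ref * (1.0 + beta1 * (min(lam_t, lamcap) - 1.0))
        ratio = ca_t / ca50
        dS = k_ws * W - k_su * S - g_su * S
        dW = k_in_w * U - k_wu * W - k_ws * W - g_wu * W
        dCaTRPN = k_trpn * (ratio**n_trpn * (1.0 - CaTRPN) - CaTRPN)
        dB = k_b * c_clip ** (-n_tm_half) * U - k_u_rate * c_clip**n_tm_half * B
        dzs = a_s * dlam_t - c_s * zs
        dzw = a_w * dlam_t - c_w * zw
        return np.array([dS, dW, dCaTRPN, dB, dzs, dzw])

    return f


def steady_state(
    params,
    Ca: float | None = None,
    lam: float | None = None,
    *,
    w_influx_power_stroke_rate: bool = False,
) -> CLSState:
    """Closed-form steady state at constant calcium and constant length.

    With d(lambda)/dt = 0 the distortions vanish, CaTRPN balances at
    ``r / (1 + r)`` with ``r = (Ca / Ca_T50)^n_TRPN``, and S, W, B, U follow
    from the linear balance of the transition rates.
    """
    ca = params.Ca_i if Ca is None else Ca
    lam0 = params.lambda_0 if lam is None else lam
    if not ca > 0:
        raise ValueError("steady state requires Ca > 0")
    r = (ca / effective_ca50(params, lam0)) ** params.n_TRPN
    catrpn = r / (1.0 + r)
    k_in_w = params.k_ws if w_influx_power_stroke_rate else params.k_uw
    w_over_u = k_in_w / (params.k_wu + params.k_ws)  # gamma_wu(0) = 0
    s_over_u = w_over_u * params.k_ws / params.k_su  # gamma_su(0) = 0
    b_over_u = (params.k_b / params.k_u) * catrpn ** (-params.n_Tm)
    u = 1.0 / (1.0 + w_over_u + s_over_u + b_over_u)
    state = CLSState(
        S=s_over_u * u,
        W=w_over_u * u,
        CaTRPN=catrpn,
        B=b_over_u * u,
        zeta_s=0.0,
        zeta_w=0.0,
    )
    f = make_rhs(params, lam=lam0, dlam=0.0, ca=ca, w_influx_power_stroke_rate=w_influx_power_stroke_rate)
    resid = float(np.max(np.abs(f(0.0, state.as_array()))))
    if resid > 1e-8:
        raise RuntimeError(f"steady-state solve failed: max |rhs| residual {resid:.3e}")
    return state


def length_factor(lambda_0: float, params) -> float:
    """Length-dependent tension factor ``L_fac`` (kPa), constant per protocol.

    Combines the reference maximal tension with the reference model's
    piecewise-linear length dependence evaluated at the sample's initial
    relative sarcomere length.
    """
    if not params.lambda_min <= lambda_0 <= params.lambda_max:
        raise ValueError(
            f"lambda_0={lambda_0} outside the configured band "
            f"[{params.lambda_min}, {params.lambda_max}]"
        )
    lam_c = min(lambda_0, params.lambda_cap)
    h = 1.0 + params.beta_0 * (lam_c + min(lam_c, 0.87) - 1.87)
    h = max(h, 0.0)
    lfac = h * params.T_ref / params.r_s
    if not lfac > 0:
        raise ValueError(f"length factor non-positive at lambda_0={lambda_0}")
    return lfac


def active_tension(state: "CLSState | np.ndarray", L_fac: float) -> "float | np.ndarray":
    """Active tension ``T = L_fac * ((zeta_s + 1) * S + zeta_w * W)``.

    Accepts a single state, a length-6 vector, or an ``(n, 6)`` trajectory
    array (returning a length-n tension series).
    """
    if not L_fac > 0:
        raise ValueError("L_fac must be positive")
    if isinstance(state, CLSState):
        return L_fac * ((state.zeta_s + 1.0) * state.S + state.zeta_w * state.W)
    y = np.asarray(state, dtype=float)
    if y.ndim == 1:
        return float(L_fac * ((y[4] + 1.0) * y[0] + y[5] * y[1]))
    return L_fac * ((y[:, 4] + 1.0) * y[:, 0] + y[:, 5] * y[:, 1])
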