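"""Parameter container for the Land active-tension model.

The base rate constants, cooperativities and duty-ratio parameters follow the
published human Land parameterisation for cardiomyocyte contraction; derived
rates (``k_su``, ``k_wu``, distortion amplitudes and decay rates, ``k_b``) are
computed from the base set exactly as in that model.  All rates are carried in
per-second units; when states evolve under a fractional order alpha the rate
constants are kept numerically unchanged (they then carry implicit units of
s^-alpha), which is the convention used throughout this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Any

__all__ = ["LandParams", "load_params", "default_params"]

_POSITIVE = (
    "k_uw",
    "k_ws",
    "r_s",
    "r_w",
    "phi",
    "A_eff",
    "gamma_s_scale",
    "gamma_w_scale",
    "k_TRPN",
    "n_TRPN",
    "Ca_T50_ref",
    "TRPN_50",
    "n_Tm",
    "k_u",
    "T_ref",
    "Ca_i",
    "lambda_0",
)


@dataclass(frozen=True)
class LandParams:
    """Complete parameter set for the cross-bridge / thin-filament model.

    Attributes marked *derived* are computed in ``__post_init__`` from the
    base parameters and must not be supplied directly.
    """

    # thick filament (cross-bridge cycling)
    k_uw: float  # U -> W attachment rate, 1/s
    k_ws: float  # W -> S power-stroke rate, 1/s
    r_s: float  # steady-state duty ratio of the S state
    r_w: float  # steady-state duty ratio of the W state
    phi: float  # distortion-decay scaling
    A_eff: float  # total response-to-distortion amplitude
    gamma_s_scale: float  # distortion-dependent S unbinding scale, 1/s
    gamma_w_scale: float  # distortion-dependent W unbinding scale, 1/s
    # thin filament
    k_TRPN: float  # troponin Ca binding rate, 1/s
    n_TRPN: float  # troponin cooperativity
    Ca_T50_ref: float  # half-activation [Ca2+] at lambda = 1, uM
    beta_1: float  # length dependence of Ca_T50
    TRPN_50: float  # CaTRPN level at half tension
    n_Tm: float  # tropomyosin cooperativity
    k_u: float  # unblocking base rate, 1/s
    # tension output
    T_ref: float  # reference maximal tension, kPa
    beta_0: float  # length-dependence coefficient of the tension factor
    # inputs / geometry
    Ca_i: float  # activating calcium level (skinned preparation), uM
    lambda_0: float  # baseline relative sarcomere length
    lambda_cap: float = 1.2  # length at which length effects saturate
    lambda_min: float = 0.8  # lower physiological bound for lambda_0
    lambda_max: float = 1.2  # upper physiological bound for lambda_0
    catrpn_floor: float | None = 1e-8  # clamp before the negative-exponent term
    # derived, filled in post-init
    k_su: float = field(init=False, default=0.0)
    k_wu: float = field(init=False, default=0.0)
    A_s: float = field(init=False, default=0.0)
    A_w: float = field(init=False, default=0.0)
    c_s: float = field(init=False, default=0.0)
    c_w: float = field(init=False, default=0.0)
    k_b: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")
        if not self.lambda_min <= self.lambda_0 <= self.lambda_max:
            raise ValueError(
                f"lambda_0={self.lambda_0} outside the physiological band "
                f"[{self.lambda_min}, {self.lambda_max}]"
            )
        object.__setattr__(self, "k_su", self.k_ws * self.r_w * (1.0 / self.r_s - 1.0))
        object.__setattr__(self, "k_wu", self.k_uw * (1.0 / self.r_w - 1.0) - self.k_ws)
        a_w = self.A_eff * self.r_s / ((1.0 - self.r_s) * self.r_w + self.r_s)
        object.__setattr__(self, "A_w", a_w)
        object.__setattr__(self, "A_s", a_w)
        object.__setattr__(
            self,
            "c_w",
            self.phi * self.k_uw * ((1.0 - self.r_s) * (1.0 - self.r_w)) / ((1.0 - self.r_s) * self.r_w),
        )
        object.__setattr__(self, "c_s", self.phi * self.k_ws * ((1.0 - self.r_s) * self.r_w) / self.r_s)
        object.__setattr__(
            self,
            "k_b",
            self.k_u * self.TRPN_50**self.n_Tm / (1.0 - self.r_s - (1.0 - self.r_s) * self.r_w),
        )

    def replace(self, **changes: Any) -> "LandParams":
        """Return a copy with base parameters changed (derived ones recomputed)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _base_field_names() -> set[str]:
    return {f.name for f in fields(LandParams) if f.init}


def load_params(path: str | Path) -> LandParams:
    """Load a parameter set from a flat JSON file.

    The file may either be a flat ``{key: value}`` mapping or carry the
    mapping under a ``"params"`` key (the packaged default layout, which also
    stores units).  Completeness and positivity are validated.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if "params" in raw and isinstance(raw["params"], dict):
        raw = raw["params"]
    return params_from_dict(raw)


def params_from_dict(raw: dict[str, Any]) -> LandParams:
    known = _base_field_names()
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    required = {
        name
        for name in known
        if name not in ("lambda_cap", "lambda_min", "lambda_max", "catrpn_floor")
    }
    missing = required - set(raw)
    if missing:
        raise ValueError(f"missing parameter keys: {sorted(missing)}")
    return LandParams(**{k: raw[k] for k in raw})


def default_params() -> LandParams:
    """The packaged default parameter set (human skinned-cell simulation)."""
    ref = resources.files("caputoland.data").joinpath("land_params.json")
    raw = json.loads(ref.read_text())
    return params_from_dict(raw["params"])
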