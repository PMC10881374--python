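"""Synthetic quick-stretch cohorts with known per-subject fractional orders.

Emulates the statistical structure of the calibration dataset: 21 skinned
left-ventricular samples split 5 / 11 / 5 across the 0.5%, 1% and 2% stretch
protocols, each with subject-specific fractional orders and measurement
noise.  Ground-truth orders are recorded alongside every trace so parameter
recovery can be tested end to end.

Default sampling rule: the thin/thick-filament states found to be strongly
fractional (W, CaTRPN, B) draw uniformly from the per-segment calibration
bound boxes; the distortion states zeta_s and zeta_w, and the weakly
fractional S state, stay at order 1.  Candidate order vectors are accepted
only if the simulated mechanical response of both segments is classified
stable (rejection sampling with a capped retry count).

The noise model is additive AR(1) Gaussian with stationary standard
deviation expressed as a fraction of the pre-stretch plateau tension; traces
are resampled onto a coarser "experimental" grid (default 1 ms) to emulate
instrument sampling and exercise grid interpolation downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import StabilityCriteria, classify_response, default_bounds
from .fde import AlphaVector, SolverConfig
from .protocol import (
    Protocol,
    TensionTrace,
    make_quick_stretch_protocol,
    simulate_protocol,
    split_segments,
)

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticSubject",
    "Cohort",
    "sample_alpha_population",
    "add_noise",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

HIGH_FRACTIONALITY_STATES = ("W", "CaTRPN", "B")
STATE_INDEX = {"S": 0, "W": 1, "CaTRPN": 2, "B": 3, "zeta_s": 4, "zeta_w": 5}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions of the emulated study cohort."""

    n_per_protocol: tuple = (5, 11, 5)  # counts for 0.5%, 1%, 2% stretch
    stretch_fractions: tuple = (0.005, 0.01, 0.02)
    sampled_states: tuple = HIGH_FRACTIONALITY_STATES
    noise_sigma: float = 0.02  # stationary noise std, fraction of plateau
    noise_rho: float = 0.8  # lag-1 autocorrelation
    sample_interval: float = 1e-3  # "experimental" grid spacing, s
    rng_seed: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if len(self.n_per_protocol) != len(self.stretch_fractions):
            raise ValueError("n_per_protocol and stretch_fractions lengths differ")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not abs(self.noise_rho) < 1:
            raise ValueError("noise_rho must satisfy |rho| < 1")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_protocol))


@dataclass
class SyntheticSubject:
    subject_id: str
    stretch_fraction: float
    trace: TensionTrace  # noisy, on the experimental grid, normalized
    alpha_stretch: AlphaVector
    alpha_release: AlphaVector
    noise_sigma: float
    noise_rho: float
    clean_trace: TensionTrace | None = None


@dataclass
class Cohort:
    spec: SyntheticCohortSpec
    subjects: list = field(default_factory=list)

    def by_protocol(self, stretch_fraction: float) -> list:
        return [s for s in self.subjects if s.stretch_fraction == stretch_fraction]

    def __len__(self) -> int:
        return len(self.subjects)


def _draw_alpha(spec: SyntheticCohortSpec, segment_kind: str, rng: np.random.Generator) -> AlphaVector:
    lb, ub = default_bounds(segment_kind)
    vec = np.ones(6)
    for name in spec.sampled_states:
        i = STATE_INDEX[name]
        vec[i] = lb[i] + rng.random() * (ub[i] - lb[i])
    return AlphaVector.from_array(vec)


def sample_alpha_population(
    spec: SyntheticCohortSpec,
    segment_kind: str,
    n: int,
    rng: "np.random.Generator | int | None" = None,
) -> list[AlphaVector]:
    """Draw ``n`` within-bounds order vectors (no stability screening here).

    Stability screening happens in :func:`generate_cohort`, where a candidate
    pair can be simulated; this operation records the raw population with its
    ground truth.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.rng_seed if rng is None else rng)
    return [_draw_alpha(spec, segment_kind, rng) for _ in range(n)]


def add_noise(
    trace: TensionTrace,
    sigma: float,
    rho: float,
    rng: np.random.Generator,
) -> TensionTrace:
    """Add AR(1) Gaussian noise with stationary std ``sigma * plateau``.

    ``plateau`` is the trace's first sample (the pre-stretch reference level
    of a normalized trace).  ``sigma = 0`` returns an identical copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    out = trace.copy()
    if sigma == 0:
        return out
    s = sigma * float(trace.tension[0])
    n = trace.tension.size
    eps = rng.normal(0.0, 1.0, size=n)
    noise = np.empty(n)
    noise[0] = s * eps[0]
    innov = s * np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        noise[i] = rho * noise[i - 1] + innov * eps[i]
    out.tension = trace.tension + noise
    out.meta["noise_sigma"] = float(sigma)
    out.meta["noise_rho"] = float(rho)
    return out


def generate_cohort(
    spec: SyntheticCohortSpec,
    params,
    solver_config: SolverConfig,
    protocols: Sequence[Protocol] | None = None,
    criteria: StabilityCriteria | None = None,
    keep_clean: bool = False,
) -> Cohort:
    """Generate the full synthetic cohort with ground-truth manifest.

    For each subject: draw a stretch/release order pair, simulate the full
    protocol, require both segments to classify stable (resampling up to
    ``spec.max_retries``), resample onto the experimental grid and add noise.
    Pure function of (spec, params, solver settings): a fixed seed reproduces
    the cohort bit for bit.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if protocols is None:
        protocols = [
            make_quick_stretch_protocol(sf, lambda_0=params.lambda_0, rise_time=max(1e-3, 4 * solver_config.h))
            for sf in spec.stretch_fractions
        ]
    cohort = Cohort(spec=spec)
    for proto, count in zip(protocols, spec.n_per_protocol):
        for k in range(count):
            accepted = None
            worst_state = None
            for _ in range(spec.max_retries):
                a_s = _draw_alpha(spec, "stretch", rng)
                a_r = _draw_alpha(spec, "release", rng)
                trace = simulate_protocol(params, a_s, a_r, proto, solver_config)
                if trace.divergent:
                    worst_state = _most_deviant_state(a_s, a_r)
                    continue
                seg_s, seg_r = split_segments(trace, proto)
                lab_s = classify_response(seg_s, criteria).label
                lab_r = classify_response(seg_r, criteria).label
                if lab_s == "stable" and lab_r == "stable":
                    accepted = (a_s, a_r, trace)
                    break
                worst_state = _most_deviant_state(a_s, a_r)
            if accepted is None:
                raise RuntimeError(
                    f"rejection cap ({spec.max_retries}) exceeded for protocol "
                    f"{proto.stretch_fraction:.3%}; most deviant state in the last "
                    f"rejected candidate: {worst_state}"
                )
            a_s, a_r, trace = accepted
            grid = np.arange(trace.time[0], trace.time[-1] + 1e-12, spec.sample_interval)
            clean = trace.interp_to(grid)
            noisy = add_noise(clean, spec.noise_sigma, spec.noise_rho, rng)
            subject = SyntheticSubject(
                subject_id=f"p{proto.stretch_fraction:.3f}_s{k:02d}",
                stretch_fraction=proto.stretch_fraction,
                trace=noisy,
                alpha_stretch=a_s,
                alpha_release=a_r,
                noise_sigma=spec.noise_sigma,
                noise_rho=spec.noise_rho,
                clean_trace=clean if keep_clean else None,
            )
            cohort.subjects.append(subject)
    return cohort


def _most_deviant_state(a_s: AlphaVector, a_r: AlphaVector) -> str:
    dev = np.maximum(np.abs(a_s.as_array() - 1.0), np.abs(a_r.as_array() - 1.0))
    from .land import STATE_NAMES

    return STATE_NAMES[int(np.argmax(dev))]


# ---------------------------------------------------------------------------
# cohort persistence


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write ``traces/*.csv`` plus a ``manifest.json`` with ground truth."""
    directory = Path(directory)
    (directory / "traces").mkdir(parents=True, exist_ok=True)
    manifest = {
        "spec": asdict(cohort.spec),
        "subjects": [],
    }
    for s in cohort.subjects:
        rel = f"traces/{s.subject_id}.csv"
        s.trace.to_csv(directory / rel)
        manifest["subjects"].append(
            {
                "subject_id": s.subject_id,
                "trace": rel,
                "stretch_fraction": s.stretch_fraction,
                "alpha_stretch": list(s.alpha_stretch.as_array()),
                "alpha_release": list(s.alpha_release.as_array()),
                "noise_sigma": s.noise_sigma,
                "noise_rho": s.noise_rho,
            }
        )
    payload = json.dumps(manifest, indent=2, sort_keys=True)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    manifest["manifest_sha256_prefix"] = digest
    tmp = directory / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(directory / "manifest.json")
    return directory


def load_cohort(directory: str | Path) -> Cohort:
    """Load a cohort directory, cross-validating manifest completeness."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec_kwargs = manifest["spec"]
    for key in ("n_per_protocol", "stretch_fractions", "sampled_states"):
        spec_kwargs[key] = tuple(spec_kwargs[key])
    spec = SyntheticCohortSpec(**spec_kwargs)
    cohort = Cohort(spec=spec)
    for entry in manifest["subjects"]:
        path = directory / entry["trace"]
        if not path.exists():
            raise FileNotFoundError(f"manifest lists missing trace file {entry['trace']}")
        trace = TensionTrace.from_csv(path)
        cohort.subjects.append(
            SyntheticSubject(
                subject_id=entry["subject_id"],
                stretch_fraction=entry["stretch_fraction"],
                trace=trace,
                alpha_stretch=AlphaVector.from_array(entry["alpha_stretch"]),
                alpha_release=AlphaVector.from_array(entry["alpha_release"]),
                noise_sigma=entry["noise_sigma"],
                noise_rho=entry["noise_rho"],
            )
        )
    listed = {e["trace"] for e in manifest["subjects"]}
    on_disk = {f"traces/{p.name}" for p in (directory / "traces").glob("*.csv")}
    orphans = on_disk - listed
    if orphans:
        raise ValueError(f"trace files without a manifest entry: {sorted(orphans)}")
    return cohort
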