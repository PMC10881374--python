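"""Model/Results interface for fitting fractional orders to one sample.

``QuickStretchModel`` wraps a measured (or synthetic) 2-s quick
stretch-and-release tension trace together with its protocol and the
physiological parameter set; ``fit()`` runs the per-segment genetic-algorithm
calibration and returns a ``QuickStretchResults`` carrying the twelve fitted
fractional orders, the fit errors against the integer-order baseline, the
fractionality labels and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import land
from .calibration import (
    GAConfig,
    SubjectReport,
    fit_subject,
)
from .fde import AlphaVector, SolverConfig
from .params import LandParams, default_params
from .protocol import Protocol, TensionTrace, normalize_trace, simulate_protocol, split_segments

__all__ = ["QuickStretchModel", "QuickStretchResults"]


class QuickStretchModel:
    """Fractional-order active-tension model for one quick-stretch sample.

    Parameters
    ----------
    data
        The clipped 2-s tension trace (a :class:`TensionTrace`).  If not yet
        normalized, it is normalized to the pre-stretch plateau.
    protocol
        The stretch protocol applied to the sample.
    params
        Physiological parameter set; the packaged defaults if omitted.
    solver_config
        Step size and solver options used for every simulated candidate.
    """

    def __init__(
        self,
        data: TensionTrace,
        protocol: Protocol,
        params: LandParams | None = None,
        solver_config: SolverConfig | None = None,
    ):
        self.params = params or default_params()
        self.protocol = protocol
        self.solver_config = solver_config or SolverConfig(h=1e-3)
        trace = data
        if trace.normalization_reference is None:
            trace = normalize_trace(trace, protocol)
        self.data = trace
        self.data_stretch, self.data_release = split_segments(trace, protocol)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        protocol: Protocol,
        time_col: str = "time_s",
        tension_col: str = "tension",
        **kwargs,
    ) -> "QuickStretchModel":
        trace = TensionTrace(df[time_col].to_numpy(float), df[tension_col].to_numpy(float))
        return cls(trace, protocol, **kwargs)

    @classmethod
    def from_csv(cls, path, protocol: Protocol, **kwargs) -> "QuickStretchModel":
        return cls(TensionTrace.from_csv(path), protocol, **kwargs)

    def simulate(self, alpha_stretch: AlphaVector, alpha_release: AlphaVector) -> TensionTrace:
        """Simulate the full protocol under given order vectors."""
        return simulate_protocol(
            self.params, alpha_stretch, alpha_release, self.protocol, self.solver_config
        )

    def fit(self, ga_config: GAConfig | None = None, seed: int | None = None) -> "QuickStretchResults":
        """Run the two-segment GA calibration and collect results."""
        cfg = ga_config or GAConfig()
        if seed is not None:
            cfg = replace(cfg, rng_seed=seed)
        report = fit_subject(
            {"stretch": self.data_stretch, "release": self.data_release},
            self.params,
            self.protocol,
            cfg,
            self.solver_config,
        )
        return QuickStretchResults(self, report, cfg)


class QuickStretchResults:
    """Fitted fractional orders and diagnostics for one sample."""

    def __init__(self, model: QuickStretchModel, report: SubjectReport, ga_config: GAConfig):
        self.model = model
        self.report = report
        self.ga_config = ga_config
        idx = pd.Index(land.STATE_NAMES, name="state")
        self.params = pd.DataFrame(
            {
                "alpha_stretch": report.stretch.alpha_f.as_array(),
                "alpha_release": report.release.alpha_f.as_array(),
            },
            index=idx,
        )
        self.fractionality = pd.DataFrame(
            {
                "stretch": [report.fractionality_stretch[n] for n in land.STATE_NAMES],
                "release": [report.fractionality_release[n] for n in land.STATE_NAMES],
            },
            index=idx,
        )

    @property
    def mse(self) -> float:
        return self.report.cls_mse

    @property
    def max_abs_error(self) -> float:
        return self.report.cls_max_abs_error

    @property
    def baseline_mse(self) -> float:
        return self.report.baseline_mse

    @property
    def baseline_max_abs_error(self) -> float:
        return self.report.baseline_max_abs_error

    @property
    def fitted_trace(self) -> TensionTrace:
        return self.report.cls_trace

    @property
    def baseline_trace(self) -> TensionTrace:
        return self.report.baseline_trace

    def to_dict(self) -> dict:
        return {
            "alpha_stretch": list(self.params["alpha_stretch"]),
            "alpha_release": list(self.params["alpha_release"]),
            "cls_mse": self.mse,
            "cls_max_abs_error": self.max_abs_error,
            "baseline_mse": self.baseline_mse,
            "baseline_max_abs_error": self.baseline_max_abs_error,
            "fractionality_stretch": self.report.fractionality_stretch,
            "fractionality_release": self.report.fractionality_release,
            "termination": {
                "stretch": self.report.stretch.termination_reason,
                "release": self.report.release.termination_reason,
            },
            "generations": {
                "stretch": self.report.stretch.generations_used,
                "release": self.report.release.generations_used,
            },
            "boundary_jump": self.report.boundary_jump,
        }

    def summary(self) -> str:
        """Plain-text summary table of the fitted orders and fit quality."""
        lines = [
            "Caputo-Land quick-stretch fit",
            "=" * 64,
            f"protocol stretch: {self.model.protocol.stretch_fraction:.1%}   "
            f"solver h: {self.model.solver_config.h:g} s",
            f"GA: pop {self.ga_config.population_size}, "
            f"max gen {self.ga_config.max_generations}, seed {self.ga_config.rng_seed}",
            "-" * 64,
            f"{'state':>8} {'a_stretch':>10} {'a_release':>10} {'fract(s)':>9} {'fract(r)':>9}",
        ]
        for name in land.STATE_NAMES:
            lines.append(
                f"{name:>8} {self.params.loc[name, 'alpha_stretch']:>10.4f} "
                f"{self.params.loc[name, 'alpha_release']:>10.4f} "
                f"{self.fractionality.loc[name, 'stretch']:>9} "
                f"{self.fractionality.loc[name, 'release']:>9}"
            )
        lines += [
            "-" * 64,
            f"CLS      mse {self.mse:.3e}   max |err| {self.max_abs_error:.3e}",
            f"baseline mse {self.baseline_mse:.3e}   max |err| {self.baseline_max_abs_error:.3e}",
            f"termination: stretch={self.report.stretch.termination_reason} "
            f"({self.report.stretch.generations_used} gen), "
            f"release={self.report.release.termination_reason} "
            f"({self.report.release.generations_used} gen)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot data, fitted CLS trace and the integer-order baseline."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.data.time, self.model.data.tension, color="0.6", lw=0.8, label="data")
        ax.plot(self.fitted_trace.time, self.fitted_trace.tension, "r-", lw=1.2, label="CLS fit")
        ax.plot(
            self.baseline_trace.time,
            self.baseline_trace.tension,
            "g--",
            lw=1.2,
            label="integer-order baseline",
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("normalized tension")
        ax.legend()
        return ax
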