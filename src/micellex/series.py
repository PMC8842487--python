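"""Tagged-chain exchange relaxation curves.

A :class:`CorrelationSeries` holds the relaxation function F(t) that both the
dynamic simulator emits and the kinetic-model fitter consumes.  Times are in
seconds (default) or Monte-Carlo cycles with a separate cycle-duration
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CorrelationSeries:
    """Time grid plus tagged-fraction relaxation values.

    ``F`` is normalised so that F(0) = 1 and the mixing-equilibrium plateau
    maps to 0.  ``f0`` records the initial number of tagged chains when the
    curve comes from a simulation (NaN for synthetic or external data).
    """

    times: np.ndarray
    F: np.ndarray
    f0: float = float("nan")
    normalization: str = "relaxation"  # (f - f_eq) / (f0 - f_eq)
    domain: str = "seconds"  # or "cycles"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.times.shape != self.F.shape or self.times.ndim != 1:
            raise ValueError("times and F must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F values must be finite")
        if self.domain not in ("seconds", "cycles"):
            raise ValueError("domain must be 'seconds' or 'cycles'")

    def __len__(self) -> int:
        return self.times.size

    def to_seconds(self, t_cycle: float) -> "CorrelationSeries":
        """Convert a cycles-domain series using a cycle duration in s/cycle."""
        if self.domain == "seconds":
            return self
        if t_cycle <= 0:
            raise ValueError("t_cycle must be positive")
        return CorrelationSeries(
            self.times * t_cycle, self.F.copy(), self.f0, self.normalization, "seconds"
        )


@dataclass
class ScaledCurve:
    """A relaxation curve in the universal (t*, y*) coordinates.

    ``log_y_star`` is carried alongside ``y_star`` because y* spans many
    orders of magnitude (y*(0) = gamma * e^(1/eps)).
    """

    t_star: np.ndarray
    y_star: np.ndarray
    log_y_star: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.t_star = np.asarray(self.t_star, dtype=float)
        self.y_star = np.asarray(self.y_star, dtype=float)
        self.log_y_star = np.asarray(self.log_y_star, dtype=float)
        if not np.all(np.isfinite(self.log_y_star)):
            raise ValueError("log y* must be finite")
        if np.any(self.y_star < 0):
            raise ValueError("y* must be positive")
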