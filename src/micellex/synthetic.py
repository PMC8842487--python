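"""Synthetic relaxation-curve fixtures.

Wraps the closed-form kinetic solution to generate curves with known ground
truth: log-uniform time sampling over a window keyed to the parameters' own
time scales (from two decades below the logarithmic onset tau1 to well past
the crossover time a = eps/k2) plus optional additive Gaussian noise.  A
manifest records ground-truth parameters and seeds so fits can be closed
against them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .eyring import EyringParams, eyring_solution
from .io import write_curve
from .series import CorrelationSeries

__all__ = ["synth_curve", "synth_curves", "default_window"]

#: default sampling density per time decade (matches the per-decade logging
#: of the dynamic simulator)
POINTS_PER_DECADE = 200


def default_window(p: EyringParams) -> tuple[float, float]:
    """(t_min, t_max): tau1/100 to 20 eps/k2, covering all regimes."""
    d = p.derived()
    lo = min(d.tau1, d.tau2) / 100.0
    hi = 20.0 * d.a
    return lo, max(hi, lo * 1e4)


def synth_curve(
    p: EyringParams,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
    window: tuple[float, float] | None = None,
    points_per_decade: int = POINTS_PER_DECADE,
) -> CorrelationSeries:
    """One synthetic relaxation curve with relative noise amplitude ``noise``.

    Noise is additive Gaussian with standard deviation ``noise`` times the
    unit initial value F(0)=1; amplitudes at or above the signal scale are
    rejected.
    """
    if noise < 0 or noise >= 1.0:
        raise ValueError("noise amplitude must be in [0, 1) of the signal scale")
    if window is None:
        window = default_window(p)
    lo, hi = window
    if not 0 < lo < hi:
        raise ValueError("invalid window")
    n = max(10, int(points_per_decade * np.log10(hi / lo)))
    t = np.geomspace(lo, hi, n)
    F = eyring_solution(t, p)
    if noise > 0:
        if rng is None:
            raise ValueError("a seeded rng is required for noisy curves")
        F = F + rng.normal(0.0, noise, size=n)
    return CorrelationSeries(t, F)


def synth_curves(
    params: list[EyringParams],
    out_dir,
    noise: float = 0.0,
    seed: int = 0,
    window: tuple[float, float] | None = None,
    points_per_decade: int = POINTS_PER_DECADE,
) -> Path:
    """Write fixture curves plus a manifest with the ground truth.

    Returns the manifest path.  Curves are named curve_000.tsv, ... in
    ``out_dir``; the manifest records (eps, k1, k2), the seed and the noise
    level for every curve.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries = []
    for i, p in enumerate(params):
        curve = synth_curve(p, noise=noise, rng=rng if noise else None,
                            window=window, points_per_decade=points_per_decade)
        name = f"curve_{i:03d}.tsv"
        write_curve(out / name, curve)
        entries.append(
            {"file": name, "eps": p.eps, "k1": p.k1, "k2": p.k2,
             "gamma": p.gamma, "noise": noise}
        )
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"seed": seed, "curves": entries}, indent=2))
    return manifest
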