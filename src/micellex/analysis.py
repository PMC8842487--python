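"""Radial conformational diagnostics of the micelle exit pathway.

As a chain leaves the micelle its hydrophobic block first crumples (hairpin
formation, lowering the energy barrier across the corona) and then relaxes
back to the bulk coil.  Two observables resolve this along the exit path:
the PO-block radius of gyration relative to its bulk value Rg*, and the
angle spanned by the two EO-block centres of mass seen from the PO centre
(180 deg = fully stretched, small angles = hairpin), both binned against the
distance of the PO-block centre of mass from the micelle centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibrium import FieldState, ShellLattice

__all__ = [
    "RadialProfile",
    "RegionBoundaries",
    "BoundaryError",
    "radial_profiles",
    "region_boundaries",
]


class BoundaryError(RuntimeError):
    """No core/corona/bulk structure found in the fields (no micelle)."""


@dataclass
class RadialProfile:
    """Weighted bin averages of a conformational observable versus the
    distance of the PO-block centre of mass from the micelle centre."""

    r_mid: np.ndarray
    mean: np.ndarray  # NaN for bins with insufficient samples
    stderr: np.ndarray
    counts: np.ndarray  # effective (weight-based) counts per bin
    rg_star: float | None = None  # bulk normaliser when the profile is Rg_PO/Rg*

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.mean)


@dataclass(frozen=True)
class RegionBoundaries:
    """Radii of the core/corona and corona/bulk interfaces (sigma)."""

    r_core_corona: float
    r_corona_bulk: float

    def __post_init__(self) -> None:
        if not (0.0 < self.r_core_corona < self.r_corona_bulk):
            raise ValueError("need 0 < r_core_corona < r_corona_bulk")


def _binned(
    r: np.ndarray,
    values: np.ndarray,
    weights: np.ndarray,
    bin_width: float,
    r_max: float,
    min_count: float,
) -> RadialProfile:
    ok = np.isfinite(values) & np.isfinite(r) & (weights > 0)
    r, values, weights = r[ok], values[ok], weights[ok]
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    nb = edges.size - 1
    idx = np.clip((r / bin_width).astype(int), 0, nb - 1)
    inside = r < edges[-1]
    idx, values, weights = idx[inside], values[inside], weights[inside]
    wsum = np.bincount(idx, weights=weights, minlength=nb)
    vsum = np.bincount(idx, weights=weights * values, minlength=nb)
    v2sum = np.bincount(idx, weights=weights * values**2, minlength=nb)
    # effective sample size per bin (Kish): (sum w)^2 / sum w^2
    w2sum = np.bincount(idx, weights=weights**2, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        ess = np.where(w2sum > 0, wsum**2 / w2sum, 0.0)
        mean = vsum / wsum
        var = np.maximum(v2sum / wsum - mean**2, 0.0)
        stderr = np.sqrt(var / np.maximum(ess, 1.0))
    bad = ess < min_count
    mean[bad] = np.nan
    stderr[bad] = np.nan
    return RadialProfile(0.5 * (edges[1:] + edges[:-1]), mean, stderr, ess)


def radial_profiles(
    r_po_com: np.ndarray,
    rg_po: np.ndarray,
    angle_deg: np.ndarray,
    weights: np.ndarray | None = None,
    rg_star: float | None = None,
    bin_width: float = 0.5,
    r_max: float = 20.0,
    min_count: float = 50.0,
) -> tuple[RadialProfile, RadialProfile]:
    """Rg and angle profiles from per-sample conformational metrics.

    Input arrays are per (weighted) sample: PO-centre radius, PO-block radius
    of gyration and EO-PO-EO angle; equilibrium callers pass the converged
    SCMF weights, dynamics callers pass unit weights over trajectory frames.
    When ``rg_star`` (the bulk free-chain value) is given the Rg profile is
    reported as the dimensionless ratio Rg_PO/Rg*.  Bins with fewer than
    ``min_count`` effective samples are reported as NaN, never interpolated.
    """
    r_po_com = np.asarray(r_po_com, dtype=float)
    if weights is None:
        weights = np.ones_like(r_po_com)
    weights = np.asarray(weights, dtype=float)
    rg = np.asarray(rg_po, dtype=float)
    if rg_star is not None:
        rg = rg / rg_star
    prof_rg = _binned(r_po_com, rg, weights, bin_width, r_max, min_count)
    prof_rg.rg_star = rg_star
    prof_an = _binned(
        r_po_com, np.asarray(angle_deg, dtype=float), weights, bin_width, r_max, min_count
    )
    return prof_rg, prof_an


def _crossing(r: np.ndarray, f: np.ndarray) -> float:
    """First downward zero crossing of f(r), linearly interpolated."""
    s = np.sign(f)
    for i in range(len(f) - 1):
        if s[i] > 0 and s[i + 1] <= 0:
            x0, x1, f0, f1 = r[i], r[i + 1], f[i], f[i + 1]
            return float(x0 + (x1 - x0) * f0 / (f0 - f1))
    raise BoundaryError("no crossing found")


def region_boundaries(fields: FieldState, lattice: ShellLattice) -> RegionBoundaries:
    """Detect the core/corona and corona/bulk interface radii.

    The core/corona interface is where the PO and EO concentration profiles
    cross; the corona/bulk interface is where the EO concentration has
    decayed to its bulk value plus 5% of its peak excess.  Profiles without
    the corresponding structure raise :class:`BoundaryError` (no micelle).
    """
    # the last (reservoir) shell provides the bulk reference; interface
    # detection itself is restricted to the uniformly discretised region
    r = lattice.radii[:-1]
    c_eo, c_po = fields.c_EO[:-1], fields.c_PO[:-1]
    if np.all(c_po <= 0):
        raise BoundaryError("no PO density: no micelle")
    r_cc = _crossing(r, c_po - c_eo)
    bulk = float(fields.c_EO[-1])
    peak = float(c_eo.max())
    if peak <= bulk:
        raise BoundaryError("EO profile has no corona peak")
    target = bulk + 0.05 * (peak - bulk)
    i_peak = int(np.argmax(c_eo))
    tail_r, tail_c = r[i_peak:], c_eo[i_peak:]
    r_cb = _crossing(tail_r, tail_c - target)
    if not r_cc < r_cb:
        raise BoundaryError("degenerate interfaces: corona collapsed")
    return RegionBoundaries(r_cc, r_cb)
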