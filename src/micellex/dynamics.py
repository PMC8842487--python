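"""Dynamic single-chain mean-field Monte Carlo of micelle chain exchange.

Every chain in the cell carries explicit coordinates and receives one
proposed local move per cycle, accepted with the Metropolis probability
min(1, exp(-dH)) where dH combines the exact intramolecular energy change
with the mean-field intermolecular energy in the current shell fields; the
fields are re-solved once per cycle from the updated ensemble.  One cycle is
one time step; the conversion to seconds compares the measured free-chain
centre-of-mass diffusion coefficient D_SCMF (sigma^2/cycle) with the
physical Stokes-Einstein diffusion D = k_B T / (6 pi eta a):

    t_cycle = D_SCMF * l^2 / D,     l = 0.2 nm (physical bead size).

The exchange observable is the TR-SANS-style relaxation function: all chains
inside the micelle are tagged at t = 0, f(t) counts tagged chains still (or
again) inside, and

    F(t) = (f(t) - f_eq) / (f(0) - f_eq),

with f_eq = f(0) * f(0)/N_chains the tagged count at complete mixing
(computed, not measured, because runs are far shorter than the mixing time).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .chain import (
    PO,
    ChainSpec,
    DEFAULT_POTENTIAL,
    PairPotential,
    build_kuhn_partition,
    sample_conformations_batch,
)
from .equilibrium import (
    FieldState,
    ShellLattice,
    TEMPERATURE_K,
    V_BEAD,
    V_SOLVENT,
    build_lattice,
)
from .series import CorrelationSeries

__all__ = [
    "DynamicsState",
    "TimeCalibration",
    "build_micelle_state",
    "mc_cycle",
    "run_exchange",
    "measure_diffusion",
    "calibrate_time",
    "record_schedule",
    "DEFAULT_AMPLITUDE",
]

BOLTZMANN = 1.380649e-23  # J/K
WATER_VISCOSITY_37C = 6.91e-4  # kg m^-1 s^-1
BEAD_SIZE_M = 0.2e-9  # physical monomer size l

#: default move amplitude (radians / sigma); acceptance saturates near
#: 55-60% for in-micelle chains at this value (the mean-field energy surface
#: is smooth, so pushing the amplitude higher buys little)
DEFAULT_AMPLITUDE = 1.5

#: membership hysteresis in sigma, suppressing boundary flicker
MEMBERSHIP_HYSTERESIS = 1.0

#: micelle sizes used for the exchange runs: the model's own preferred
#: aggregation numbers for flexible/semiflexible (so the micelle neither
#: grows nor shrinks during the run), and a reduced size for the rigid case
#: to keep the run affordable (micelle size has little effect on the
#: exchange dynamics)
DEFAULT_EXCHANGE_SIZES = {"flexible": 145, "semiflexible": 280, "rigid": 200}


@dataclass
class DynamicsState:
    """Explicit chain ensemble plus the shell fields it generates."""

    spec: ChainSpec
    pot: PairPotential
    lattice: ShellLattice
    positions: np.ndarray  # (Nc, nb, 3)
    tagged: np.ndarray  # (Nc,) bool, immutable after tagging
    inside: np.ndarray  # (Nc,) bool, membership with hysteresis
    r_bound: float  # corona/bulk interface radius used for membership
    amplitude: float = DEFAULT_AMPLITUDE
    r_wall: float = 0.0  # confining wall for the PO-block COM
    t_cyc: int = 0
    seed: int = 0
    acceptance: float = float("nan")
    n_bulk_pending: int = 0  # untagged bulk chains injected at tagging time

    @property
    def n_chains(self) -> int:
        return self.positions.shape[0]

    def field_state(self) -> FieldState:
        """Shell fields from the instantaneous bead counts."""
        lab = self.spec.block_labels
        is_po = lab == PO
        r = np.linalg.norm(self.positions, axis=2)
        idx = self.lattice.shell_of(np.minimum(r.ravel(), self.lattice.edges[-1] - 1e-9))
        idx = idx.reshape(r.shape)
        J = self.lattice.n_shells
        vols = self.lattice.volumes
        c_eo = np.bincount(idx[:, ~is_po].ravel(), minlength=J) / vols
        c_po = np.bincount(idx[:, is_po].ravel(), minlength=J) / vols
        omega = self.pot.well_volume
        m_eo, m_po = omega * c_eo, omega * c_po
        phi_s = np.clip(1.0 - V_BEAD * (c_eo + c_po), 1e-12, 1.0)
        c_s = phi_s / V_SOLVENT
        pi = -(np.log(phi_s) + self.pot.e_EO_s * m_eo + self.pot.e_PO_s * m_po) / V_SOLVENT
        return FieldState(c_eo, c_po, c_s, pi, m_eo, m_po, N=self.n_chains)


@dataclass(frozen=True)
class TimeCalibration:
    """Conversion between Monte-Carlo cycles and physical time."""

    D_scmf: float  # sigma^2 / cycle
    a_hydro_m: float  # hydrodynamic radius (m)
    T: float = TEMPERATURE_K
    eta: float = WATER_VISCOSITY_37C
    l: float = BEAD_SIZE_M

    def __post_init__(self) -> None:
        if self.a_hydro_m <= 0 or self.eta <= 0:
            raise ValueError("hydrodynamic radius and viscosity must be positive")

    @property
    def D_phys(self) -> float:
        """Stokes-Einstein diffusion coefficient, m^2/s."""
        return BOLTZMANN * self.T / (6.0 * np.pi * self.eta * self.a_hydro_m)

    @property
    def t_cycle(self) -> float:
        """Seconds per Monte-Carlo cycle."""
        return self.D_scmf * self.l**2 / self.D_phys


def calibrate_time(
    D_scmf: float,
    a_hydro_m: float,
    T: float = TEMPERATURE_K,
    eta: float = WATER_VISCOSITY_37C,
    l: float = BEAD_SIZE_M,
) -> TimeCalibration:
    """Build a :class:`TimeCalibration`; see the module docstring.

    The hydrodynamic radius ``a`` must be supplied explicitly (a reasonable
    default is the measured free-chain radius of gyration times the physical
    bead size)."""
    return TimeCalibration(D_scmf, a_hydro_m, T, eta, l)


def _seg_stops(spec: ChainSpec) -> np.ndarray:
    return np.array([s.stop for s in build_kuhn_partition(spec)], dtype=np.int64)


def build_micelle_state(
    spec: ChainSpec,
    pot: PairPotential,
    n_micelle: int,
    n_bulk: int | None = None,
    lattice: ShellLattice | None = None,
    seed: int = 0,
    amplitude: float = DEFAULT_AMPLITUDE,
) -> DynamicsState:
    """Initial condition: ``n_micelle`` chains packed near the centre plus a
    small bulk population; run a burn-in before tagging."""
    rng = np.random.default_rng(seed)
    if lattice is None:
        lattice = build_lattice(n_inner=36)
    if n_bulk is None:
        n_bulk = max(10, n_micelle // 4)
    pos, _, _ = sample_conformations_batch(spec, n_micelle, rng, pot)
    # initial packing at total bead volume fraction ~0.6 so the cell is not
    # over-filled before the fields relax
    r_init = float((3.0 * n_micelle * spec.n_beads * V_BEAD / (4.0 * np.pi * 0.6)) ** (1 / 3))
    r_core = float((3.0 * n_micelle * spec.n_PO * V_BEAD / (4.0 * np.pi * 0.85)) ** (1 / 3))
    r_wall = lattice.r_inner - 2.0
    radii = r_init * rng.random(n_micelle) ** (1 / 3)
    dirs = rng.normal(size=(n_micelle, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pos = pos + (dirs * radii[:, None])[:, None, :]
    inside = np.ones(n_micelle, dtype=bool)
    return DynamicsState(
        spec=spec,
        pot=pot,
        lattice=lattice,
        positions=pos,
        tagged=np.zeros(n_micelle, dtype=bool),
        inside=inside,
        r_bound=r_core + 4.0,  # refined after burn-in
        amplitude=amplitude,
        r_wall=r_wall,
        seed=seed,
        n_bulk_pending=n_bulk,
    )


def _run(state: DynamicsState, n_cycles: int, record_at: np.ndarray,
         prof_stride: int = 0, max_prof: int = 1, freeze_fields: bool = False,
         frozen_potentials: tuple[np.ndarray, np.ndarray] | None = None,
         seed_offset: int = 0):
    lab = state.spec.block_labels
    is_po = lab == PO
    J = state.lattice.n_shells
    if frozen_potentials is None:
        u_eo = np.zeros(J)
        u_po = np.zeros(J)
        u_pi = np.zeros(J)
    else:
        u_eo, u_po, u_pi = (np.array(u, dtype=float) for u in frozen_potentials)
    prof_r = np.zeros(max_prof)
    prof_rg = np.zeros(max_prof)
    prof_angle = np.zeros(max_prof)
    f_out, n_acc, prof_count = _kernels.run_dynamics(
        state.positions,
        is_po,
        _seg_stops(state.spec),
        state.pot.e_EO_PO,
        state.pot.e_EO_PO,
        state.pot.e_EO_s,
        state.pot.e_PO_s,
        V_BEAD,
        V_SOLVENT,
        state.pot.well_volume,
        state.pot.well_outer,
        state.pot.hard_core,
        state.pot.exclusion_radius,
        state.lattice.volumes,
        state.lattice.shell_width,
        state.lattice.r_inner,
        state.amplitude,
        state.r_wall,
        int(n_cycles),
        record_at.astype(np.int64),
        state.tagged,
        state.inside,
        state.r_bound,
        MEMBERSHIP_HYSTERESIS,
        (state.seed + seed_offset) % (2**31 - 1),
        int(prof_stride),
        prof_r,
        prof_rg,
        prof_angle,
        int(state.spec.n_head_EO),
        int(state.spec.n_PO),
        freeze_fields,
        u_eo,
        u_po,
        u_pi,
    )
    state.t_cyc += int(n_cycles)
    state.acceptance = n_acc / max(n_cycles * state.n_chains, 1)
    profiles = (prof_r[:prof_count], prof_rg[:prof_count], prof_angle[:prof_count])
    return f_out, profiles


def mc_cycle(state: DynamicsState, n_cycles: int = 1,
             freeze_fields: bool = False,
             frozen_potentials: tuple[np.ndarray, np.ndarray] | None = None) -> DynamicsState:
    """Advance the ensemble by ``n_cycles`` Metropolis cycles in place."""
    _run(state, n_cycles, np.empty(0, dtype=np.int64), freeze_fields=freeze_fields,
         frozen_potentials=frozen_potentials, seed_offset=17 + state.t_cyc)
    return state


def record_schedule(n_cycles: int, per_decade: int = 25) -> np.ndarray:
    """Log-spaced cycle indices (unique integers, always including 1 and n)."""
    raw = np.geomspace(1, n_cycles, int(per_decade * np.log10(max(n_cycles, 2)) + 2))
    return np.unique(np.round(raw).astype(np.int64))


def run_exchange(
    state: DynamicsState,
    n_cycles: int,
    burn_in: int = 2000,
    per_decade: int = 25,
    prof_stride: int = 0,
    calibration: TimeCalibration | None = None,
) -> tuple[CorrelationSeries, dict]:
    """Equilibrate, tag the in-micelle chains, and track F(t).

    Returns the relaxation curve (cycles domain, or seconds when a
    calibration is given) and a diagnostics dict that includes the membership
    boundary, acceptance rate and any conformational profile samples.
    """
    from .analysis import BoundaryError, region_boundaries

    if burn_in > 0:
        mc_cycle(state, burn_in)
    # refine the membership boundary from the equilibrated fields
    try:
        rb = region_boundaries(state.field_state(), state.lattice)
        state.r_bound = rb.r_corona_bulk
    except BoundaryError:
        pass  # keep the geometric estimate
    # inject the untagged bulk population outside the equilibrated micelle
    if state.n_bulk_pending > 0:
        rng = np.random.default_rng(state.seed + 7919)
        nb_chains = state.n_bulk_pending
        bpos, _, _ = sample_conformations_batch(state.spec, nb_chains, rng, state.pot)
        lo = state.r_bound + 2.0
        hi = max(state.r_wall - 1.0, lo + 1.0)
        radii = (lo**3 + (hi**3 - lo**3) * rng.random(nb_chains)) ** (1 / 3)
        dirs = rng.normal(size=(nb_chains, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        bpos = bpos + (dirs * radii[:, None])[:, None, :]
        state.positions = np.concatenate([state.positions, bpos], axis=0)
        state.inside = np.concatenate([state.inside, np.zeros(nb_chains, dtype=bool)])
        state.tagged = np.concatenate([state.tagged, np.zeros(nb_chains, dtype=bool)])
        state.n_bulk_pending = 0
    r = np.linalg.norm(
        state.positions[:, state.spec.block_labels == PO, :].mean(axis=1), axis=1
    )
    state.inside[:] = r < state.r_bound
    state.tagged[:] = state.inside
    f0 = int(state.tagged.sum())
    if f0 == 0:
        raise RuntimeError("no chains inside the micelle at t=0; cannot tag")
    if f0 == state.n_chains:
        raise RuntimeError("no untagged bulk chains present; F(t) is degenerate")

    record_at = record_schedule(n_cycles, per_decade)
    max_prof = 1
    if prof_stride:
        max_prof = (n_cycles // prof_stride + 1) * state.n_chains
    f_vals, profiles = _run(
        state, n_cycles, record_at, prof_stride=prof_stride, max_prof=max_prof,
        seed_offset=101,
    )
    f_eq = f0 * f0 / state.n_chains
    F = (f_vals - f_eq) / (f0 - f_eq)
    times = np.concatenate(([0.0], record_at.astype(float)))
    F = np.concatenate(([1.0], F))
    series = CorrelationSeries(times[1:], F[1:], f0=float(f0), domain="cycles")
    if calibration is not None:
        series = series.to_seconds(calibration.t_cycle)
    diag = {
        "f0": f0,
        "f_eq": f_eq,
        "r_bound": state.r_bound,
        "acceptance": state.acceptance,
        "profiles": profiles,
        "n_chains": state.n_chains,
    }
    return series, diag


def measure_diffusion(
    spec: ChainSpec,
    pot: PairPotential = DEFAULT_POTENTIAL,
    n_chains: int = 64,
    n_cycles: int = 20000,
    amplitude: float = DEFAULT_AMPLITUDE,
    seed: int = 0,
    stride: int = 50,
) -> tuple[float, dict]:
    """Free-chain centre-of-mass diffusion coefficient D_SCMF (sigma^2/cycle).

    Chains evolve in bulk (no fields); D is the slope of the mean-square
    centre-of-mass displacement against cycles, divided by 6.  Raises when
    the track is too short to show a linear regime.
    """
    if n_cycles < 10 * stride:
        raise ValueError("n_cycles too short for a linear MSD regime")
    rng = np.random.default_rng(seed)
    pos, _, _ = sample_conformations_batch(spec, n_chains, rng, pot)
    coms, n_acc = _kernels.free_diffusion(
        pos,
        spec.block_labels == PO,
        _seg_stops(spec),
        pot.e_EO_PO,
        amplitude,
        int(n_cycles),
        int(stride),
        seed % (2**31 - 1),
    )
    disp = coms - coms[0]
    msd = np.mean(np.sum(disp**2, axis=2), axis=1)
    t = np.arange(msd.size) * stride
    # fit the latter 80% (skip any ballistic-ish transient)
    i0 = max(1, msd.size // 5)
    slope = np.polyfit(t[i0:], msd[i0:], 1)[0]
    com = pos.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum((pos - com) ** 2, axis=2), axis=1))
    diag = {
        "acceptance": n_acc / (n_cycles * n_chains),
        "msd": msd,
        "cycles": t,
        "rg_mean": float(rg.mean()),
    }
    return float(slope / 6.0), diag
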