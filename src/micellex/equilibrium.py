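"""Self-consistent single-chain mean-field equilibrium on spherical shells.

One explicit self-avoiding chain interacts with the *average* concentration
fields of the other chains and of the implicit solvent.  The fields live on
concentric spherical shells centred on the (pinned) micelle; every sampled
conformation alpha is projected onto the shells as

* ``phi(alpha, r)``     volume fraction of its beads,
* ``c_X(alpha, r)``     bead-number concentration per species,
* ``Phi_X(alpha, r)``   the square-well ("available interaction") volume
                        around its beads of species X, apportioned to shells
                        by exact sphere-sphere overlap.

The free energy per cell (units of k_B T, lengths in sigma) is

    F = N <U_intra>_P
      + (eps_EO,PO/z) (N-1)/N * 1/2 Int [ <Phi_EO><c_PO> + <Phi_PO><c_EO> ]
      + (eps_EO,s/z) Int <Phi_EO> c_s  +  (eps_PO,s/z) Int <Phi_PO> c_s
      + N Sum_a P[a] ln( P[a] / w0[a] )          (conformational entropy)
      + Int c_s(r) [ ln phi_s(r) - 1 ]           (solvent translational entropy)

minimised over the conformation probabilities P[a] subject to the
incompressibility constraint phi_chains(r) + phi_s(r) = 1, which is
eliminated exactly: c_s = (1 - phi_chains)/v_s and the Lagrange field

    pi(r) = -[ ln phi_s(r) + (eps_EO,s/z)<Phi_EO> + (eps_PO,s/z)<Phi_PO> ] / v_s

follows from the solvent stationarity condition.  The resulting fixed point
is P[a] proportional to w0[a] exp(-H[a]) with the single-chain Hamiltonian
H[a] = dF/d(N P[a]); the implementation keeps F and H *exactly* variationally
consistent, so the self-consistent solution coincides with a direct
minimisation of the functional.

``w0`` are the a-priori measure weights of the sampled conformations
(placement volume element divided by the sampling density), so entropies are
absolute up to a single internal-conformation reference that cancels in all
chemical-potential differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .chain import (
    EO,
    PO,
    ChainSpec,
    Conformation,
    DEFAULT_POTENTIAL,
    PairPotential,
    intra_energy,
    sample_conformation,
    shape_metrics,
)

__all__ = [
    "ShellLattice",
    "FieldState",
    "ConformationEnsemble",
    "SCFResult",
    "MicellizationScan",
    "LatticeError",
    "ConvergenceError",
    "build_lattice",
    "project_conformation",
    "scmf_hamiltonian",
    "solve_self_consistent",
    "free_energy",
    "micellization_scan",
    "sample_ensemble",
    "sample_ensemble_grid",
    "chain_standard_potential",
    "cmc_from_delta_mu",
    "build_lattice",
    "V_BEAD",
    "V_SOLVENT",
    "WATER_MOLARITY",
]

#: bead (monomer) volume in sigma^3; the solvent molecule occupies the same
#: volume by default, which makes the number of solvent neighbours of an
#: isolated bead equal the coordination number z = 26 of the printed well
#: depths.
V_BEAD = np.pi / 6.0

#: effective solvent-site volume in sigma^3.  Kept equal to the bead volume:
#: a fully exposed bead then makes well_volume/v_s = 26 solvent contacts,
#: which is exactly the coordination number z = 26 that normalises the
#: printed well depths.  (The overall binding-depth calibration lives in the
#: self-exclusion radius of the pair potential instead; see the methods
#: note.)
V_SOLVENT = 1.0 * V_BEAD

#: molar concentration of water used to convert min(delta mu) to a CMC
WATER_MOLARITY = 55.5

#: simulation temperature (the interaction parameters are only valid here)
TEMPERATURE_K = 310.15

_PHI_S_FLOOR = 1e-12


class LatticeError(ValueError):
    """Conformation beads fall outside the lattice (cell too small)."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


@dataclass(frozen=True)
class ShellLattice:
    """Concentric spherical shells: uniform inner shells + one wide outer
    reservoir shell that plays the role of the bulk solution."""

    edges: np.ndarray  # (J+1,) increasing, edges[0] == 0
    shell_width: float

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e[0] != 0.0 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must start at 0 and increase")
        object.__setattr__(self, "edges", e)

    @property
    def n_shells(self) -> int:
        return self.edges.size - 1

    @property
    def radii(self) -> np.ndarray:
        """Mid-shell radii."""
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    @property
    def volumes(self) -> np.ndarray:
        return 4.0 * np.pi / 3.0 * np.diff(self.edges**3)

    @property
    def V(self) -> float:
        return float(4.0 * np.pi / 3.0 * self.edges[-1] ** 3)

    @property
    def r_inner(self) -> float:
        """Outer radius of the uniformly discretised region."""
        return float(self.edges[-2])

    def shell_of(self, r: np.ndarray) -> np.ndarray:
        """Shell index for radii; raises LatticeError beyond the cell."""
        r = np.asarray(r, dtype=float)
        if np.any(r > self.edges[-1]):
            raise LatticeError("bead radius exceeds the cell: lattice too small")
        idx = np.minimum((r / self.shell_width).astype(np.int64), self.n_shells - 2)
        return np.where(r >= self.r_inner, self.n_shells - 1, idx)


def build_lattice(
    shell_width: float = 1.0, n_inner: int = 24, reservoir_extent: float = 45.0
) -> ShellLattice:
    """Uniform shells out to ``n_inner * shell_width`` plus a bulk reservoir
    shell wide enough that no bead of a chain placed inside the inner region
    can leave the cell."""
    inner = np.arange(n_inner + 1, dtype=float) * shell_width
    edges = np.append(inner, inner[-1] + reservoir_extent)
    return ShellLattice(edges, shell_width)


# ---------------------------------------------------------------------------
# projections


def _sphere_overlap(R: np.ndarray, a: float, d: np.ndarray) -> np.ndarray:
    """Volume of the intersection of a sphere of radius ``R`` at the origin
    with a sphere of radius ``a`` centred a distance ``d`` away."""
    R = np.asarray(R, dtype=float)
    d = np.asarray(d, dtype=float)
    full = 4.0 * np.pi / 3.0 * min(a, 1e300) ** 3
    out = np.zeros(np.broadcast_shapes(R.shape, d.shape))
    Rb, db = np.broadcast_arrays(R, d)
    # no overlap
    far = db >= Rb + a
    # one sphere inside the other
    inside = db <= np.abs(Rb - a)
    lens = ~far & ~inside
    Rl, dl = Rb[lens], db[lens]
    out[lens] = (
        np.pi
        * (Rl + a - dl) ** 2
        * (dl**2 + 2.0 * dl * (a + Rl) - 3.0 * (a - Rl) ** 2)
        / (12.0 * dl)
    )
    out[inside & (Rb >= a)] = full
    small = inside & (Rb < a)
    out[small] = 4.0 * np.pi / 3.0 * Rb[small] ** 3
    return out


def _well_shell_volumes(radii: np.ndarray, lattice: ShellLattice, pot: PairPotential) -> np.ndarray:
    """Apportion each bead's square-well volume onto the lattice shells.

    For a bead at radius ``d`` the well occupies the region between spheres
    of radii ``hard_core`` and ``well_outer`` around it; its overlap with the
    radial bin [R_j, R_{j+1}] follows from four concentric-sphere overlap
    volumes.  Returns an array (n_beads, n_shells) of volumes.
    """
    d = np.asarray(radii, dtype=float)[:, None]
    edges = lattice.edges[None, :]
    W = _sphere_overlap(edges, pot.well_outer, d) - _sphere_overlap(edges, pot.hard_core, d)
    return np.diff(W, axis=1)


def project_conformation(
    conf: Conformation,
    lattice: ShellLattice,
    center: np.ndarray | None = None,
    pot: PairPotential = DEFAULT_POTENTIAL,
    exclude_self: bool = False,
):
    """Project one placed conformation onto the shell lattice.

    Returns ``(phi_EO, phi_PO, Phi_EO, Phi_PO)``: bead volume fractions
    (bead volume binned by the bead-centre shell, divided by the shell
    volume) and square-well volume densities per shell.  With
    ``exclude_self`` the well volumes are reduced to the fractions not
    blocked by the chain's own beads (the "available" interaction volume
    used by the ensemble builders and the dynamics).
    """
    from .chain import available_fractions

    pos = conf.positions if center is None else conf.positions + np.asarray(center)
    r = np.linalg.norm(pos, axis=1)
    if np.any(r + pot.well_outer > lattice.edges[-1]):
        raise LatticeError("conformation extends outside the lattice")
    J = lattice.n_shells
    vols = lattice.volumes
    idx = lattice.shell_of(r)
    phi = np.zeros((2, J))
    for species in (EO, PO):
        sel = conf.block_labels == species
        phi[species] = np.bincount(idx[sel], minlength=J) * V_BEAD / vols
    well = _well_shell_volumes(r, lattice, pot)
    if exclude_self:
        well = well * available_fractions(pos, pot)[:, None]
    Phi_EO = well[conf.block_labels == EO].sum(axis=0) / vols
    Phi_PO = well[conf.block_labels == PO].sum(axis=0) / vols
    return phi[EO], phi[PO], Phi_EO, Phi_PO


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class ConformationEnsemble:
    """A sampled set {alpha} of placed conformations in shell projection.

    ``n_EO``/``n_PO`` are bead counts per shell, ``Phi_EO``/``Phi_PO`` the
    square-well volume densities, ``U`` the exact intramolecular energies and
    ``log_w0`` the log a-priori measure weights (placement volume element over
    sampling density; their exponentials sum to the sampled placement volume).
    """

    n_EO: np.ndarray  # (M, J) float
    n_PO: np.ndarray  # (M, J)
    Phi_EO: np.ndarray  # (M, J) well-volume density
    Phi_PO: np.ndarray  # (M, J)
    U: np.ndarray  # (M,)
    log_w0: np.ndarray  # (M,)
    lattice: ShellLattice
    r_place: np.ndarray | None = None  # placement radius of the PO-block COM
    rg_PO: np.ndarray | None = None
    angle: np.ndarray | None = None
    conf_index: np.ndarray | None = None  # internal-conformation id per state
    r_grid: np.ndarray | None = None  # placement radii when grid-sampled

    @property
    def M(self) -> int:
        return self.U.size

    @property
    def n_beads_per_chain(self) -> float:
        return float((self.n_EO[0] + self.n_PO[0]).sum())


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def sample_ensemble(
    spec: ChainSpec,
    lattice: ShellLattice,
    n_samples: int,
    rng: np.random.Generator,
    pot: PairPotential = DEFAULT_POTENTIAL,
    r_max: float | None = None,
    radial_density: tuple[np.ndarray, np.ndarray] | None = None,
) -> ConformationEnsemble:
    """Sample free-chain conformations and place them in the cell.

    Internal conformations are drawn from the uniform self-avoiding ensemble;
    each is randomly rotated and its PO-block centre of mass is placed at a
    radius drawn uniformly in [0, r_max] (importance weight proportional to
    r^2 corrects back to a uniform-in-volume measure).  ``radial_density``
    optionally supplies a piecewise-constant radial density (bin edges,
    probabilities) that is mixed 50/50 with the uniform draw to enrich
    poorly sampled regions; the measure weights account for it exactly.
    """
    if r_max is None:
        r_max = lattice.r_inner
    J = lattice.n_shells
    M = n_samples
    n_EO = np.zeros((M, J))
    n_PO = np.zeros((M, J))
    Phi_EO = np.zeros((M, J))
    Phi_PO = np.zeros((M, J))
    U = np.zeros(M)
    log_w0 = np.zeros(M)
    r_place = np.zeros(M)
    rg_po = np.zeros(M)
    angle = np.zeros(M)
    vols = lattice.volumes

    if radial_density is not None:
        bin_edges, bin_probs = radial_density
        bin_probs = np.maximum(np.asarray(bin_probs, dtype=float), 0.0)
        bin_probs = bin_probs / bin_probs.sum()
        widths = np.diff(bin_edges)

    labels = spec.block_labels
    is_po = labels == PO
    is_eo = ~is_po
    for m in range(M):
        conf = sample_conformation(spec, rng)
        Q = _random_rotation(rng)
        pos = conf.positions @ Q.T
        po_com = pos[is_po].mean(axis=0)
        if radial_density is not None and rng.random() < 0.5:
            b = rng.choice(bin_probs.size, p=bin_probs)
            r = float(rng.uniform(bin_edges[b], bin_edges[b + 1]))
        else:
            r = float(rng.uniform(0.0, r_max))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos - po_com + direction * r
        # sampling density of the radius (per unit r)
        g_r = 1.0 / r_max
        if radial_density is not None:
            b = min(int(np.searchsorted(bin_edges, r, side="right")) - 1, widths.size - 1)
            g_r = 0.5 / r_max + 0.5 * bin_probs[b] / widths[b]
        # measure weight: dV / (M * g) with dV = 4 pi r^2 dr
        log_w0[m] = np.log(4.0 * np.pi * max(r, 1e-300) ** 2 / (M * g_r))
        radii = np.linalg.norm(pos, axis=1)
        idx = lattice.shell_of(radii)
        n_EO[m] = np.bincount(idx[is_eo], minlength=J)
        n_PO[m] = np.bincount(idx[is_po], minlength=J)
        from .chain import available_fractions

        well = _well_shell_volumes(radii, lattice, pot)
        well = well * available_fractions(pos, pot)[:, None]
        Phi_EO[m] = well[is_eo].sum(axis=0) / vols
        Phi_PO[m] = well[is_po].sum(axis=0) / vols
        U[m] = intra_energy(Conformation(pos, labels), pot)
        r_place[m] = r
        sm = shape_metrics(Conformation(pos, labels))
        rg_po[m] = sm.rg_PO
        angle[m] = sm.eo_po_eo_angle_deg
    return ConformationEnsemble(
        n_EO, n_PO, Phi_EO, Phi_PO, U, log_w0, lattice, r_place, rg_po, angle
    )


def sample_ensemble_grid(
    spec: ChainSpec,
    lattice: ShellLattice,
    n_conf: int,
    rng: np.random.Generator,
    pot: PairPotential = DEFAULT_POTENTIAL,
    n_radii: int = 16,
    r_max: float = 20.0,
    chunk: int = 250,
) -> ConformationEnsemble:
    """Sample internal conformations and integrate placements on a radial grid.

    Every internal conformation (isotropically oriented, PO-block centre of
    mass at the origin) is projected onto the lattice at *every* radius of a
    uniform grid covering [0, r_max]; each (conformation, radius) pair is one
    ensemble state whose measure weight is the volume of its radial bin
    divided by the number of conformations.  Placing each conformation at all
    radii, rather than one sampled radius, is what lets a modest conformation
    count resolve both the dense micelle core and the dilute bulk.
    """
    from .chain import sample_conformations_batch

    pos, U_conf, avail = sample_conformations_batch(spec, n_conf, rng, pot)
    labels = spec.block_labels
    is_po = labels == PO
    is_eo = ~is_po
    nb = spec.n_beads
    J = lattice.n_shells
    vols = lattice.volumes
    dr = r_max / n_radii
    rho = (np.arange(n_radii) + 0.5) * dr
    dV = 4.0 * np.pi / 3.0 * ((rho + 0.5 * dr) ** 3 - (rho - 0.5 * dr) ** 3)

    M = n_conf * n_radii
    n_EO = np.zeros((M, J))
    n_PO = np.zeros((M, J))
    Phi_EO = np.zeros((M, J))
    Phi_PO = np.zeros((M, J))

    for c0 in range(0, n_conf, chunk):
        c1 = min(c0 + chunk, n_conf)
        C = c1 - c0
        p = pos[c0:c1]  # (C, nb, 3)
        # place along z at every grid radius; orientations are already random
        rad = np.sqrt(
            p[:, :, 0][:, :, None] ** 2
            + p[:, :, 1][:, :, None] ** 2
            + (p[:, :, 2][:, :, None] + rho[None, None, :]) ** 2
        )  # (C, nb, n_radii)
        idx = lattice.shell_of(rad.ravel()).reshape(C, nb, n_radii)
        # bead counts per (conformation, radius, shell)
        state = np.broadcast_to(
            (np.arange(C)[:, None, None] * n_radii + np.arange(n_radii)[None, None, :]),
            idx.shape,
        )
        flat = state * J + idx
        row0 = c0 * n_radii
        for species, sel in ((EO, is_eo), (PO, is_po)):
            counts = np.bincount(flat[:, sel, :].ravel(), minlength=C * n_radii * J)
            counts = counts.reshape(C * n_radii, J)
            if species == EO:
                n_EO[row0 : row0 + C * n_radii] = counts
            else:
                n_PO[row0 : row0 + C * n_radii] = counts
        # square-well volumes via exact sphere overlaps, scaled down by the
        # fraction blocked by the chain's own beads
        well = _well_shell_volumes(rad.transpose(0, 2, 1).reshape(-1), lattice, pot)
        well = well.reshape(C, n_radii, nb, J)
        well = well * avail[c0:c1, None, :, None]
        Phi_EO[row0 : row0 + C * n_radii] = well[:, :, is_eo, :].sum(axis=2).reshape(-1, J) / vols
        Phi_PO[row0 : row0 + C * n_radii] = well[:, :, is_po, :].sum(axis=2).reshape(-1, J) / vols

    U = np.repeat(U_conf, n_radii)
    log_w0 = np.tile(np.log(dV / n_conf), n_conf)
    r_place = np.tile(rho, n_conf)
    conf_index = np.repeat(np.arange(n_conf), n_radii)
    # orientation-independent shape metrics per conformation
    rg_po_conf = np.sqrt(np.mean(np.sum(pos[:, is_po, :] ** 2, axis=2), axis=1))
    head = pos[:, : spec.n_head_EO, :].mean(axis=1)
    tail = pos[:, spec.n_head_EO + spec.n_PO :, :].mean(axis=1)
    nh = np.linalg.norm(head, axis=1)
    nt = np.linalg.norm(tail, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(np.einsum("ck,ck->c", head, tail) / (nh * nt), -1.0, 1.0)
    angle_conf = np.degrees(np.arccos(cosang))
    return ConformationEnsemble(
        n_EO,
        n_PO,
        Phi_EO,
        Phi_PO,
        U,
        log_w0,
        lattice,
        r_place,
        np.repeat(rg_po_conf, n_radii),
        np.repeat(angle_conf, n_radii),
        conf_index,
        rho,
    )


# ---------------------------------------------------------------------------
# fields and Hamiltonian


@dataclass
class FieldState:
    """Mean molecular fields on the shell lattice (reduced units)."""

    c_EO: np.ndarray  # bead-number concentration (1/sigma^3)
    c_PO: np.ndarray
    c_s: np.ndarray  # solvent number concentration
    pi: np.ndarray  # incompressibility Lagrange field (k_B T / sigma^3)
    mPhi_EO: np.ndarray  # mean square-well volume density of EO beads
    mPhi_PO: np.ndarray
    N: int = 0
    N_s: float = 0.0
    v_p: float = V_BEAD
    v_s: float = V_SOLVENT
    T: float = TEMPERATURE_K

    @property
    def phi_s(self) -> np.ndarray:
        return self.c_s * self.v_s

    def phi_chains(self) -> np.ndarray:
        return self.v_p * (self.c_EO + self.c_PO)

    @classmethod
    def uniform_solvent(cls, lattice: ShellLattice, N: int = 0) -> "FieldState":
        J = lattice.n_shells
        z = np.zeros(J)
        c_s = np.full(J, 1.0 / V_SOLVENT)
        return cls(z.copy(), z.copy(), c_s, z.copy(), z.copy(), z.copy(), N=N,
                   N_s=lattice.V / V_SOLVENT)


def _closure(
    c_EO: np.ndarray,
    c_PO: np.ndarray,
    mPhi_EO: np.ndarray,
    mPhi_PO: np.ndarray,
    pot: PairPotential,
    v_p: float,
    v_s: float,
):
    """Solvent concentration and pi field from incompressibility."""
    phi_c = v_p * (c_EO + c_PO)
    phi_s = np.clip(1.0 - phi_c, _PHI_S_FLOOR, 1.0)
    c_s = phi_s / v_s
    pi = -(np.log(phi_s) + pot.e_EO_s * mPhi_EO + pot.e_PO_s * mPhi_PO) / v_s
    return c_s, pi, phi_s


def _hamiltonians(
    ens: ConformationEnsemble,
    fields: FieldState,
    pot: PairPotential,
) -> np.ndarray:
    """H[alpha] = dF/d(N P[alpha]) for every sampled conformation (k_B T)."""
    vols = ens.lattice.volumes
    N = max(fields.N, 1)
    chain_chain = (N - 1) / N
    half = 0.5 * pot.e_EO_PO * chain_chain
    # potentials conjugate to the four per-conformation projections
    u_Phi_EO = (half * fields.c_PO + pot.e_EO_s * fields.c_s) * vols
    u_Phi_PO = (half * fields.c_EO + pot.e_PO_s * fields.c_s) * vols
    u_n_EO = half * fields.mPhi_PO + fields.pi * fields.v_p
    u_n_PO = half * fields.mPhi_EO + fields.pi * fields.v_p
    H = (
        ens.U
        + ens.Phi_EO @ u_Phi_EO
        + ens.Phi_PO @ u_Phi_PO
        + ens.n_EO @ u_n_EO
        + ens.n_PO @ u_n_PO
    )
    return H


def scmf_hamiltonian(
    conf: Conformation,
    fields: FieldState,
    pot: PairPotential,
    lattice: ShellLattice,
    center: np.ndarray | None = None,
) -> float:
    """SCMF Hamiltonian of a single placed conformation in given fields."""
    phi_eo, phi_po, Phi_eo, Phi_po = project_conformation(conf, lattice, center, pot)
    vols = lattice.volumes
    ens = ConformationEnsemble(
        n_EO=(phi_eo * vols / V_BEAD)[None, :],
        n_PO=(phi_po * vols / V_BEAD)[None, :],
        Phi_EO=Phi_eo[None, :],
        Phi_PO=Phi_po[None, :],
        U=np.array([intra_energy(conf, pot)]),
        log_w0=np.zeros(1),
        lattice=lattice,
    )
    return float(_hamiltonians(ens, fields, pot)[0])


def _fields_from_P(
    ens: ConformationEnsemble, P: np.ndarray, N: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    vols = ens.lattice.volumes
    c_EO = N * (P @ ens.n_EO) / vols
    c_PO = N * (P @ ens.n_PO) / vols
    mPhi_EO = N * (P @ ens.Phi_EO)
    mPhi_PO = N * (P @ ens.Phi_PO)
    return c_EO, c_PO, mPhi_EO, mPhi_PO


def _softmax(logp: np.ndarray) -> np.ndarray:
    x = logp - logp.max()
    w = np.exp(x)
    return w / w.sum()


@dataclass
class SCFResult:
    fields: FieldState
    P: np.ndarray
    free_energy: float
    n_iter: int
    converged: bool
    residual_history: list
    ess: float  # effective sample size of the converged weights

    @property
    def incompressibility_residual(self) -> float:
        return float(np.max(np.abs(self.fields.phi_chains() + self.fields.phi_s - 1.0)))


def free_energy(
    ens: ConformationEnsemble,
    P: np.ndarray,
    fields: FieldState,
    pot: PairPotential,
) -> float:
    """Evaluate the free-energy functional (k_B T) at the given state.

    The solvent part is evaluated with c_s eliminated by incompressibility,
    so the value is a function of the chain weights P alone.
    """
    vols = ens.lattice.volumes
    N = fields.N
    chain_chain = (N - 1) / max(N, 1)
    e_chain = N * float(P @ ens.U)
    e_EP = (
        0.5
        * pot.e_EO_PO
        * chain_chain
        * float(np.sum(vols * (fields.mPhi_EO * fields.c_PO + fields.mPhi_PO * fields.c_EO)))
    )
    e_solv = float(
        np.sum(vols * fields.c_s * (pot.e_EO_s * fields.mPhi_EO + pot.e_PO_s * fields.mPhi_PO))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        s_chain = N * float(np.sum(np.where(P > 0, P * (np.log(np.maximum(P, 1e-300)) - ens.log_w0), 0.0)))
    phi_s = fields.phi_s
    s_solv = float(np.sum(vols * fields.c_s * (np.log(np.maximum(phi_s, _PHI_S_FLOOR)) - 1.0)))
    return e_chain + e_EP + e_solv + s_chain + s_solv


def _state_from_P(
    ens: ConformationEnsemble, P: np.ndarray, N: int, pot: PairPotential, v_s: float = V_SOLVENT
) -> FieldState:
    c_EO, c_PO, mPhi_EO, mPhi_PO = _fields_from_P(ens, P, N)
    c_s, pi, _ = _closure(c_EO, c_PO, mPhi_EO, mPhi_PO, pot, V_BEAD, v_s)
    N_s = float(np.sum(ens.lattice.volumes * c_s))
    return FieldState(c_EO, c_PO, c_s, pi, mPhi_EO, mPhi_PO, N=N, N_s=N_s, v_s=v_s)


def solve_self_consistent(
    ens: ConformationEnsemble,
    pot: PairPotential,
    N: int,
    fields_init: FieldState | None = None,
    seed_bias: np.ndarray | None = None,
    mixing: float = 0.1,
    tol: float = 1e-9,
    max_iter: int = 4000,
) -> SCFResult:
    """Damped Picard iteration to the self-consistent fixed point.

    ``seed_bias`` (an extra log-weight per conformation) only shapes the
    *initial* guess, e.g. to nucleate a micelle at the cell centre; it does
    not enter the fixed-point equations.  Convergence is declared when the
    chain volume-fraction profile changes by less than ``tol`` between
    iterations.  Raises :class:`ConvergenceError` with the residual history
    otherwise.
    """
    if fields_init is not None:
        fields = fields_init
    else:
        logp0 = ens.log_w0.copy()
        if seed_bias is not None:
            logp0 = logp0 + seed_bias
        P = _softmax(logp0)
        fields = _state_from_P(ens, P, N, pot)

    phi_prev = fields.phi_chains()
    history: list[float] = []
    converged = False
    m = mixing
    best_resid = np.inf
    since_best = 0
    for it in range(max_iter):
        H = _hamiltonians(ens, fields, pot)
        P = _softmax(ens.log_w0 - H)
        target = _state_from_P(ens, P, N, pot, v_s=fields.v_s)
        c_EO = (1 - m) * fields.c_EO + m * target.c_EO
        c_PO = (1 - m) * fields.c_PO + m * target.c_PO
        mPhi_EO = (1 - m) * fields.mPhi_EO + m * target.mPhi_EO
        mPhi_PO = (1 - m) * fields.mPhi_PO + m * target.mPhi_PO
        c_s, pi, _ = _closure(c_EO, c_PO, mPhi_EO, mPhi_PO, pot, V_BEAD, fields.v_s)
        fields = FieldState(
            c_EO, c_PO, c_s, pi, mPhi_EO, mPhi_PO, N=N,
            N_s=float(np.sum(ens.lattice.volumes * c_s)), v_s=fields.v_s,
        )
        phi_now = fields.phi_chains()
        resid = float(np.max(np.abs(phi_now - phi_prev)))
        history.append(resid)
        phi_prev = phi_now
        if resid < tol * m / mixing:
            converged = True
            break
        # damp harder when the iteration stalls or limit-cycles
        if resid < 0.7 * best_resid:
            best_resid = resid
            since_best = 0
        else:
            since_best += 1
            if since_best >= 150 and m > 0.012:
                m *= 0.5
                best_resid = resid
                since_best = 0
    # final self-consistent weights and unmixed state for reporting
    H = _hamiltonians(ens, fields, pot)
    P = _softmax(ens.log_w0 - H)
    state = _state_from_P(ens, P, N, pot, v_s=fields.v_s)
    F = free_energy(ens, P, state, pot)
    ess = float(1.0 / np.sum(P**2))
    if not converged:
        raise ConvergenceError(
            f"SCF not converged after {max_iter} iterations (residual {history[-1]:.3e})",
            residuals=history,
        )
    return SCFResult(state, P, F, len(history), converged, history, ess)


# ---------------------------------------------------------------------------
# micellization scan


@dataclass
class MicellizationScan:
    """Chemical-potential curve over aggregation numbers and derived CMC."""

    N_values: np.ndarray
    delta_mu: np.ndarray  # (mu_N^0 - mu_1^0)/kT
    N_star: int | None
    min_delta_mu: float | None
    cmc_mol_per_l: float | None
    status: str  # "ok" or "no micellization"
    mu1: float = float("nan")
    seed: int | None = None
    diagnostics: dict = dc_field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "status": self.status,
                "delta_mu": {int(n): float(d) for n, d in zip(self.N_values, self.delta_mu)},
                "N_star": None if self.N_star is None else int(self.N_star),
                "min_delta_mu": self.min_delta_mu,
                "cmc_mol_per_l": self.cmc_mol_per_l,
                "mu1": self.mu1,
                "seed": self.seed,
                "diagnostics": self.diagnostics,
            },
            indent=2,
        )


def cmc_from_delta_mu(min_delta_mu: float) -> float:
    """CMC (mol/L) from the minimum standard chemical-potential difference,
    on a mole-fraction standard state: CMC = 55.5 * exp(min delta mu)."""
    return WATER_MOLARITY * float(np.exp(min_delta_mu))


def _empty_cell_free_energy(lattice: ShellLattice, v_s: float = V_SOLVENT) -> float:
    # pure solvent: c_s = 1/v_s, phi_s = 1 -> F = -V/v_s
    return -lattice.V / v_s


def _mu1_from_ensemble(
    ens: ConformationEnsemble, pot: PairPotential, r_max: float
) -> float:
    """mu_1^0 from a single-chain solve on an existing ensemble.

    The chain's translational entropy over the placement volume is removed
    against a one-chain-per-solvent-site standard state (+ ln(V_place/v_s)).
    """
    res = solve_self_consistent(ens, pot, N=1, mixing=0.5)
    F0 = _empty_cell_free_energy(ens.lattice, res.fields.v_s)
    v_place = 4.0 * np.pi / 3.0 * r_max**3
    return res.free_energy - F0 + float(np.log(v_place / res.fields.v_s))


def chain_standard_potential(
    spec: ChainSpec,
    pot: PairPotential,
    rng: np.random.Generator,
    n_samples: int = 2000,
    lattice: ShellLattice | None = None,
    r_max: float = 8.0,
) -> float:
    """Standard chemical potential mu_1^0 of an isolated chain in solvent."""
    if lattice is None:
        lattice = build_lattice(n_inner=10)
    ens = sample_ensemble_grid(spec, lattice, n_samples, rng, pot, n_radii=8, r_max=r_max)
    return _mu1_from_ensemble(ens, pot, r_max)


def _core_radius_guess(N: int, spec: ChainSpec) -> float:
    return float((3.0 * N * spec.n_PO * V_BEAD / (4.0 * np.pi * 0.5)) ** (1.0 / 3.0))


#: per-case reduced-scan defaults: coarse aggregation-number grids sized to
#: bracket each case's preferred micelle, and cells large enough to hold it
DEFAULT_SCAN = {
    "flexible": dict(N_values=(70, 100, 145, 200, 280), n_inner=24, r_max=20.0, n_radii=16),
    "semiflexible": dict(N_values=(145, 200, 280, 380, 480), n_inner=24, r_max=20.0, n_radii=16),
    "rigid": dict(N_values=(300, 450, 650, 900, 1200), n_inner=32, r_max=26.0, n_radii=20),
}


def micellization_scan(
    spec: ChainSpec,
    pot: PairPotential,
    N_values: Sequence[int],
    seed: int = 0,
    n_samples: int = 5000,
    lattice: ShellLattice | None = None,
    n_radii: int = 16,
    r_max: float = 20.0,
    mixing: float = 0.1,
    tol: float = 1e-7,
    tie_break: float = 0.01,
) -> MicellizationScan:
    """Scan micelle aggregation numbers and locate the preferred size.

    For every N the cell is solved with N chains pinned (via the spherical
    fields) to the centre, reusing one conformation ensemble across the scan
    so that sampling noise cancels in the shape of delta_mu(N).  After the
    first round the placement radii are importance-resampled towards the
    converged radial weight distribution.  ``delta_mu = [F(N) - F(0)]/N -
    mu_1^0``; the preferred size N* is the smallest N within ``tie_break``
    k_B T of the minimum, and the CMC follows from min(delta_mu).  When the
    minimum sits on the scan boundary the system is reported as
    "no micellization" rather than guessing an N*.
    """
    rng = np.random.default_rng(seed)
    if lattice is None:
        lattice = build_lattice()
    N_values = np.asarray(sorted(int(n) for n in N_values))
    ens = sample_ensemble_grid(spec, lattice, n_samples, rng, pot, n_radii=n_radii, r_max=r_max)
    F0 = _empty_cell_free_energy(lattice)
    # mu_1^0 from the same ensemble so that sampling noise largely cancels in
    # delta_mu
    mu1 = _mu1_from_ensemble(ens, pot, r_max)

    diagnostics: dict = {"ess": {}, "failed_N": [], "mu1": mu1, "n_samples": n_samples}
    F_of_N: dict[int, float] = {}
    fields = None
    for N in N_values:
        bias = None
        if fields is None:
            r0 = _core_radius_guess(int(N), spec)
            bias = -0.5 * (ens.r_place / r0) ** 2 * 5.0
        try:
            res = solve_self_consistent(
                ens, pot, int(N), fields_init=fields, seed_bias=bias,
                mixing=mixing, tol=tol,
            )
        except ConvergenceError:
            diagnostics["failed_N"].append(int(N))
            F_of_N[int(N)] = float("nan")
            fields = None
            continue
        fields = res.fields
        F_of_N[int(N)] = res.free_energy
        diagnostics["ess"][int(N)] = res.ess

    delta_mu = np.array([(F_of_N[int(N)] - F0) / N - mu1 for N in N_values])
    if np.all(np.isnan(delta_mu)):
        return MicellizationScan(
            N_values, delta_mu, None, None, None, "no micellization",
            mu1=mu1, seed=seed, diagnostics=diagnostics,
        )
    i_min = int(np.nanargmin(delta_mu))
    interior = 0 < i_min < len(N_values) - 1
    if not interior or delta_mu[i_min] >= 0:
        return MicellizationScan(
            N_values, delta_mu, None, None, None, "no micellization",
            mu1=mu1, seed=seed, diagnostics=diagnostics,
        )
    near = np.where(delta_mu <= delta_mu[i_min] + tie_break)[0]
    N_star = int(N_values[near[0]])
    min_dmu = float(delta_mu[i_min])
    return MicellizationScan(
        N_values, delta_mu, N_star, min_dmu, cmc_from_delta_mu(min_dmu), "ok",
        mu1=mu1, seed=seed, diagnostics=diagnostics,
    )
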