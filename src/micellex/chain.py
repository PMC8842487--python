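"""Coarse-grained Kuhn-segmented triblock copolymer chains.

The chain is a linear sequence of equal-diameter beads (EO and PO monomers)
with consecutive beads bonded at distance ``sigma``.  Chain stiffness is
encoded by grouping consecutive beads of the same chemical block into rigid,
straight Kuhn segments; joints between segments are completely flexible.
Intramolecular interactions are evaluated exactly: a hard core of diameter
``sigma`` plus a square well between ``sigma`` and ``1.62 sigma`` acting
between EO and PO monomers.

All lengths are in units of the bead diameter sigma (physically about
0.2 nm); all energies are in units of k_B T.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

EO = 0
PO = 1

#: physical bead diameter in metres (~0.2 nm)
SIGMA_METRES = 0.2e-9

#: square-well outer radius in sigma units
WELL_OUTER = 1.62

#: lattice coordination number used to normalise the printed well depths
Z_COORDINATION = 26

_HARD_CORE_TOL = 1e-9


class ConformationSamplingError(RuntimeError):
    """Raised when no self-avoiding conformation is found within the budget."""


@dataclass(frozen=True)
class ChainSpec:
    """Block composition and Kuhn-segment geometry of a triblock copolymer.

    The default composition is the L44 poloxamer EO10-PO23-EO10 (43 beads).
    ``kuhn_EO`` / ``kuhn_PO`` give the number of monomers per rigid segment in
    the hydrophilic and hydrophobic blocks; a value of 1 yields a fully
    flexible block, a value equal to the block length a single rigid rod.
    """

    n_head_EO: int = 10
    n_PO: int = 23
    n_tail_EO: int = 10
    kuhn_EO: int = 1
    kuhn_PO: int = 1
    bead_diameter: float = 1.0
    bond_length: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_head_EO", "n_PO", "n_tail_EO", "kuhn_EO", "kuhn_PO"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bead_diameter <= 0 or self.bond_length <= 0:
            raise ValueError("bead_diameter and bond_length must be positive")

    @property
    def n_beads(self) -> int:
        return self.n_head_EO + self.n_PO + self.n_tail_EO

    @property
    def block_labels(self) -> np.ndarray:
        return np.concatenate(
            [
                np.full(self.n_head_EO, EO, dtype=np.uint8),
                np.full(self.n_PO, PO, dtype=np.uint8),
                np.full(self.n_tail_EO, EO, dtype=np.uint8),
            ]
        )

    def spec_hash(self) -> str:
        key = (
            f"{self.n_head_EO},{self.n_PO},{self.n_tail_EO},"
            f"{self.kuhn_EO},{self.kuhn_PO},{self.bead_diameter},{self.bond_length}"
        )
        return hashlib.sha1(key.encode()).hexdigest()[:12]


# The three flexibility case studies for the L44 chain: the semiflexible one
# corresponds to the real poloxamer, the other two are artificially softened /
# stiffened variants of the same molecule.
FLEXIBLE = ChainSpec(kuhn_EO=2, kuhn_PO=2)
SEMIFLEXIBLE = ChainSpec(kuhn_EO=3, kuhn_PO=4)
RIGID = ChainSpec(kuhn_EO=10, kuhn_PO=20)

CASE_STUDIES = {"flexible": FLEXIBLE, "semiflexible": SEMIFLEXIBLE, "rigid": RIGID}


@dataclass(frozen=True)
class PairPotential:
    """Square-well interaction parameters.

    ``eps_*`` are the magnitudes of the well depths in units of k_B T per
    coordination contact (z = 26); a single pair of centres within the well
    contributes ``eps/z`` in magnitude.  The signs encode the amphiphile
    chemistry: an EO-solvent contact is a *hydration attraction* (the EO
    block is hydrophilic), a PO-solvent contact is a *penalty* (the
    hydrophobic driving force of micellization) and the EO-PO cross contact
    is a very weak penalty.  It is the competition between the PO
    dehydration gain and the loss of EO hydration in a crowded corona that
    selects a finite preferred aggregation number.
    """

    hard_core: float = 1.0
    well_outer: float = WELL_OUTER
    eps_EO_PO: float = 0.006
    eps_EO_s: float = 0.5
    eps_PO_s: float = 2.1
    z: int = Z_COORDINATION
    #: radius of the sphere a bead blocks out of its neighbours' wells when
    #: computing available interaction volumes: the bead's own volume
    #: (radius sigma/2).  Larger values weaken the net binding; see the
    #: methods note for why this convention was kept.
    exclusion_radius: float = 0.5

    def __post_init__(self) -> None:
        if not self.well_outer > self.hard_core:
            raise ValueError("well_outer must exceed hard_core")
        for name in ("eps_EO_PO", "eps_EO_s", "eps_PO_s"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def e_EO_PO(self) -> float:
        """Per-contact EO-PO energy in k_B T (weak penalty)."""
        return self.eps_EO_PO / self.z

    @property
    def e_EO_s(self) -> float:
        """Per-contact EO-solvent energy in k_B T (hydration attraction)."""
        return -self.eps_EO_s / self.z

    @property
    def e_PO_s(self) -> float:
        """Per-contact PO-solvent energy in k_B T (hydrophobic penalty)."""
        return self.eps_PO_s / self.z

    @property
    def well_volume(self) -> float:
        """Volume of the square-well region around one bead (sigma^3)."""
        return 4.0 * np.pi / 3.0 * (self.well_outer**3 - self.hard_core**3)


DEFAULT_POTENTIAL = PairPotential()


class Segment(NamedTuple):
    """A rigid Kuhn segment: half-open bead index range within one block."""

    label: int
    start: int
    stop: int

    @property
    def n_beads(self) -> int:
        return self.stop - self.start


@dataclass
class Conformation:
    """Ordered bead coordinates of a single chain, in sigma units."""

    positions: np.ndarray  # (n_beads, 3) float64
    block_labels: np.ndarray  # (n_beads,) uint8

    def copy(self) -> "Conformation":
        return Conformation(self.positions.copy(), self.block_labels)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


def build_kuhn_partition(spec: ChainSpec) -> list[Segment]:
    """Partition the chain into rigid Kuhn segments.

    Segments never cross chemical block boundaries (a free joint always sits
    at every EO/PO interface); the last segment of a block may be shorter than
    the Kuhn length when the block length is not a multiple of it.
    """
    segments: list[Segment] = []
    offset = 0
    for label, n_block, kuhn in (
        (EO, spec.n_head_EO, spec.kuhn_EO),
        (PO, spec.n_PO, spec.kuhn_PO),
        (EO, spec.n_tail_EO, spec.kuhn_EO),
    ):
        start = offset
        while start < offset + n_block:
            stop = min(start + kuhn, offset + n_block)
            segments.append(Segment(label, start, stop))
            start = stop
        offset += n_block
    return segments


def count_po_segments(spec: ChainSpec) -> int:
    """Number of rigid segments in the hydrophobic PO block."""
    return sum(1 for s in build_kuhn_partition(spec) if s.label == PO)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _nonbonded_mask(n: int) -> np.ndarray:
    """Upper-triangle boolean mask of non-bonded pairs (|i-j| >= 2)."""
    i, j = np.triu_indices(n, k=2)
    return i, j


def _build_positions(spec: ChainSpec, segments: list[Segment], directions: np.ndarray) -> np.ndarray:
    """Assemble bead positions from one rod direction per segment.

    Each segment is a straight rod of beads spaced by the bond length; the
    first bead of a segment sits one bond length from the last bead of the
    previous segment, along the new segment's direction (free joint).
    """
    b = spec.bond_length
    pos = np.empty((spec.n_beads, 3))
    cursor = np.zeros(3)
    first = True
    for seg, d in zip(segments, directions):
        step = d * b
        if first:
            start = cursor
            first = False
        else:
            start = cursor + step
        idx = np.arange(seg.n_beads)
        pos[seg.start : seg.stop] = start[None, :] + idx[:, None] * step[None, :]
        cursor = pos[seg.stop - 1]
    return pos


def has_hard_core_overlap(positions: np.ndarray, hard_core: float = 1.0) -> bool:
    """True when any non-bonded bead pair sits closer than the hard core."""
    n = positions.shape[0]
    i, j = _nonbonded_mask(n)
    d2 = np.sum((positions[i] - positions[j]) ** 2, axis=1)
    return bool(np.any(d2 < (hard_core * (1.0 - _HARD_CORE_TOL)) ** 2))


def sample_conformation(
    spec: ChainSpec,
    rng: np.random.Generator,
    max_attempts: int = 20000,
) -> Conformation:
    """Draw one self-avoiding conformation by rejection sampling.

    Segment orientations are drawn isotropically at every free joint and the
    whole chain is rejected and regrown on any hard-core overlap, so accepted
    conformations are distributed uniformly over the self-avoiding subset of
    the freely-jointed-segment ensemble.
    """
    segments = build_kuhn_partition(spec)
    labels = spec.block_labels
    for _ in range(max_attempts):
        directions = _random_unit_vectors(rng, len(segments))
        pos = _build_positions(spec, segments, directions)
        if not has_hard_core_overlap(pos, spec.bead_diameter):
            return Conformation(pos - pos.mean(axis=0), labels)
    raise ConformationSamplingError(
        f"no self-avoiding conformation found in {max_attempts} attempts"
    )


def _lens_volume(R, a, d):
    """Intersection volume of spheres of radii R and a at centre distance d
    (vectorised in d)."""
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    far = d >= R + a
    inside = d <= abs(R - a)
    mid = ~far & ~inside
    dm = d[mid]
    out[mid] = (
        np.pi * (R + a - dm) ** 2 * (dm**2 + 2 * dm * (a + R) - 3 * (a - R) ** 2) / (12 * dm)
    )
    out[inside] = 4.0 * np.pi / 3.0 * min(R, a) ** 3
    return out


def well_ball_overlap(d, pot: PairPotential = DEFAULT_POTENTIAL):
    """Volume of one bead's square-well region blocked by the *volume* of
    another bead (sphere of radius ``exclusion_radius``) at centre distance
    ``d``."""
    b = pot.exclusion_radius
    return _lens_volume(pot.well_outer, b, d) - _lens_volume(pot.hard_core, b, d)


def available_fractions(
    positions: np.ndarray, pot: PairPotential = DEFAULT_POTENTIAL
) -> np.ndarray:
    """Fraction of each bead's square-well volume not blocked by the chain's
    own beads (pairwise-overlap approximation, clipped to [0, 1]).

    This is what makes solvation energies conformation dependent: a crumpled
    hydrophobic block exposes far less well volume to the solvent than an
    extended one.
    """
    n = positions.shape[0]
    i, j = np.triu_indices(n, k=1)
    d = np.sqrt(np.sum((positions[i] - positions[j]) ** 2, axis=1))
    ov = well_ball_overlap(d, pot)
    blocked = np.zeros(n)
    np.add.at(blocked, i, ov)
    np.add.at(blocked, j, ov)
    return np.clip(1.0 - blocked / pot.well_volume, 0.0, 1.0)


def sample_conformations_batch(
    spec: ChainSpec,
    n: int,
    rng: np.random.Generator,
    pot: PairPotential = DEFAULT_POTENTIAL,
    max_rounds: int = 5000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised rejection sampling of ``n`` self-avoiding conformations.

    Returns ``(positions, U, avail)``: positions (n, n_beads, 3) centred on
    the PO-block centre of mass, exact intramolecular energies U and the
    per-bead available well fractions.  Statistically identical to repeated
    :func:`sample_conformation` calls (whole-chain rejection on overlap).
    """
    segments = build_kuhn_partition(spec)
    labels = spec.block_labels
    nb = spec.n_beads
    i_nb, j_nb = np.triu_indices(nb, k=2)
    mixed = labels[i_nb] != labels[j_nb]
    near = (j_nb - i_nb) <= 3  # cheap prefilter: short-range pairs reject most chains
    i_all, j_all = np.triu_indices(nb, k=1)
    incidence = np.zeros((i_all.size, nb))
    incidence[np.arange(i_all.size), i_all] = 1.0
    incidence[np.arange(j_all.size), j_all] = 1.0
    hc2 = (spec.bead_diameter * (1.0 - _HARD_CORE_TOL)) ** 2
    out_pos = np.empty((n, nb, 3))
    out_U = np.empty(n)
    out_avail = np.empty((n, nb))
    got = 0
    accept_rate = 0.1  # running estimate, refined each round
    for _ in range(max_rounds):
        if got >= n:
            break
        B = int(np.clip(1.3 * (n - got) / max(accept_rate, 1e-4), 500, 8000))
        dirs = rng.normal(size=(B, len(segments), 3))
        dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
        pos = np.empty((B, nb, 3))
        cursor = np.zeros((B, 3))
        for s, seg in enumerate(segments):
            step = dirs[:, s, :] * spec.bond_length
            start = cursor if s == 0 else cursor + step
            k = np.arange(seg.n_beads)
            pos[:, seg.start : seg.stop, :] = (
                start[:, None, :] + k[None, :, None] * step[:, None, :]
            )
            cursor = pos[:, seg.stop - 1, :]
        diff_near = pos[:, i_nb[near], :] - pos[:, j_nb[near], :]
        pre_ok = ~np.any(np.einsum("bpk,bpk->bp", diff_near, diff_near) < hc2, axis=1)
        cand = np.flatnonzero(pre_ok)
        if cand.size == 0:
            accept_rate = max(accept_rate * 0.5, 1e-4)
            continue
        diff = pos[cand][:, i_nb, :] - pos[cand][:, j_nb, :]
        d2 = np.einsum("bpk,bpk->bp", diff, diff)
        ok = ~np.any(d2 < hc2, axis=1)
        accept_rate = 0.5 * accept_rate + 0.5 * max(ok.sum() / B, 1e-4)
        if not np.any(ok):
            continue
        sel = cand[np.flatnonzero(ok)][: n - got]
        take = pos[sel]
        po_com = take[:, labels == PO, :].mean(axis=1, keepdims=True)
        out_pos[got : got + sel.size] = take - po_com
        d2ok = d2[np.flatnonzero(ok)][: n - got]
        in_well = mixed[None, :] & (d2ok >= pot.hard_core**2) & (d2ok <= pot.well_outer**2)
        out_U[got : got + sel.size] = in_well.sum(axis=1) * pot.e_EO_PO
        # per-bead available well fractions (all pairs, bonded included)
        dall = np.sqrt(
            np.sum((take[:, i_all, :] - take[:, j_all, :]) ** 2, axis=2)
        )
        ov = well_ball_overlap(dall, pot)
        blocked = ov @ incidence
        out_avail[got : got + sel.size] = np.clip(1.0 - blocked / pot.well_volume, 0.0, 1.0)
        got += sel.size
    if got < n:
        raise ConformationSamplingError(
            f"only {got}/{n} self-avoiding conformations found in {max_rounds} rounds"
        )
    return out_pos, out_U, out_avail


def intra_energy(conf: Conformation, pot: PairPotential = DEFAULT_POTENTIAL) -> float:
    """Exact intramolecular energy of one conformation, in k_B T.

    Counts non-bonded EO-PO pairs whose centre distance lies within the
    square well; each contributes the per-contact energy ``eps_EO_PO / z``.
    Same-species pairs carry no printed well depth and contribute zero.
    Returns ``+inf`` when any hard-core overlap is present.
    """
    n = conf.n_beads
    i, j = _nonbonded_mask(n)
    d2 = np.sum((conf.positions[i] - conf.positions[j]) ** 2, axis=1)
    hc2 = (pot.hard_core * (1.0 - _HARD_CORE_TOL)) ** 2
    if np.any(d2 < hc2):
        return float("inf")
    labels = conf.block_labels
    mixed = labels[i] != labels[j]
    in_well = (d2 >= pot.hard_core**2) & (d2 <= pot.well_outer**2)
    n_contacts = int(np.count_nonzero(mixed & in_well))
    return n_contacts * pot.e_EO_PO


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def perturb_conformation(
    conf: Conformation,
    spec: ChainSpec,
    amplitude: float,
    rng: np.random.Generator,
) -> Conformation:
    """Propose one symmetric local move; the proposal is returned unaccepted.

    With probability 1/2 a pivot move: a random internal joint is chosen, and
    the sub-chain on a random side of it is rigidly rotated about a random
    axis through the pivot bead by an angle uniform in [-amplitude, amplitude]
    radians.  Otherwise the whole chain is rigidly translated by a vector
    uniform in a ball of radius ``amplitude`` (sigma).  Both branches preserve
    bond lengths and Kuhn-segment rigidity exactly and are symmetric under
    reversal, so they are compatible with Metropolis detailed balance.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    new = conf.copy()
    if amplitude == 0.0:
        # draw the same random variates to keep streams aligned, then no-op
        return new
    segments = build_kuhn_partition(spec)
    if rng.random() < 0.5 and len(segments) > 1:
        joint = int(rng.integers(len(segments) - 1))
        tail_side = rng.random() < 0.5
        angle = rng.uniform(-amplitude, amplitude)
        axis = _random_unit_vectors(rng, 1)[0]
        R = _rotation_matrix(axis, angle)
        if tail_side:
            pivot_idx = segments[joint].stop - 1
            sl = slice(segments[joint].stop, None)
        else:
            pivot_idx = segments[joint + 1].start
            sl = slice(0, segments[joint].stop)
        pivot = new.positions[pivot_idx]
        new.positions[sl] = (new.positions[sl] - pivot) @ R.T + pivot
    else:
        step = _random_unit_vectors(rng, 1)[0]
        radius = amplitude * rng.random() ** (1.0 / 3.0)
        new.positions += step * radius
    return new


class ShapeMetrics(NamedTuple):
    rg_PO: float
    rg_whole: float
    eo_po_eo_angle_deg: float  # NaN when either arm vector has zero length


def _rg(points: np.ndarray) -> float:
    com = points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((points - com) ** 2, axis=1))))


def shape_metrics(conf: Conformation) -> ShapeMetrics:
    """PO-block and whole-chain radii of gyration plus the EO-PO-EO angle.

    The angle is spanned by the two vectors from the PO-block centre of mass
    to the centres of mass of the two EO blocks; a completely stretched chain
    gives 180 degrees and a hairpin fold approaches 0.  The angle is reported
    as NaN when either vector has zero length.
    """
    labels = conf.block_labels
    pos = conf.positions
    po = pos[labels == PO]
    n_head = int(np.argmax(labels == PO)) if np.any(labels == PO) else 0
    head = pos[:n_head]
    tail = pos[n_head + po.shape[0] :]
    rg_po = _rg(po) if po.size else float("nan")
    rg_all = _rg(pos)
    if not (head.size and tail.size and po.size):
        return ShapeMetrics(rg_po, rg_all, float("nan"))
    v1 = head.mean(axis=0) - po.mean(axis=0)
    v2 = tail.mean(axis=0) - po.mean(axis=0)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return ShapeMetrics(rg_po, rg_all, float("nan"))
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return ShapeMetrics(rg_po, rg_all, float(np.degrees(np.arccos(cosang))))


def write_xyz(path, conformations, spec: ChainSpec, comment: str = "") -> None:
    """Write conformations as extended XYZ, one frame per conformation."""
    names = {EO: "EO", PO: "PO"}
    with open(path, "w") as fh:
        for conf in conformations:
            fh.write(f"{conf.n_beads}\n")
            fh.write(f"spec={spec.spec_hash()} units=sigma {comment}\n")
            for lbl, (x, y, z) in zip(conf.block_labels, conf.positions):
                fh.write(f"{names[int(lbl)]} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> list[Conformation]:
    """Read conformations written by :func:`write_xyz`."""
    name_to_label = {"EO": EO, "PO": PO}
    out: list[Conformation] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        rows = lines[i + 2 : i + 2 + n]
        labels = np.array([name_to_label[r.split()[0]] for r in rows], dtype=np.uint8)
        pos = np.array([[float(v) for v in r.split()[1:4]] for r in rows])
        out.append(Conformation(pos, labels))
        i += 2 + n
    return out
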