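"""Chain model: Kuhn partitioning, self-avoiding sampling, exact energies,
move symmetry and shape metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micellex.chain import (
    EO,
    PO,
    ChainSpec,
    Conformation,
    FLEXIBLE,
    RIGID,
    SEMIFLEXIBLE,
    PairPotential,
    available_fractions,
    build_kuhn_partition,
    count_po_segments,
    intra_energy,
    perturb_conformation,
    read_xyz,
    sample_conformation,
    sample_conformations_batch,
    shape_metrics,
    well_ball_overlap,
    write_xyz,
)

POT = PairPotential()


class TestKuhnPartition:
    @pytest.mark.parametrize(
        "spec,expected_po_segments",
        [
            (SEMIFLEXIBLE, 6),  # ceil(23/4)
            (RIGID, 2),  # ceil(23/20)
            (FLEXIBLE, 12),  # ceil(23/2)
        ],
    )
    def test_po_segment_counts(self, spec, expected_po_segments):
        assert count_po_segments(spec) == expected_po_segments

    def test_eo_block_single_segment_when_kuhn_matches_block(self):
        spec = ChainSpec(kuhn_EO=10, kuhn_PO=4)
        segs = [s for s in build_kuhn_partition(spec) if s.label == EO]
        assert len(segs) == 2  # one rigid segment per EO block
        assert all(s.n_beads == 10 for s in segs)

    @given(
        n_head=st.integers(1, 12),
        n_po=st.integers(1, 25),
        n_tail=st.integers(1, 12),
        k_eo=st.integers(1, 12),
        k_po=st.integers(1, 25),
    )
    @settings(max_examples=60, deadline=None)
    def test_partition_tiles_chain_within_blocks(self, n_head, n_po, n_tail, k_eo, k_po):
        spec = ChainSpec(n_head, n_po, n_tail, k_eo, k_po)
        segs = build_kuhn_partition(spec)
        # segments tile [0, n_beads) without gaps or overlap
        assert segs[0].start == 0 and segs[-1].stop == spec.n_beads
        for a, b in zip(segs, segs[1:]):
            assert a.stop == b.start
        # no segment crosses a chemical block boundary
        labels = spec.block_labels
        for s in segs:
            assert len(set(labels[s.start : s.stop].tolist())) == 1
        assert sum(1 for s in segs if s.label == PO) == int(np.ceil(n_po / k_po))


class TestSampling:
    def test_seeded_reproducibility(self):
        c1 = sample_conformation(SEMIFLEXIBLE, np.random.default_rng(7))
        c2 = sample_conformation(SEMIFLEXIBLE, np.random.default_rng(7))
        np.testing.assert_array_equal(c1.positions, c2.positions)

    def test_invariants_bond_lengths_and_hard_core(self, rng):
        conf = sample_conformation(SEMIFLEXIBLE, rng)
        bonds = np.linalg.norm(np.diff(conf.positions, axis=0), axis=1)
        np.testing.assert_allclose(bonds, 1.0, atol=1e-9)
        n = conf.n_beads
        i, j = np.triu_indices(n, k=2)
        d = np.linalg.norm(conf.positions[i] - conf.positions[j], axis=1)
        assert d.min() >= 1.0 - 1e-9

    def test_batch_matches_invariants_and_energy(self, rng):
        pos, U, avail = sample_conformations_batch(SEMIFLEXIBLE, 50, rng)
        labels = SEMIFLEXIBLE.block_labels
        for k in range(0, 50, 10):
            conf = Conformation(pos[k], labels)
            assert np.isfinite(intra_energy(conf, POT))
            assert intra_energy(conf, POT) == pytest.approx(U[k], abs=1e-12)
        assert np.all((avail > 0) & (avail <= 1))

    def test_excluded_volume_swelling_vs_ideal_chain(self, rng):
        # short fully flexible chain: self-avoidance swells the coil beyond
        # the freely jointed value <R_ee^2> = (n-1) b^2
        spec = ChainSpec(2, 6, 2, kuhn_EO=1, kuhn_PO=1)
        pos, _, _ = sample_conformations_batch(spec, 10000, rng)
        r2 = np.sum((pos[:, -1, :] - pos[:, 0, :]) ** 2, axis=1)
        ideal = (spec.n_beads - 1) * 1.0
        assert r2.mean() > ideal * 1.05


class TestIntraEnergy:
    def _conf(self, positions, labels):
        return Conformation(np.asarray(positions, dtype=float), np.asarray(labels, dtype=np.uint8))

    def test_single_contact(self):
        # EO bead and PO bead, non-bonded, at 1.3 sigma: exactly one contact
        conf = self._conf(
            [[0, 0, 0], [1.0, 0, 0], [0.0, 1.3, 0]],
            [EO, EO, PO],
        )
        d02 = np.linalg.norm(conf.positions[2] - conf.positions[0])
        assert 1.0 <= d02 <= 1.62  # the only non-bonded pair
        assert intra_energy(conf, POT) == pytest.approx(POT.e_EO_PO)

    def test_straight_rod_has_no_contacts(self):
        pos = np.zeros((10, 3))
        pos[:, 0] = np.arange(10)
        labels = [EO] * 3 + [PO] * 4 + [EO] * 3
        assert intra_energy(self._conf(pos, labels), POT) == 0.0

    def test_overlap_flags_infinite_energy(self):
        conf = self._conf([[0, 0, 0], [1, 0, 0], [0.4, 0.1, 0]], [EO, PO, EO])
        assert intra_energy(conf, POT) == np.inf

    def test_brute_force_oracle(self, rng):
        # O(n^2) pure-python double loop as the independent reference
        for _ in range(100):
            conf = sample_conformation(SEMIFLEXIBLE, rng)
            e = 0.0
            n = conf.n_beads
            for i in range(n):
                for j in range(i + 2, n):
                    d = float(np.linalg.norm(conf.positions[i] - conf.positions[j]))
                    if 1.0 <= d <= 1.62 and conf.block_labels[i] != conf.block_labels[j]:
                        e += POT.e_EO_PO
            assert intra_energy(conf, POT) == pytest.approx(e, abs=1e-12)


class TestPerturbation:
    def test_segment_rigidity_preserved(self, rng):
        conf = sample_conformation(RIGID, rng)
        segs = build_kuhn_partition(RIGID)
        new = perturb_conformation(conf, RIGID, amplitude=0.8, rng=rng)
        for s in segs:
            p0 = conf.positions[s.start : s.stop]
            p1 = new.positions[s.start : s.stop]
            i, j = np.triu_indices(s.n_beads, k=1)
            d0 = np.linalg.norm(p0[i] - p0[j], axis=1)
            d1 = np.linalg.norm(p1[i] - p1[j], axis=1)
            np.testing.assert_allclose(d0, d1, atol=1e-9)
        bonds = np.linalg.norm(np.diff(new.positions, axis=0), axis=1)
        np.testing.assert_allclose(bonds, 1.0, atol=1e-9)

    def test_zero_amplitude_is_identity(self, rng):
        conf = sample_conformation(SEMIFLEXIBLE, rng)
        new = perturb_conformation(conf, SEMIFLEXIBLE, amplitude=0.0, rng=rng)
        np.testing.assert_array_equal(conf.positions, new.positions)

    def test_proposal_symmetry_zero_mean_com_displacement(self, rng):
        conf = sample_conformation(SEMIFLEXIBLE, rng)
        n = 4000
        disp = np.zeros(3)
        d2 = 0.0
        for _ in range(n):
            new = perturb_conformation(conf, SEMIFLEXIBLE, amplitude=0.5, rng=rng)
            v = new.positions.mean(axis=0) - conf.positions.mean(axis=0)
            disp += v
            d2 += float(v @ v)
        mean = disp / n
        sigma = np.sqrt(d2 / n / 3.0)  # per-component spread
        assert np.all(np.abs(mean) < 4.0 * sigma / np.sqrt(n))


class TestShapeMetrics:
    def test_stretched_chain_angle_180(self):
        pos = np.zeros((43, 3))
        pos[:, 0] = np.arange(43)
        conf = Conformation(pos, SEMIFLEXIBLE.block_labels)
        assert shape_metrics(conf).eo_po_eo_angle_deg == pytest.approx(180.0, abs=1e-6)

    def test_hairpin_angle_small(self):
        # both EO arms folded back to the same side of the PO block
        pos = np.zeros((43, 3))
        pos[:10, 0] = -np.arange(10, 0, -1) * 0.0
        pos[:10, 1] = np.arange(10, 0, -1)  # head arm up
        pos[10:33, 0] = np.arange(23) * 0.1  # PO block near origin
        pos[33:, 1] = np.arange(1, 11)  # tail arm up
        pos[33:, 0] = 2.3
        conf = Conformation(pos, SEMIFLEXIBLE.block_labels)
        assert shape_metrics(conf).eo_po_eo_angle_deg < 45.0

    def test_rod_rg_closed_form(self):
        n = 43
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n)
        conf = Conformation(pos, SEMIFLEXIBLE.block_labels)
        expected = np.sqrt((n**2 - 1) / 12.0)
        assert shape_metrics(conf).rg_whole == pytest.approx(expected, rel=1e-12)

    def test_mean_rg_ordering_with_stiffness(self, rng):
        means = {}
        for name, spec in (("flex", FLEXIBLE), ("semi", SEMIFLEXIBLE), ("rigid", RIGID)):
            pos, _, _ = sample_conformations_batch(spec, 1000, rng)
            com = pos.mean(axis=1, keepdims=True)
            means[name] = np.sqrt(np.mean(np.sum((pos - com) ** 2, axis=2), axis=1)).mean()
        assert means["flex"] < means["semi"] < means["rigid"]


class TestAvailability:
    def test_isolated_bead_fully_available(self):
        assert well_ball_overlap(np.array([3.0]), POT)[0] == 0.0

    def test_bonded_neighbours_reduce_availability(self):
        pos = np.zeros((3, 3))
        pos[:, 0] = [0.0, 1.0, 2.0]
        av = available_fractions(pos, POT)
        assert av[1] < av[0] < 1.0  # middle bead has two blockers
        assert np.all(av > 0.4)

    def test_crumpled_block_less_available_than_rod(self, rng):
        pos_rod = np.zeros((10, 3))
        pos_rod[:, 0] = np.arange(10)
        # dense zig-zag packing
        pos_zz = np.array(
            [[i % 2, i // 2, 0.3 * (i % 3)] for i in range(10)], dtype=float
        )
        pos_zz += rng.normal(0, 1e-3, pos_zz.shape)
        assert available_fractions(pos_zz, POT).mean() < available_fractions(pos_rod, POT).mean()


def test_xyz_round_trip(tmp_path, rng):
    confs = [sample_conformation(SEMIFLEXIBLE, rng) for _ in range(3)]
    path = tmp_path / "confs.xyz"
    write_xyz(path, confs, SEMIFLEXIBLE, comment="seed=1")
    back = read_xyz(path)
    assert len(back) == 3
    for a, b in zip(confs, back):
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-7)
        np.testing.assert_array_equal(a.block_labels, b.block_labels)
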