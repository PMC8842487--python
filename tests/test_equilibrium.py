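"""Shell lattice projections, SCMF Hamiltonian, self-consistent solve and
free energy, plus the micellization bookkeeping."""

import numpy as np
import pytest
from scipy.optimize import minimize

from micellex.chain import EO, PO, Conformation, PairPotential, SEMIFLEXIBLE
from micellex.equilibrium import (
    ConformationEnsemble,
    FieldState,
    LatticeError,
    ShellLattice,
    V_BEAD,
    build_lattice,
    cmc_from_delta_mu,
    free_energy,
    project_conformation,
    scmf_hamiltonian,
    solve_self_consistent,
)
from micellex.equilibrium import _hamiltonians, _softmax, _state_from_P

from conftest import make_toy_ensemble

POT = PairPotential()


class TestLattice:
    def test_volumes_tile_the_cell(self):
        lat = build_lattice(n_inner=10, reservoir_extent=20.0)
        assert lat.volumes.sum() == pytest.approx(lat.V, rel=1e-12)
        assert np.all(lat.volumes > 0)
        assert lat.n_shells == 11

    def test_shell_lookup(self):
        lat = build_lattice(n_inner=5, reservoir_extent=10.0)
        assert lat.shell_of(np.array([0.2]))[0] == 0
        assert lat.shell_of(np.array([4.9]))[0] == 4
        assert lat.shell_of(np.array([7.0]))[0] == 5  # reservoir shell
        with pytest.raises(LatticeError):
            lat.shell_of(np.array([100.0]))


class TestProjection:
    def _bead(self, r):
        return Conformation(np.array([[r, 0.0, 0.0]]), np.array([EO], dtype=np.uint8))

    def test_single_bead_volume_conservation(self):
        lat = build_lattice(n_inner=10, reservoir_extent=20.0)
        phi_eo, phi_po, Phi_eo, Phi_po = project_conformation(self._bead(3.3), lat)
        assert (phi_eo * lat.volumes).sum() == pytest.approx(V_BEAD, rel=1e-12)
        assert phi_po.sum() == 0.0
        # the bead's centre shell carries all of its volume
        assert phi_eo[3] > 0 and np.count_nonzero(phi_eo) == 1

    def test_well_volume_conservation(self):
        lat = build_lattice(n_inner=12, reservoir_extent=20.0)
        # well-separated beads, none near the lattice edge
        pos = np.array([[2.0, 0, 0], [7.0, 0, 0], [0, 0, 4.5]])
        conf = Conformation(pos, np.array([EO, PO, EO], dtype=np.uint8))
        _, _, Phi_eo, Phi_po = project_conformation(conf, lat)
        omega = POT.well_volume
        assert (Phi_eo * lat.volumes).sum() == pytest.approx(2 * omega, rel=1e-9)
        assert (Phi_po * lat.volumes).sum() == pytest.approx(omega, rel=1e-9)

    def test_self_exclusion_reduces_well_volume(self):
        lat = build_lattice(n_inner=12, reservoir_extent=20.0)
        pos = np.array([[4.0, 0, 0], [5.0, 0, 0], [6.0, 0, 0]])
        conf = Conformation(pos, np.array([EO, EO, EO], dtype=np.uint8))
        _, _, bare, _ = project_conformation(conf, lat, exclude_self=False)
        _, _, avail, _ = project_conformation(conf, lat, exclude_self=True)
        assert (avail * lat.volumes).sum() < (bare * lat.volumes).sum()

    def test_radial_translation_shifts_binning(self):
        lat = build_lattice(n_inner=10, reservoir_extent=20.0)
        a = project_conformation(self._bead(3.4), lat)[0]
        b = project_conformation(self._bead(4.4), lat)[0]
        assert np.argmax(a) + 1 == np.argmax(b)

    def test_out_of_cell_flagged(self):
        lat = ShellLattice(np.array([0.0, 2.0, 4.0]), 2.0)
        with pytest.raises(LatticeError):
            project_conformation(self._bead(3.9), lat)  # well exits the cell


class TestHamiltonian:
    def test_decoupled_limit_equals_intra_energy(self, rng):
        lat = build_lattice(n_inner=10, reservoir_extent=50.0)
        from micellex.chain import sample_conformation, intra_energy

        conf = sample_conformation(SEMIFLEXIBLE, rng)
        pot0 = PairPotential(eps_EO_PO=0.0, eps_EO_s=0.0, eps_PO_s=0.0)
        J = lat.n_shells
        fields = FieldState(
            np.zeros(J), np.zeros(J), np.full(J, 1.0), np.zeros(J), np.zeros(J), np.zeros(J), N=2
        )
        H = scmf_hamiltonian(conf, fields, pot0, lat)
        assert H == pytest.approx(intra_energy(conf, pot0), abs=1e-10)

    def test_linearity_in_solvent_field(self, rng):
        lat = build_lattice(n_inner=10, reservoir_extent=50.0)
        from micellex.chain import sample_conformation, intra_energy

        conf = sample_conformation(SEMIFLEXIBLE, rng)
        J = lat.n_shells
        zeros = np.zeros(J)

        def H_with_cs(cs_val):
            fields = FieldState(zeros, zeros, np.full(J, cs_val), zeros, zeros, zeros, N=2)
            return scmf_hamiltonian(conf, fields, POT, lat) - intra_energy(conf, POT)

        assert H_with_cs(2.0) == pytest.approx(2 * H_with_cs(1.0), rel=1e-9)

    def test_toy_hand_computed_sum(self):
        """Two-shell, hand-built projections: H assembled term by term."""
        lat = ShellLattice(np.array([0.0, 4.0, 8.0]), 4.0)
        vols = lat.volumes
        ens = ConformationEnsemble(
            n_EO=np.array([[2.0, 1.0]]),
            n_PO=np.array([[1.0, 2.0]]),
            Phi_EO=np.array([[0.1, 0.05]]),
            Phi_PO=np.array([[0.04, 0.08]]),
            U=np.array([0.7]),
            log_w0=np.zeros(1),
            lattice=lat,
        )
        N = 10
        fields = FieldState(
            c_EO=np.array([0.2, 0.1]),
            c_PO=np.array([0.3, 0.05]),
            c_s=np.array([0.5, 1.0]),
            pi=np.array([0.9, 0.1]),
            mPhi_EO=np.array([0.6, 0.2]),
            mPhi_PO=np.array([0.5, 0.15]),
            N=N,
        )
        half = 0.5 * POT.e_EO_PO * (N - 1) / N
        expected = 0.7
        for j in range(2):
            expected += (half * fields.c_PO[j] + POT.e_EO_s * fields.c_s[j]) * ens.Phi_EO[0, j] * vols[j]
            expected += (half * fields.c_EO[j] + POT.e_PO_s * fields.c_s[j]) * ens.Phi_PO[0, j] * vols[j]
            expected += (half * fields.mPhi_PO[j] + fields.pi[j] * V_BEAD) * ens.n_EO[0, j]
            expected += (half * fields.mPhi_EO[j] + fields.pi[j] * V_BEAD) * ens.n_PO[0, j]
        assert _hamiltonians(ens, fields, POT)[0] == pytest.approx(expected, rel=1e-12)


class TestSelfConsistentSolve:
    def test_ideal_symmetric_toy_gives_uniform_weights(self, toy_lattice):
        pot0 = PairPotential(eps_EO_PO=0.0, eps_EO_s=0.0, eps_PO_s=0.0)
        base = np.array([[2.0, 1.0, 1.0]])
        ens = ConformationEnsemble(
            n_EO=np.tile(base, (4, 1)),
            n_PO=np.tile(np.array([[1.0, 1.0, 0.0]]), (4, 1)),
            Phi_EO=np.tile(np.array([[0.1, 0.05, 0.02]]), (4, 1)),
            Phi_PO=np.tile(np.array([[0.05, 0.02, 0.01]]), (4, 1)),
            U=np.zeros(4),
            log_w0=np.log(np.full(4, toy_lattice.V / 4)),
            lattice=toy_lattice,
        )
        res = solve_self_consistent(ens, pot0, N=5, mixing=0.5)
        np.testing.assert_allclose(res.P, 0.25, atol=1e-12)

    def test_fixed_point_matches_direct_minimisation(self, toy_lattice):
        """Dual route: Picard fixed point vs direct optimisation of the
        functional over the probability simplex."""
        ens = make_toy_ensemble(toy_lattice, M=6, seed=0)
        N = 3
        res = solve_self_consistent(ens, POT, N=N, mixing=0.4)
        assert res.incompressibility_residual <= 1e-6

        def objective(theta):
            P = _softmax(np.append(theta, 0.0))
            return free_energy(ens, P, _state_from_P(ens, P, N, POT), POT)

        best = None
        for trial in range(5):
            x0 = np.random.default_rng(trial).normal(0, 2, ens.M - 1)
            r = minimize(objective, x0, method="Nelder-Mead",
                         options={"xatol": 1e-13, "fatol": 1e-14, "maxiter": 60000, "maxfev": 60000})
            if best is None or r.fun < best.fun:
                best = r
        assert abs(best.fun - res.free_energy) <= 1e-6

    def test_nonconvergence_reports_residual_history(self, toy_lattice):
        from micellex.equilibrium import ConvergenceError

        ens = make_toy_ensemble(toy_lattice, M=6, seed=0)
        with pytest.raises(ConvergenceError) as err:
            solve_self_consistent(ens, POT, N=3, mixing=0.4, max_iter=2, tol=1e-15)
        assert err.value.residuals


class TestFreeEnergy:
    def test_uniform_weights_entropy_relative_to_delta(self, toy_lattice):
        ens = make_toy_ensemble(toy_lattice, M=5, seed=1, scale=0.2)
        ens.U[:] = 0.0
        # duplicate the same projection so energies are weight-independent
        for arr in (ens.n_EO, ens.n_PO, ens.Phi_EO, ens.Phi_PO):
            arr[:] = arr[0]
        N = 2
        P_uniform = np.full(5, 0.2)
        P_delta = np.array([1.0, 0, 0, 0, 0])
        f_u = free_energy(ens, P_uniform, _state_from_P(ens, P_uniform, N, POT), POT)
        f_d = free_energy(ens, P_delta, _state_from_P(ens, P_delta, N, POT), POT)
        assert f_u - f_d == pytest.approx(-N * np.log(5), rel=1e-12)

    def test_fixed_point_is_local_minimum(self, toy_lattice):
        ens = make_toy_ensemble(toy_lattice, M=6, seed=2)
        N = 3
        res = solve_self_consistent(ens, POT, N=N, mixing=0.4)
        r = np.random.default_rng(0)
        for _ in range(12):
            dP = r.normal(0, 1e-4, ens.M)
            dP -= dP.mean()
            P = np.clip(res.P + dP, 1e-14, None)
            P /= P.sum()
            f = free_energy(ens, P, _state_from_P(ens, P, N, POT), POT)
            assert f >= res.free_energy - 1e-10

    def test_adding_pure_solvent_shell_adds_bulk_term(self, toy_lattice):
        """Extending the cell by an empty shell shifts F by the analytic
        bulk-solvent free energy of that shell."""
        ens = make_toy_ensemble(toy_lattice, M=6, seed=0)
        N = 3
        res = solve_self_consistent(ens, POT, N=N, mixing=0.4)
        big = ShellLattice(np.append(toy_lattice.edges, 16.0), 4.0)
        ens_big = ConformationEnsemble(
            n_EO=np.pad(ens.n_EO, ((0, 0), (0, 1))),
            n_PO=np.pad(ens.n_PO, ((0, 0), (0, 1))),
            Phi_EO=np.pad(ens.Phi_EO, ((0, 0), (0, 1))),
            Phi_PO=np.pad(ens.Phi_PO, ((0, 0), (0, 1))),
            U=ens.U,
            log_w0=ens.log_w0,
            lattice=big,
        )
        res_big = solve_self_consistent(ens_big, POT, N=N, mixing=0.4)
        from micellex.equilibrium import V_SOLVENT

        extra = big.volumes[-1]
        assert res_big.free_energy - res.free_energy == pytest.approx(
            -extra / V_SOLVENT, rel=1e-9
        )


class TestMicellizationBookkeeping:
    def test_cmc_conversion_reproduces_printed_pair(self):
        # exp(-9.7) * 55.5 mol/L ~ 3.4e-3, against the printed 3.3e-3
        assert cmc_from_delta_mu(-9.7) == pytest.approx(3.3e-3, rel=0.05)
        assert cmc_from_delta_mu(-9.4) == pytest.approx(4.0e-3, rel=0.15)
        assert cmc_from_delta_mu(-9.2) == pytest.approx(5.1e-3, rel=0.15)

    def test_deeper_minimum_for_stronger_hydrophobic_penalty(self):
        """Raising the PO-solvent penalty strengthens the driving force for
        aggregation: the micellization chemical potential deepens
        monotonically on a fixed small ensemble."""
        from micellex.equilibrium import (
            _empty_cell_free_energy,
            _mu1_from_ensemble,
            build_lattice,
            sample_ensemble_grid,
        )

        lat = build_lattice(n_inner=16)
        rng = np.random.default_rng(4)
        ens = sample_ensemble_grid(SEMIFLEXIBLE, lat, 400, rng, PairPotential(),
                                   n_radii=10, r_max=13.0)
        N = 60
        dmus = []
        for eps_ps in (1.6, 2.1, 2.6):
            pot = PairPotential(eps_PO_s=eps_ps)
            # same geometry; only the energy scale changes, so the projected
            # ensemble can be reused (projections are potential-independent
            # except through the exclusion radius, which is unchanged)
            mu1 = _mu1_from_ensemble(ens, pot, 13.0)
            bias = -0.5 * (ens.r_place / 4.0) ** 2 * 5.0
            res = solve_self_consistent(ens, pot, N=N, seed_bias=bias, mixing=0.15,
                                        tol=1e-7)
            dmus.append((res.free_energy - _empty_cell_free_energy(lat)) / N - mu1)
        assert dmus[0] > dmus[1] > dmus[2]
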