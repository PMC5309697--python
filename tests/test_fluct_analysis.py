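"""Correlated wavefunctions, densities, spectra, projections, collectivity."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mbdfluct.chem_io import Structure
from mbdfluct.coupling import bare_dipole_tensor, long_range_tensor
from mbdfluct.fixtures import FixtureSpec, generate
from mbdfluct.fluct_analysis import (
    ModeExpansion,
    build_wavefunction,
    charge_density,
    collectivity,
    density_difference,
    displaced_charge,
    energy_spectrum,
    make_grid,
    mode_binding_contributions,
    mode_dipole_field,
    project_modes,
)
from mbdfluct.mbd_core import (
    build_hamiltonian_matrix,
    diagonalize,
    mbd_energy,
    mbd_solution,
    solve_complex_and_fragments,
)
from mbdfluct.vdw_params import PerAtomVdWParams, scale_parameters


def pair_solution(alpha=1.0, omega=1.0, r=6.0, coupled=True):
    coords = np.array([[0.0, 0, 0], [0, 0, r]])
    c6 = 0.75 * alpha**2 * omega
    p = PerAtomVdWParams(
        alpha0=[alpha, alpha], c6=[c6, c6], omega=[omega, omega], rvdw=[3.0, 3.0]
    )
    t = bare_dipole_tensor(coords) if coupled else np.zeros((6, 6))
    return diagonalize(build_hamiltonian_matrix(p, t), p, t), coords, p


class TestWavefunction:
    def test_zero_coupling_isotropic_covariance(self):
        sol, _, p = pair_solution(alpha=2.0, omega=0.7, coupled=False)
        wf = build_wavefunction(sol)
        m = 1.0 / (p.alpha0 * p.omega**2)
        for a in range(2):
            assert np.allclose(
                wf.covariance[a], np.eye(3) / (2 * m[a] * p.omega[a]), atol=1e-14
            )

    def test_coupling_stretches_covariance_along_axis(self):
        """The attractive aligned (z) fluctuation softens, widening the
        ground state along the binding axis relative to the free atom."""
        sol, _, p = pair_solution(alpha=1.0, omega=1.0, r=3.0)
        wf = build_wavefunction(sol)
        free = 1.0 / (2 * (1.0 / (p.alpha0[0] * p.omega[0] ** 2)) * p.omega[0])
        assert wf.covariance[0][2, 2] > free
        assert np.allclose(wf.covariance[0], np.diag(np.diag(wf.covariance[0])))

    def test_rotation_equivariance(self):
        s, r = generate(
            FixtureSpec(topology="random_cluster", n_atoms=5, spacing=5.0, seed=9,
                        ratio=("uniform", 0.8, 1.1))
        )
        p = scale_parameters(s, r)
        rot = Rotation.from_rotvec([0.3, 0.9, -0.5]).as_matrix()
        cov = build_wavefunction(mbd_solution(s, p)[0]).covariance
        cov_rot = build_wavefunction(mbd_solution(s.rotated(rot), p)[0]).covariance
        for a in range(5):
            assert np.allclose(cov_rot[a], rot @ cov[a] @ rot.T, atol=1e-10)


class TestChargeDensity:
    def test_single_atom_unit_charge_peak_at_site(self):
        s = Structure(["C"], [[1.0, -2.0, 0.5]], [0])
        p = scale_parameters(s, np.ones(1))
        sol = diagonalize(build_hamiltonian_matrix(p, np.zeros((3, 3))), p)
        wf = build_wavefunction(sol)
        grid = make_grid(s, spacing=0.4, padding_angstrom=6.0)
        rho = charge_density(wf, grid, s)
        assert rho.integrate() == pytest.approx(1.0, abs=1e-6)
        peak = np.unravel_index(np.argmax(rho.values), rho.shape)
        peak_xyz = rho.origin + np.array(peak) @ rho.axes
        assert np.linalg.norm(peak_xyz - s.coords[0]) < 0.5

    def test_total_integral_is_atom_count(self):
        s, r = generate(FixtureSpec(topology="ring", n_atoms=6, spacing=2.7,
                                    ratio=("constant", 0.9)))
        p = scale_parameters(s, r)
        wf = build_wavefunction(mbd_solution(s, p)[0])
        grid = make_grid(s, spacing=0.45, padding_angstrom=6.0)
        assert charge_density(wf, grid, s).integrate() == pytest.approx(6.0, abs=1e-6)

    def test_coarse_grid_flagged(self):
        s = Structure(["C"], [[0.0, 0.0, 0.0]], [0])
        p = scale_parameters(s, np.ones(1))
        wf = build_wavefunction(
            diagonalize(build_hamiltonian_matrix(p, np.zeros((3, 3))), p)
        )
        grid = make_grid(s, spacing=4.0, padding_angstrom=4.0)
        rho = charge_density(wf, grid, s)
        assert "warning" in rho.meta


class TestDensityDifference:
    def stacked(self, separation=6.5):
        s, r = generate(
            FixtureSpec(topology="stacked_rings", n_atoms=12, spacing=2.7,
                        separation=separation, ratio=("constant", 0.9))
        )
        return s, scale_parameters(s, r)

    def test_zero_interfragment_coupling_gives_zero(self):
        s, p = self.stacked()
        frag_atoms = s.fragments()
        # identical uncoupled solutions for complex and fragments
        sol_c = diagonalize(build_hamiltonian_matrix(p, np.zeros((36, 36))), p)
        frag_sols = [
            diagonalize(
                build_hamiltonian_matrix(p.subset(a), np.zeros((18, 18))), p.subset(a)
            )
            for a in frag_atoms
        ]
        grid = make_grid(s, spacing=0.6, padding_angstrom=3.0)
        delta = density_difference(
            build_wavefunction(sol_c),
            [build_wavefunction(f) for f in frag_sols],
            grid, s, frag_atoms,
        )
        assert np.allclose(delta.values, 0.0, atol=1e-14)

    def test_difference_integrates_to_zero(self):
        s, p = self.stacked()
        sol, fsols, fatoms = solve_complex_and_fragments(
            s, p, rescreen_fragments=False
        )
        grid = make_grid(s, spacing=0.45, padding_angstrom=6.0)
        delta = density_difference(
            build_wavefunction(sol), [build_wavefunction(f) for f in fsols],
            grid, s, fatoms,
        )
        assert delta.integrate() == pytest.approx(0.0, abs=1e-6)
        assert displaced_charge(delta) > 0.0

    def test_displaced_charge_grid_converged(self):
        s, p = self.stacked()
        sol, fsols, fatoms = solve_complex_and_fragments(
            s, p, rescreen_fragments=False
        )
        wfs = build_wavefunction(sol), [build_wavefunction(f) for f in fsols]
        q = []
        for spacing in (0.5, 0.25):
            grid = make_grid(s, spacing=spacing, padding_angstrom=4.0)
            q.append(displaced_charge(
                density_difference(wfs[0], wfs[1], grid, s, fatoms)
            ))
        assert q[1] == pytest.approx(q[0], rel=1e-2)

    def test_non_partition_rejected(self):
        s, p = self.stacked()
        sol, fsols, fatoms = solve_complex_and_fragments(
            s, p, rescreen_fragments=False
        )
        grid = make_grid(s, spacing=1.0, padding_angstrom=2.0)
        with pytest.raises(ValueError, match="partition"):
            density_difference(
                build_wavefunction(sol), [build_wavefunction(fsols[0])] * 2,
                grid, s, [fatoms[0], fatoms[0]],
            )


class TestSpectrum:
    def test_single_frequency_single_gaussian(self):
        spec = energy_spectrum(np.array([0.5]), half_width_ev=0.06)
        assert spec.integral() == pytest.approx(1.0, abs=1e-6)
        peak = spec.energies[np.argmax(spec.density)]
        assert peak == pytest.approx(0.5 * 27.211386, abs=1e-2)
        # half width at half maximum
        half = spec.density.max() / 2
        above = spec.energies[spec.density >= half]
        assert (above.max() - above.min()) / 2 == pytest.approx(0.06, rel=2e-2)

    def test_integral_counts_states(self):
        sol, _, _ = pair_solution()
        spec = energy_spectrum(sol.omega_coupled)
        assert spec.integral() == pytest.approx(6.0, abs=1e-6)

    def test_complex_broader_than_fragments(self):
        s, r = generate(
            FixtureSpec(topology="stacked_rings", n_atoms=12, spacing=2.7,
                        separation=6.5, ratio=("constant", 0.9))
        )
        p = scale_parameters(s, r)
        sol, fsols, _ = solve_complex_and_fragments(s, p, rescreen_fragments=False)
        pooled = np.concatenate([f.omega_coupled for f in fsols])
        assert np.var(sol.omega_coupled) >= np.var(pooled)


class TestModeDipoleField:
    def test_diagonal_hamiltonian_single_atom_vector(self):
        sol, _, _ = pair_solution(coupled=False)
        vectors, _ = mode_dipole_field(sol, 0)
        norms = np.linalg.norm(vectors, axis=1)
        assert np.sum(norms > 1e-12) == 1

    def test_binding_mode_vectors_parallel(self):
        sol, _, _ = pair_solution(r=3.0)
        # lowest mode of an aligned pair: in-phase z fluctuation
        vectors, visible = mode_dipole_field(sol, 0)
        assert visible.all()
        cosine = vectors[0] @ vectors[1] / (
            np.linalg.norm(vectors[0]) * np.linalg.norm(vectors[1])
        )
        assert cosine == pytest.approx(1.0, abs=1e-10)

    def test_full_threshold_keeps_only_largest(self):
        s, r = generate(
            FixtureSpec(topology="chain", n_atoms=4, spacing=4.0,
                        ratio=("uniform", 0.7, 1.2), seed=2)
        )
        p = scale_parameters(s, r)
        sol, _ = mbd_solution(s, p)
        _, visible = mode_dipole_field(sol, 0, threshold=1.0)
        assert visible.sum() == 1

    def test_out_of_range_mode(self):
        sol, _, _ = pair_solution()
        with pytest.raises(IndexError):
            mode_dipole_field(sol, 6)


class TestProjection:
    def coupled_system(self, separation=6.5):
        s, r = generate(
            FixtureSpec(topology="stacked_rings", n_atoms=12, spacing=2.7,
                        separation=separation, ratio=("constant", 0.9))
        )
        p = scale_parameters(s, r)
        return s, solve_complex_and_fragments(s, p, rescreen_fragments=False)

    def test_rows_normalized_and_orthogonal(self):
        _, (sol, fsols, fatoms) = self.coupled_system()
        exp = project_modes(sol, fsols, fatoms)
        assert np.allclose((exp.coeffs**2).sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(exp.coeffs @ exp.coeffs.T, np.eye(36), atol=1e-10)

    def test_round_trip_reconstructs_modes(self):
        _, (sol, fsols, fatoms) = self.coupled_system()
        exp = project_modes(sol, fsols, fatoms)
        basis = np.zeros((36, 36))
        col = 0
        for fsol, atoms in zip(fsols, fatoms):
            rows = np.concatenate([[3 * a, 3 * a + 1, 3 * a + 2] for a in atoms])
            basis[rows[:, None], col + np.arange(18)[None, :]] = fsol.modes
            col += 18
        assert np.allclose(basis @ exp.coeffs.T, sol.modes, atol=1e-10)

    def test_zero_coupling_is_signed_permutation(self):
        s, _ = self.coupled_system()
        p = scale_parameters(s, np.full(12, 0.9))
        fatoms = s.fragments()
        sol_c = diagonalize(build_hamiltonian_matrix(p, np.zeros((36, 36))), p)
        fsols = [
            diagonalize(
                build_hamiltonian_matrix(p.subset(a), np.zeros((18, 18))),
                p.subset(a),
            )
            for a in fatoms
        ]
        exp = project_modes(sol_c, fsols, fatoms)
        # every row concentrated on a single fragment mode
        assert np.allclose(np.max(exp.coeffs**2, axis=1), 1.0, atol=1e-10)

    def test_symmetric_homodimer_binding_modes_shared_equally(self):
        sol, coords, p = pair_solution(r=3.0)
        fatoms = [np.array([0]), np.array([1])]
        fsols = [
            diagonalize(
                build_hamiltonian_matrix(p.subset(a), np.zeros((3, 3))), p.subset(a)
            )
            for a in fatoms
        ]
        exp = project_modes(sol, fsols, fatoms)
        # each coupled mode is an even/odd combination of one mode per atom
        weights = np.zeros((6, 2))
        for j in range(6):
            weights[:, exp.fragment_id[j]] += exp.coeffs[:, j] ** 2
        assert np.allclose(weights, 0.5, atol=1e-10)


class TestCollectivity:
    def expansion(self, row):
        row = np.asarray(row, dtype=float)
        coeffs = np.zeros((1, len(row)))
        coeffs[0] = row
        return ModeExpansion(
            coeffs=coeffs,
            fragment_id=np.zeros(len(row), int),
            within_index=np.arange(len(row)),
            fragment_omega=np.ones(len(row)),
        )

    def test_single_component_is_one(self):
        assert collectivity(self.expansion([1.0, 0.0, 0.0]), 0) == pytest.approx(1.0)

    def test_equal_three_component_is_three(self):
        exp = self.expansion(np.full(3, 1 / np.sqrt(3)))
        assert collectivity(exp, 0) == pytest.approx(3.0, rel=1e-12)
        assert collectivity(exp, 0, convention="linear") == pytest.approx(np.sqrt(3))

    @pytest.mark.parametrize("n", [2, 5, 12])
    def test_equal_n_component_is_n(self, n):
        exp = self.expansion(np.full(n, 1 / np.sqrt(n)))
        assert collectivity(exp, 0) == pytest.approx(float(n), rel=1e-12)

    def test_bounded_by_mode_count(self):
        _, (sol, fsols, fatoms) = TestProjection().coupled_system()
        exp = project_modes(sol, fsols, fatoms)
        values = [collectivity(exp, i) for i in range(exp.n_modes)]
        assert all(1.0 - 1e-12 <= v <= 36.0 for v in values)


class TestBindingContributions:
    def test_zero_coupling_all_zero(self):
        s, r = generate(
            FixtureSpec(topology="stacked_rings", n_atoms=8, spacing=2.8,
                        separation=7.0, ratio=("constant", 0.9))
        )
        p = scale_parameters(s, r)
        fatoms = s.fragments()
        sol_c = diagonalize(build_hamiltonian_matrix(p, np.zeros((24, 24))), p)
        fsols = [
            diagonalize(
                build_hamiltonian_matrix(p.subset(a), np.zeros((12, 12))),
                p.subset(a),
            )
            for a in fatoms
        ]
        contrib = mode_binding_contributions(sol_c, project_modes(sol_c, fsols, fatoms))
        assert np.allclose(contrib, 0.0, atol=1e-12)

    def test_contributions_sum_to_interfragment_energy(self):
        s, r = generate(
            FixtureSpec(topology="stacked_rings", n_atoms=12, spacing=2.7,
                        separation=6.5, ratio=("constant", 0.9))
        )
        p = scale_parameters(s, r)
        sol, fsols, fatoms = solve_complex_and_fragments(s, p, rescreen_fragments=False)
        contrib = mode_binding_contributions(sol, project_modes(sol, fsols, fatoms))
        e_int = mbd_energy(sol) - sum(mbd_energy(f) for f in fsols)
        assert contrib.sum() == pytest.approx(e_int, abs=1e-10)
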