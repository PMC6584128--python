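"""Grid construction, boundary conditions and the (N)LPB solver."""

import io
import math

import numpy as np
import pytest

from radial_oracle import solve_radial_nlpb
from ioncount.geometry import Atom, Molecule, SequenceRecord, build_bform_duplex, \
    build_sphere_molecule
from ioncount.pb_engine import (
    ElectrolyteSpec,
    IonSpecies,
    bjerrum_length,
    build_field_maps,
    debye_length,
    dh_boundary,
    dh_potential_field,
    analytic_dh_sphere,
    make_grid,
    solve_lpb,
    solve_nlpb,
    write_dx,
)

TINY_SALT = ElectrolyteSpec.monovalent(1e-12)  # effectively unscreened


class TestElectrolyte:
    def test_electroneutrality_enforced(self):
        with pytest.raises(ValueError, match="electroneutral"):
            ElectrolyteSpec((IonSpecies("Na", 1, 0.01), IonSpecies("Br", -1, 0.02)))

    @pytest.mark.parametrize(
        "elec, expected",
        [
            (ElectrolyteSpec.monovalent(0.010), 30.32),
            (ElectrolyteSpec.monovalent(0.040), 15.16),
            (ElectrolyteSpec.mixed_mg_na(0.0025, 0.025), 16.82),
        ],
    )
    def test_debye_lengths(self, elec, expected):
        """kappa^-1 from I = 1/2 sum z_i^2 c_i at 298.15 K, eps 78."""
        # independent closed form: kappa^2 = 8 pi l_B N_A I
        lB = bjerrum_length()
        I_num = elec.ionic_strength_molar() * 6.02214076e-4
        closed_form = 1.0 / math.sqrt(8 * math.pi * lB * I_num)
        assert debye_length(elec) == pytest.approx(closed_form, rel=1e-12)
        assert debye_length(elec) == pytest.approx(expected, abs=0.01)

    def test_bjerrum_length_in_water(self):
        assert bjerrum_length(298.15, 78.0) == pytest.approx(7.19, abs=0.05)


class TestMakeGrid:
    def test_single_atom_cube(self):
        mol = build_sphere_molecule(1e-6, 0.0, 1)
        grid = make_grid(mol, 1.0, 50.0)
        assert all(n >= 101 for n in grid.shape)

    def test_duplex_box_is_anisotropic(self):
        mol = build_bform_duplex(
            SequenceRecord("d24", "GGTGACGAGTGAGCTACTGGGCGG", "dna")
        )
        grid = make_grid(mol, 2.0, 60.0)
        assert grid.shape[2] > grid.shape[0]
        lo = np.array(grid.origin)
        hi = grid.upper_corner()
        pos = mol.positions()
        assert np.all(pos - 60.0 >= lo - 2.0) and np.all(pos + 60.0 <= hi + 2.0)

    def test_halving_spacing_doubles_nodes(self):
        mol = build_sphere_molecule(10.0, 0.0, 1)
        g2 = make_grid(mol, 2.0, 40.0)
        g1 = make_grid(mol, 1.0, 40.0)
        for a, b in zip(g1.shape, g2.shape):
            assert abs(a - 2 * b) <= 3

    def test_memory_cap(self):
        mol = build_sphere_molecule(10.0, 0.0, 1)
        with pytest.raises(MemoryError, match="spacing"):
            make_grid(mol, 0.1, 100.0)

    def test_padding_guard(self):
        mol = build_sphere_molecule(10.0, 0.0, 1)
        elec = ElectrolyteSpec.monovalent(0.010)  # debye ~30 Å
        with pytest.raises(ValueError, match="Debye"):
            make_grid(mol, 2.0, 30.0, elec)
        with pytest.warns(UserWarning, match="Debye"):
            make_grid(mol, 2.0, 75.0, elec)


class TestFieldMaps:
    def test_dielectric_interior(self):
        mol = build_sphere_molecule(2.0, -1.0, 1)
        elec = ElectrolyteSpec.monovalent(0.1, ion_radius=0.0)
        grid = make_grid(mol, 1.0, 15.0)
        maps = build_field_maps(mol, grid, elec, probe_radius=0.0)
        ax = grid.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2)
        assert np.all(maps.dielectric[r <= 2.0] == 2.0)
        assert np.all(maps.dielectric[r > 2.0 + 1e-9] == 78.0)

    def test_gridded_601_charge(self):
        """Trilinear spreading conserves the duplex formal charge (-292 e)."""
        from ioncount.geometry import WIDOM_601

        mol = build_bform_duplex(SequenceRecord("601", WIDOM_601, "dna")).centered()
        elec = ElectrolyteSpec.monovalent(0.010)
        grid = make_grid(mol, 4.0, 25.0)
        maps = build_field_maps(mol, grid, elec)
        assert maps.total_charge() == pytest.approx(-292.0, abs=0.01)

    def test_ion_exclusion_contains_dielectric_interior(self):
        """lam=0 region includes the solute dielectric region when the ion
        radius is at least the probe radius."""
        mol = build_sphere_molecule(5.0, -2.0, 1)
        elec = ElectrolyteSpec.monovalent(0.1, ion_radius=2.0)
        grid = make_grid(mol, 1.0, 12.0)
        maps = build_field_maps(mol, grid, elec, probe_radius=1.4)
        solute = maps.dielectric == elec.eps_solute
        assert np.all(maps.accessibility[solute] == 0.0)
        assert maps.accessibility.sum() < maps.accessibility.size

    def test_atom_outside_grid(self):
        mol = build_sphere_molecule(5.0, -2.0, 1)
        elec = ElectrolyteSpec.monovalent(0.1)
        grid = make_grid(mol, 1.0, 12.0)
        shifted = Molecule([Atom(np.array([999.0, 0, 0]), -2.0, 5.0)], -2)
        with pytest.raises(ValueError, match="outside"):
            build_field_maps(shifted, grid, elec)


class TestDhBoundary:
    def test_neutral_molecule_zero(self):
        mol = build_sphere_molecule(5.0, 0.0, 1)
        elec = ElectrolyteSpec.monovalent(0.05)
        grid = make_grid(mol, 2.0, 30.0)
        bnd = dh_boundary(grid, mol, elec)
        assert np.all(bnd == 0.0)

    def test_coulomb_limit(self):
        """With kappa -> 0 the point form reduces to l_B q / d."""
        mol = Molecule([Atom(np.zeros(3), -1.0, 0.0)], -1)
        grid = make_grid(mol, 5.0, 40.0)
        bnd = dh_boundary(grid, mol, TINY_SALT, size_corrected=False)
        lB = TINY_SALT.bjerrum_length()
        ax = grid.axes()
        j = grid.shape[1] // 2
        k = grid.shape[2] // 2
        d = abs(ax[0][0])
        assert bnd[0, j, k] == pytest.approx(-lB / d, rel=1e-4)

    def test_analytic_dh_sphere_limits(self):
        elec = ElectrolyteSpec.monovalent(0.01)
        assert analytic_dh_sphere(0.0, 10.0, elec, 25.0) == 0.0
        # Coulomb limit at the surface: -l_B/R
        val = analytic_dh_sphere(-1.0, 10.0, TINY_SALT, 10.0)
        assert val == pytest.approx(-TINY_SALT.bjerrum_length() / 10.0, rel=1e-4)
        # monotone decay of |phi| with distance
        rs = np.linspace(10, 120, 40)
        phi = analytic_dh_sphere(-5.0, 10.0, elec, rs)
        assert np.all(np.diff(np.abs(phi)) < 0)
        with pytest.raises(ValueError):
            analytic_dh_sphere(-1.0, 10.0, elec, 5.0)


class TestSolver:
    def test_zero_charge_gives_zero_field(self):
        mol = build_sphere_molecule(5.0, 0.0, 1)
        elec = ElectrolyteSpec.monovalent(0.1)
        grid = make_grid(mol, 2.0, 20.0)
        maps = build_field_maps(mol, grid, elec)
        for solver in (solve_nlpb, solve_lpb):
            sol = solver(maps, elec)
            assert sol.converged
            assert np.all(sol.phi == 0.0)

    def test_weak_sphere_matches_analytic_dh(self, weak_sphere_run, elec_50mM_clean):
        """NLPB potential on a -1 e sphere tracks the analytic DH solution
        to within 2% beyond 2 Å from the surface."""
        mol, sol = weak_sphere_run
        grid = sol.maps.grid
        ax = grid.axes()
        j, k = grid.shape[1] // 2, grid.shape[2] // 2
        r = np.abs(ax[0])
        ray = sol.phi[:, j, k]
        # strictly beyond 2 Å from the surface (the node at exactly R+2
        # sits on the ion-exclusion boundary)
        sel = (r > 12.0 + 1e-9) & (r <= 3 * elec_50mM_clean.debye_length() + 12)
        ana = analytic_dh_sphere(-1.0, 10.0, elec_50mM_clean, r[sel])
        assert np.max(np.abs(ray[sel] - ana) / np.abs(ana)) < 0.02

    def test_strong_sphere_surface_potential_vs_radial_oracle(
        self, strong_shell_run, elec_50mM_clean
    ):
        """-50 e sphere: 3D surface potential within 2% of the independent
        1D finite-volume Newton oracle."""
        mol, sol = strong_shell_run
        rad = solve_radial_nlpb(-50.0, 10.0, elec_50mM_clean)
        grid = sol.maps.grid
        ax = grid.axes()
        X = ax[0][:, None, None]
        Y = ax[1][None, :, None]
        Z = ax[2][None, None, :]
        R = np.sqrt(X**2 + Y**2 + Z**2)
        sel = (R >= 10.0) & (R <= 12.0)
        phi3d = sol.phi[sel].mean()
        phi1d = rad.phi_at(R[sel]).mean()
        assert abs(phi3d - phi1d) / abs(phi1d) < 0.02
        # sanity: strongly nonlinear regime (linear theory would give ~ -21)
        assert -10.0 < phi3d < -3.0

    def test_negative_molecule_nonpositive_potential(self, strong_shell_run):
        """Discrete maximum principle: phi <= 0 everywhere around a
        uniformly negative molecule."""
        _, sol = strong_shell_run
        assert sol.phi.max() <= 1e-9

    def test_lpb_matches_nlpb_for_small_potentials(self):
        """|phi| < 0.1 everywhere: linear and nonlinear solutions agree to 1%."""
        # a large weakly charged sphere keeps the surface potential small
        mol = build_sphere_molecule(30.0, -1.0, 1)
        elec = ElectrolyteSpec.monovalent(0.1, ion_radius=0.0)
        grid = make_grid(mol, 2.5, 4 * elec.debye_length(), elec)
        maps = build_field_maps(mol, grid, elec, probe_radius=0.0)
        phi0 = dh_potential_field(grid, mol, elec)
        nl = solve_nlpb(maps, elec, phi_init=phi0.copy())
        li = solve_lpb(maps, elec, phi_init=phi0.copy())
        # small-potential regime holds wherever ions actually live
        ions = maps.accessibility > 0
        assert np.max(np.abs(nl.phi[ions])) < 0.1
        big = ions & (np.abs(li.phi) > 1e-3)
        assert np.max(np.abs((nl.phi[big] - li.phi[big]) / li.phi[big])) < 0.01

    def test_lpb_superposition(self):
        """Linearity: phi(q1 + q2) = phi(q1) + phi(q2) on identical maps."""
        elec = ElectrolyteSpec.monovalent(0.1, ion_radius=0.0)
        a1 = Atom(np.array([-5.0, 0, 0]), -2.0, 0.0)
        a2 = Atom(np.array([5.0, 0, 0]), 1.0, 0.0)

        def solve_for(atoms, q):
            mol = Molecule(list(atoms), q)
            grid = make_grid(Molecule([Atom(np.zeros(3), 0.0, 12.0)], 0),
                             2.0, 3.5 * elec.debye_length())
            maps = build_field_maps(mol, grid, elec, probe_radius=0.0)
            return solve_lpb(maps, elec, tolerance=1e-9,
                             phi_init=dh_boundary(grid, mol, elec))

        s1 = solve_for([a1], -2)
        s2 = solve_for([a2], 1)
        s12 = solve_for([a1, a2], -1)
        assert np.max(np.abs(s12.phi - (s1.phi + s2.phi))) < 1e-6 * 50

    def test_translation_invariance(self):
        """Shifting the molecule by a non-integer number of voxels moves
        N_i by < 1%."""
        from ioncount.atmosphere import integrate_ion_excess

        elec = ElectrolyteSpec.monovalent(0.05, ion_radius=0.0)
        results = []
        for shift in (0.0, 0.9):  # 0.36 voxels at h=2.5
            mol = Molecule(
                [Atom(np.array([shift, 0.0, 0.0]), -5.0, 10.0)], -5
            )
            grid = make_grid(
                Molecule([Atom(np.zeros(3), 0.0, 10.0)], 0), 2.5,
                3.5 * elec.debye_length(),
            )
            maps = build_field_maps(mol, grid, elec, probe_radius=0.0)
            sol = solve_nlpb(
                maps, elec, phi_init=dh_potential_field(grid, mol, elec)
            )
            assert sol.converged
            exc = integrate_ion_excess(sol, molecule_charge=-5.0)
            results.append(exc.n_atmosphere)
        for label in results[0]:
            a, b = results[0][label], results[1][label]
            assert abs(a - b) / abs(a) < 0.01

    def test_grid_refinement_stability(self, refinement_counts):
        """Halving the spacing from 2 Å to 1 Å moves the -10 e sphere's
        excess counts by < 2%."""
        counts = refinement_counts
        for label in counts[2.0]:
            drift = abs(counts[1.0][label] - counts[2.0][label])
            assert drift / abs(counts[1.0][label]) < 0.02

    def test_nonconvergence_is_flagged_not_raised(self):
        mol = build_sphere_molecule(10.0, -10.0, 1)
        elec = ElectrolyteSpec.monovalent(0.1)
        grid = make_grid(mol, 2.0, 4 * elec.debye_length(), elec)
        maps = build_field_maps(mol, grid, elec)
        with pytest.warns(UserWarning, match="did not converge"):
            sol = solve_nlpb(maps, elec, max_iterations=2)
        assert not sol.converged
        assert sol.iterations == 2
        assert np.all(np.isfinite(sol.phi))


class TestDxExport:
    def test_header_and_values(self):
        mol = build_sphere_molecule(5.0, 0.0, 1)
        grid = make_grid(mol, 2.0, 20.0)
        data = np.arange(grid.n_nodes, dtype=float).reshape(grid.shape)
        buf = io.StringIO()
        write_dx(data, grid, buf)
        text = buf.getvalue()
        nx, ny, nz = grid.shape
        assert f"gridpositions counts {nx} {ny} {nz}" in text
        assert f"items {data.size}" in text
        values = [
            float(v)
            for line in text.splitlines()
            if line and line[0] in "0123456789-."
            for v in line.split()
        ]
        assert values[:4] == [0.0, 1.0, 2.0, 3.0]
        assert len(values) == data.size
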