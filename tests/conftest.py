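"""Shared fixtures: expensive PB solves are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ioncount.atmosphere import pb_ion_count
from ioncount.geometry import Atom, Molecule, build_sphere_molecule
from ioncount.pb_engine import (
    ElectrolyteSpec,
    build_field_maps,
    dh_potential_field,
    make_grid,
    solve_nlpb,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def elec_50mM_clean() -> ElectrolyteSpec:
    """50 mM 1:1 salt with zero Stern radius (clean analytic geometry)."""
    return ElectrolyteSpec.monovalent(0.050, ion_radius=0.0)


@pytest.fixture(scope="session")
def weak_sphere_run(elec_50mM_clean):
    """-1 e, R=10 Å sphere in 50 mM 1:1 salt, probe 0: NLPB solution."""
    elec = elec_50mM_clean
    mol = build_sphere_molecule(10.0, -1.0, 1)
    grid = make_grid(mol, 2.0, 5 * elec.debye_length(), elec)
    maps = build_field_maps(mol, grid, elec, probe_radius=0.0)
    phi0 = dh_potential_field(grid, mol, elec)
    sol = solve_nlpb(maps, elec, phi_init=phi0)
    assert sol.converged
    return mol, sol


@pytest.fixture(scope="session")
def strong_shell_run(elec_50mM_clean):
    """-50 e shell-charged sphere (R=10 Å), 50 mM, h=1.5 Å: NLPB solution.

    The charge is tiled on a Fibonacci lattice 1 Å inside the surface with
    a neutral core atom, matching the radial oracle's thin-shell charge.
    """
    elec = elec_50mM_clean
    shell = build_sphere_molecule(9.0, -50.0, 400)
    mol = Molecule(shell.atoms + [Atom(np.zeros(3), 0.0, 10.0, name="COR")], -50)
    grid = make_grid(mol, 1.5, 5 * elec.debye_length(), elec)
    maps = build_field_maps(mol, grid, elec, probe_radius=0.0)
    phi0 = dh_potential_field(grid, mol, elec)
    sol = solve_nlpb(maps, elec, phi_init=phi0)
    assert sol.converged
    return mol, sol


@pytest.fixture(scope="session")
def ten_e_run():
    """-10 e, R=10 Å sphere in 10 mM 1:1 salt (the oracle-comparison case)."""
    elec = ElectrolyteSpec.monovalent(0.010, ion_radius=0.0)
    mol = build_sphere_molecule(10.0, -10.0, 1)
    grid = make_grid(mol, 3.3, 4 * elec.debye_length(), elec)
    maps = build_field_maps(mol, grid, elec, probe_radius=0.0)
    phi0 = dh_potential_field(grid, mol, elec)
    sol = solve_nlpb(maps, elec, phi_init=phi0)
    assert sol.converged
    return mol, elec, sol


@pytest.fixture(scope="session")
def weak_sphere_default_run():
    """-1 e sphere at 10 mM with production defaults (probe 1.4, ion 2 Å,
    padding six Debye lengths, <=80 nodes/axis)."""
    mol = build_sphere_molecule(10.0, -1.0, 1)
    elec = ElectrolyteSpec.monovalent(0.010)
    pad = 6 * elec.debye_length()
    spacing = 2 * (10 + 1.4 + pad) / 79
    sol, exc = pb_ion_count(
        mol, elec, spacing=spacing, padding=pad, convention="atmosphere"
    )
    assert sol.converged
    return mol, sol, exc


@pytest.fixture(scope="session")
def beta_vs_charge_betas(elec_50mM_clean):
    """beta_plus (atmosphere convention) for R=10 Å spheres of -2/-10/-30 e."""
    from ioncount.atmosphere import beta_from_excess, integrate_ion_excess

    elec = elec_50mM_clean
    out = {}
    for q in (-2.0, -10.0, -30.0):
        mol = build_sphere_molecule(10.0, q, 1)
        grid = make_grid(mol, 2.5, 4 * elec.debye_length(), elec)
        maps = build_field_maps(mol, grid, elec, probe_radius=0.0)
        sol = solve_nlpb(maps, elec, phi_init=dh_potential_field(grid, mol, elec))
        assert sol.converged
        exc = integrate_ion_excess(sol, convention="atmosphere", molecule_charge=q)
        out[q] = beta_from_excess(exc).beta_plus
    return out


@pytest.fixture(scope="session")
def salt_series_counts():
    """Measured (whole-box) excess counts for the -10 e sphere at 10 mM vs
    100 mM 1:1 salt, with the production Stern layer.

    The decline of counterion attraction with salt is partly an
    excluded-volume effect, so it appears in the box convention (which a
    buffer-equilibration measurement reports) with a finite ion radius;
    the bare diffuse-atmosphere count alone is nearly salt-independent
    for this geometry.
    """
    mol = build_sphere_molecule(10.0, -10.0, 1)
    out = {}
    for conc, spacing in ((0.010, 4.0), (0.100, 2.0)):
        elec = ElectrolyteSpec.monovalent(conc)
        _, exc = pb_ion_count(
            mol, elec, spacing=spacing, padding=5 * elec.debye_length(),
            convention="box",
        )
        out[conc] = exc.n_box
    return out


@pytest.fixture(scope="session")
def refinement_counts():
    """Excess counts for the -10 e sphere at spacings 2 Å and 1 Å (100 mM)."""
    from ioncount.atmosphere import integrate_ion_excess

    elec = ElectrolyteSpec.monovalent(0.1, ion_radius=0.0)
    mol = build_sphere_molecule(10.0, -10.0, 1)
    counts = {}
    for h in (2.0, 1.0):
        grid = make_grid(mol, h, 4 * elec.debye_length(), elec)
        maps = build_field_maps(mol, grid, elec, probe_radius=0.0)
        sol = solve_nlpb(maps, elec, phi_init=dh_potential_field(grid, mol, elec))
        assert sol.converged
        counts[h] = integrate_ion_excess(sol, molecule_charge=-10.0).n_atmosphere
    return counts


@pytest.fixture(scope="session")
def mg_na_weak_lpb_run():
    """-1 e sphere in 2.5 mM MgBr2 + 25 mM NaBr, linearized PB."""
    mol = build_sphere_molecule(10.0, -1.0, 1)
    elec = ElectrolyteSpec.mixed_mg_na(0.0025, 0.025)
    pad = 5 * elec.debye_length()
    spacing = 2 * (10 + 1.4 + pad) / 79
    sol, exc = pb_ion_count(
        mol, elec, spacing=spacing, padding=pad, linear=True,
        convention="atmosphere",
    )
    assert sol.converged
    return mol, sol, exc
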