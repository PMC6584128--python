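"""Finite-difference nonlinear Poisson-Boltzmann solver.

The electrostatic potential phi is carried in thermal units (kT/e) on a
uniform Cartesian grid.  In Gaussian-style units with lengths in Å the
mean-field equation reads

    div( eps(r) grad phi ) = -alpha * [ rho_f(r) + lam(r) * S(phi) ],

    S(phi) = sum_i z_i c_i exp(-z_i phi),       alpha = 4 pi l_B eps_s,

where rho_f is the fixed (molecular) charge density in e/Å^3, lam(r) is
the 0/1 ion-accessibility map, c_i are bulk number densities (ions/Å^3),
and l_B = e^2 / (4 pi eps0 eps_s kT) is the Bjerrum length (~7.2 Å in
water at 298.15 K).  Linearizing S about phi = 0 recovers the
Debye-Hückel equation with kappa^2 = 8 pi l_B I.

Discretization: 7-point stencil with harmonic-mean face dielectrics and
trilinear charge spreading.  Nonlinear iteration: damped Newton
Gauss-Seidel sweeps in red-black ordering with successive
over-relaxation; Dirichlet boundaries from a screened-Coulomb
(Debye-Hückel) superposition over the atoms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np

from .geometry import Molecule

__all__ = [
    "IonSpecies",
    "ElectrolyteSpec",
    "Grid3D",
    "FieldMaps",
    "PBSolution",
    "bjerrum_length",
    "debye_length",
    "make_grid",
    "build_field_maps",
    "dh_boundary",
    "dh_potential_field",
    "analytic_dh_sphere",
    "solve_nlpb",
    "solve_lpb",
    "write_dx",
    "MOLAR_TO_PER_A3",
]

#: e^2 / (4 pi eps0 k_B) in Å·K — converts to Bjerrum length via /(eps*T).
_E2_OVER_4PIEPS0_KB = 1.6710095e5
#: mol/L -> ions/Å^3
MOLAR_TO_PER_A3 = 6.02214076e-4


def bjerrum_length(temperature: float = 298.15, eps_solvent: float = 78.0) -> float:
    """Bjerrum length in Å (≈7.19 Å for water, eps 78, 298.15 K)."""
    return _E2_OVER_4PIEPS0_KB / (eps_solvent * temperature)


@dataclass(frozen=True)
class IonSpecies:
    label: str
    valence: int
    concentration_molar: float

    def __post_init__(self) -> None:
        if self.concentration_molar <= 0:
            raise ValueError("bulk concentration must be positive")
        if self.valence == 0:
            raise ValueError("ion valence must be nonzero")


@dataclass(frozen=True)
class ElectrolyteSpec:
    """Bulk electrolyte: species, temperature, dielectrics, ion size."""

    species: tuple[IonSpecies, ...]
    temperature: float = 298.15
    eps_solvent: float = 78.0
    eps_solute: float = 2.0
    ion_radius: float = 2.0  # Å, shared Stern exclusion radius

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not self.species:
            raise ValueError("electrolyte needs at least one ion species")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ion_radius < 0:
            raise ValueError("ion radius must be non-negative")
        net = sum(s.valence * s.concentration_molar for s in self.species)
        scale = sum(abs(s.valence) * s.concentration_molar for s in self.species)
        if abs(net) > 1e-9 * max(scale, 1e-300):
            raise ValueError(f"bulk electrolyte not electroneutral (sum z*c = {net:g})")

    @classmethod
    def monovalent(cls, concentration_molar: float, cation: str = "Na",
                   anion: str = "Br", **kw) -> "ElectrolyteSpec":
        """A 1:1 salt such as NaBr."""
        return cls(
            (
                IonSpecies(cation, +1, concentration_molar),
                IonSpecies(anion, -1, concentration_molar),
            ),
            **kw,
        )

    @classmethod
    def mixed_mg_na(cls, c_mg_molar: float, c_na_molar: float,
                    anion: str = "Br", **kw) -> "ElectrolyteSpec":
        """MgBr2 + NaBr mixture (the divalent-competition condition)."""
        return cls(
            (
                IonSpecies("Mg", +2, c_mg_molar),
                IonSpecies("Na", +1, c_na_molar),
                IonSpecies(anion, -1, 2 * c_mg_molar + c_na_molar),
            ),
            **kw,
        )

    def bjerrum_length(self) -> float:
        return bjerrum_length(self.temperature, self.eps_solvent)

    def ionic_strength_molar(self) -> float:
        return 0.5 * sum(s.valence**2 * s.concentration_molar for s in self.species)

    def kappa(self) -> float:
        """Inverse Debye length in 1/Å."""
        I_num = self.ionic_strength_molar() * MOLAR_TO_PER_A3
        return math.sqrt(8.0 * math.pi * self.bjerrum_length() * I_num)

    def debye_length(self) -> float:
        return 1.0 / self.kappa()

    def valences(self) -> np.ndarray:
        return np.array([s.valence for s in self.species], dtype=float)

    def number_densities(self) -> np.ndarray:
        """Bulk densities in ions/Å^3."""
        return np.array(
            [s.concentration_molar * MOLAR_TO_PER_A3 for s in self.species]
        )


def debye_length(electrolyte: ElectrolyteSpec) -> float:
    """Debye screening length kappa^-1 in Å."""
    return electrolyte.debye_length()


@dataclass(frozen=True)
class Grid3D:
    """Uniform node-centered grid: node (i,j,k) at origin + spacing*(i,j,k)."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(n < 17 for n in self.shape):
            raise ValueError("grid must have at least 17 nodes per axis")

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.shape[d])
            for d in range(3)
        )

    def upper_corner(self) -> np.ndarray:
        return np.array(self.origin) + self.spacing * (np.array(self.shape) - 1)

    def voxel_volume(self) -> float:
        return self.spacing**3


@dataclass
class FieldMaps:
    """Per-node dielectric, ion accessibility and fixed charge (e per node)."""

    grid: Grid3D
    dielectric: np.ndarray
    accessibility: np.ndarray
    fixed_charge: np.ndarray

    def total_charge(self) -> float:
        return float(self.fixed_charge.sum())


@dataclass
class PBSolution:
    """Converged (or flagged) PB potential in kT/e with its input maps."""

    phi: np.ndarray
    maps: FieldMaps
    electrolyte: ElectrolyteSpec
    residual: float
    iterations: int
    converged: bool
    tolerance: float
    linear: bool = False
    residual_history: list[float] = field(default_factory=list)


def make_grid(
    molecule: Molecule,
    spacing: float,
    padding: float,
    electrolyte: ElectrolyteSpec | None = None,
    max_nodes: int = 64_000_000,
) -> Grid3D:
    """Enclose the molecule plus ``padding`` on all sides in a uniform grid.

    ``padding`` should be at least two (ideally three or more) Debye
    lengths so the Dirichlet boundary values are accurate; with an
    electrolyte given, a warning is emitted below three.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if electrolyte is not None:
        ld = electrolyte.debye_length()
        if padding < 2 * ld:
            raise ValueError(
                f"padding {padding:.1f} Å is below two Debye lengths ({2 * ld:.1f} Å)"
            )
        if padding < 3 * ld:
            warnings.warn(
                f"padding {padding:.1f} Å is below three Debye lengths "
                f"({3 * ld:.1f} Å); boundary and truncation errors may be large",
                stacklevel=2,
            )
    pos = molecule.positions()
    rad = molecule.radii()
    lo = (pos - rad[:, None]).min(axis=0) - padding
    hi = (pos + rad[:, None]).max(axis=0) + padding
    shape = tuple(
        max(17, int(math.ceil((hi[d] - lo[d]) / spacing)) + 1) for d in range(3)
    )
    n = int(np.prod(shape))
    if n > max_nodes:
        raise MemoryError(
            f"grid would need {n} nodes (> cap {max_nodes}); "
            "increase spacing or reduce padding"
        )
    # center the requested box inside the (rounded-up) grid extent
    center = 0.5 * (lo + hi)
    origin = tuple(center[d] - 0.5 * spacing * (shape[d] - 1) for d in range(3))
    return Grid3D(origin, spacing, shape)


def _paint_spheres(
    grid: Grid3D, out: np.ndarray, centers: np.ndarray, radii: np.ndarray, value
) -> None:
    """Set ``out`` nodes within radii of the centers to ``value``."""
    h = grid.spacing
    origin = np.array(grid.origin)
    shape = np.array(grid.shape)
    for c, r in zip(centers, radii):
        if r <= 0:
            continue
        lo_i = np.maximum(np.floor((c - r - origin) / h).astype(int), 0)
        hi_i = np.minimum(np.ceil((c + r - origin) / h).astype(int), shape - 1)
        if np.any(lo_i > hi_i):
            continue
        ax = [origin[d] + h * np.arange(lo_i[d], hi_i[d] + 1) - c[d] for d in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        sub = out[lo_i[0]:hi_i[0] + 1, lo_i[1]:hi_i[1] + 1, lo_i[2]:hi_i[2] + 1]
        sub[d2 <= r * r] = value


def build_field_maps(
    molecule: Molecule,
    grid: Grid3D,
    electrolyte: ElectrolyteSpec,
    probe_radius: float = 1.4,
) -> FieldMaps:
    """Dielectric / accessibility / charge maps for a molecule on a grid.

    The solute dielectric region is the union of atom spheres inflated by
    the solvent probe radius (an inflated-sphere approximation of the
    solvent-excluded surface); the ion-inaccessible region (lam = 0) is
    the union inflated by the shared ion radius.  Atom charges are spread
    by trilinear weighting onto the eight surrounding nodes, conserving
    the total charge exactly.
    """
    pos = molecule.positions()
    q = molecule.charges()
    rad = molecule.radii()
    origin = np.array(grid.origin)
    h = grid.spacing
    upper = grid.upper_corner()
    if np.any(pos < origin - 1e-9) or np.any(pos > upper + 1e-9):
        raise ValueError("atom lies outside the grid")

    eps = np.full(grid.shape, electrolyte.eps_solvent, dtype=float)
    _paint_spheres(grid, eps, pos, rad + probe_radius, electrolyte.eps_solute)

    lam = np.ones(grid.shape, dtype=float)
    _paint_spheres(grid, lam, pos, rad + electrolyte.ion_radius, 0.0)

    charge = np.zeros(grid.shape, dtype=float)
    frac = (pos - origin) / h
    base = np.floor(frac).astype(int)
    base = np.clip(base, 0, np.array(grid.shape) - 2)
    t = frac - base
    for dx in (0, 1):
        wx = np.where(dx, t[:, 0], 1 - t[:, 0])
        for dy in (0, 1):
            wy = np.where(dy, t[:, 1], 1 - t[:, 1])
            for dz in (0, 1):
                wz = np.where(dz, t[:, 2], 1 - t[:, 2])
                np.add.at(
                    charge,
                    (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz),
                    q * wx * wy * wz,
                )
    total = charge.sum()
    if abs(total - molecule.total_charge()) > 0.01:
        raise RuntimeError("gridded charge does not match molecule charge")
    return FieldMaps(grid, eps, lam, charge)


def analytic_dh_sphere(
    total_charge: float, radius: float, electrolyte: ElectrolyteSpec, r
) -> np.ndarray | float:
    """Debye-Hückel potential (kT/e) outside a charged sphere.

    phi(r) = l_B q exp(-kappa (r - R)) / ( r (1 + kappa R) ), valid for
    r >= R with an ion-free interior and central/surface charge q.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < radius):
        raise ValueError("analytic DH sphere is defined only for r >= radius")
    lB = electrolyte.bjerrum_length()
    kappa = electrolyte.kappa()
    out = lB * total_charge * np.exp(-kappa * (r_arr - radius)) / (
        r_arr * (1.0 + kappa * radius)
    )
    return out if out.shape else float(out)


def dh_potential_field(
    grid: Grid3D,
    molecule: Molecule,
    electrolyte: ElectrolyteSpec,
    size_corrected: bool = True,
    min_distance: float = 1e-6,
) -> np.ndarray:
    """Screened-Coulomb superposition over atoms, evaluated at every node.

    Used both as the Dirichlet boundary condition and as the initial
    guess of the iterative solver.  With ``size_corrected`` each atom uses
    the finite-size Debye-Hückel form (the ``analytic_dh_sphere``
    amplitude); otherwise the point form l_B q exp(-kappa d)/d.
    Distances are floored inside each atom to its radius (or
    ``min_distance``) so interior nodes get finite values.
    """
    lB = electrolyte.bjerrum_length()
    kappa = electrolyte.kappa()
    ax = grid.axes()
    X = ax[0][:, None, None]
    Y = ax[1][None, :, None]
    Z = ax[2][None, None, :]
    phi = np.zeros(grid.shape, dtype=float)
    for atom in molecule.atoms:
        if atom.charge == 0.0:
            continue
        d = np.sqrt(
            (X - atom.position[0]) ** 2
            + (Y - atom.position[1]) ** 2
            + (Z - atom.position[2]) ** 2
        )
        R = max(atom.radius, min_distance)
        np.maximum(d, R, out=d)
        if size_corrected and atom.radius > 0:
            amp = atom.charge * lB / (1.0 + kappa * atom.radius)
            phi += amp * np.exp(-kappa * (d - atom.radius)) / d
        else:
            phi += atom.charge * lB * np.exp(-kappa * d) / d
    return phi


def dh_boundary(
    grid: Grid3D,
    molecule: Molecule,
    electrolyte: ElectrolyteSpec,
    size_corrected: bool = True,
) -> np.ndarray:
    """Dirichlet boundary values (kT/e) on the six grid faces.

    Returns a full-shape array whose interior is zero and whose boundary
    nodes hold the screened-Coulomb superposition.  Raises if a boundary
    node coincides with an atom center.
    """
    pos = molecule.positions()
    ax = grid.axes()
    lo = np.array(grid.origin)
    hi = grid.upper_corner()
    on_face = np.zeros(len(pos), dtype=bool)
    for d in range(3):
        on_face |= np.isclose(pos[:, d], lo[d]) | np.isclose(pos[:, d], hi[d])
    inside = np.all((pos >= lo) & (pos <= hi), axis=1)
    if np.any(on_face & inside):
        raise ValueError("boundary node coincident with an atom center")
    full = dh_potential_field(grid, molecule, electrolyte, size_corrected)
    out = np.zeros(grid.shape, dtype=float)
    for d in range(3):
        sl_lo = [slice(None)] * 3
        sl_lo[d] = 0
        sl_hi = [slice(None)] * 3
        sl_hi[d] = -1
        out[tuple(sl_lo)] = full[tuple(sl_lo)]
        out[tuple(sl_hi)] = full[tuple(sl_hi)]
    return out


def _solve_pb(
    maps: FieldMaps,
    electrolyte: ElectrolyteSpec,
    tolerance: float,
    max_iterations: int,
    linear: bool,
    phi_init: np.ndarray | None,
    omega: float,
    exp_cap: float,
    warmup_sweeps: int,
    max_newton_step: float,
) -> PBSolution:
    grid = maps.grid
    h = grid.spacing
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    eps = maps.dielectric
    lam = maps.accessibility
    alpha = 4.0 * math.pi * electrolyte.bjerrum_length() * electrolyte.eps_solvent
    z = electrolyte.valences()
    c = electrolyte.number_densities()

    phi = (
        np.zeros(grid.shape, dtype=float)
        if phi_init is None
        else np.array(phi_init, dtype=float)
    )
    if phi.shape != grid.shape:
        raise ValueError("phi_init shape does not match grid")

    # harmonic-mean face dielectrics
    ex = 2.0 * eps[:-1] * eps[1:] / (eps[:-1] + eps[1:])
    ey = 2.0 * eps[:, :-1] * eps[:, 1:] / (eps[:, :-1] + eps[:, 1:])
    ez = 2.0 * eps[:, :, :-1] * eps[:, :, 1:] / (eps[:, :, :-1] + eps[:, :, 1:])
    W = ex[:-1, 1:-1, 1:-1]
    E = ex[1:, 1:-1, 1:-1]
    S_ = ey[1:-1, :-1, 1:-1]
    N_ = ey[1:-1, 1:, 1:-1]
    B = ez[1:-1, 1:-1, :-1]
    F_ = ez[1:-1, 1:-1, 1:]
    inv_h2 = 1.0 / (h * h)
    diag0 = (W + E + S_ + N_ + B + F_) * inv_h2

    lam_i = lam[1:-1, 1:-1, 1:-1]
    src = alpha * maps.fixed_charge[1:-1, 1:-1, 1:-1] / grid.voxel_volume()

    ii, jj, kk = np.indices(diag0.shape)
    masks = [((ii + jj + kk) % 2) == p for p in (0, 1)]
    # linearized screening term: lam * sum z^2 c  (exact for the LPB)
    lin_diag = alpha * lam_i * float(np.sum(z * z * c))

    residual_history: list[float] = []
    residual = math.inf
    it = 0
    for it in range(1, max_iterations + 1):
        om = 1.0 if it <= warmup_sweeps else omega
        residual = 0.0
        for mask in masks:
            phi_c = phi[1:-1, 1:-1, 1:-1]
            nb = (
                W * phi[:-2, 1:-1, 1:-1]
                + E * phi[2:, 1:-1, 1:-1]
                + S_ * phi[1:-1, :-2, 1:-1]
                + N_ * phi[1:-1, 2:, 1:-1]
                + B * phi[1:-1, 1:-1, :-2]
                + F_ * phi[1:-1, 1:-1, 2:]
            ) * inv_h2
            if linear:
                res = (diag0 + lin_diag) * phi_c - nb - src
                dphi = res / (diag0 + lin_diag)
            else:
                S = np.zeros_like(phi_c)
                Sp = np.zeros_like(phi_c)
                for zi, ci in zip(z, c):
                    b = np.exp(np.clip(-zi * phi_c, -exp_cap, exp_cap))
                    S += zi * ci * b
                    Sp += zi * zi * ci * b
                res = diag0 * phi_c - nb - src - alpha * lam_i * S
                dphi = res / (diag0 + alpha * lam_i * Sp)
                if np.isfinite(max_newton_step):
                    # Damp only ion-accessible nodes: the exponential lives
                    # there, while the ion-free interior is a linear Poisson
                    # region whose potential may legitimately be huge.
                    clipped = np.clip(dphi, -max_newton_step, max_newton_step)
                    dphi = np.where(lam_i > 0, clipped, dphi)
            step = om * dphi[mask]
            phi_c[mask] -= step
            if step.size:
                residual = max(residual, float(np.abs(step).max()))
        residual_history.append(residual)
        if residual <= tolerance:
            break
    converged = residual <= tolerance
    if not converged:
        warnings.warn(
            f"PB solver did not converge in {max_iterations} sweeps "
            f"(final max update {residual:.3e} kT/e)",
            stacklevel=3,
        )
    return PBSolution(
        phi=phi,
        maps=maps,
        electrolyte=electrolyte,
        residual=residual,
        iterations=it,
        converged=converged,
        tolerance=tolerance,
        linear=linear,
        residual_history=residual_history,
    )


def solve_nlpb(
    maps: FieldMaps,
    electrolyte: ElectrolyteSpec,
    tolerance: float = 1e-6,
    max_iterations: int = 5000,
    phi_init: np.ndarray | None = None,
    omega: float = 1.8,
    exp_cap: float = 85.0,
    warmup_sweeps: int = 10,
    max_newton_step: float = 0.5,
) -> PBSolution:
    """Solve the nonlinear PB equation by damped Newton-Gauss-Seidel.

    Red-black over-relaxed sweeps; convergence is declared when the
    largest node update in a sweep falls below ``tolerance`` (kT/e).
    Non-convergence returns a flagged solution rather than raising.
    Exponentials are capped at ``exp_cap`` during iteration only.
    """
    return _solve_pb(
        maps, electrolyte, tolerance, max_iterations, False, phi_init,
        omega, exp_cap, warmup_sweeps, max_newton_step,
    )


def solve_lpb(
    maps: FieldMaps,
    electrolyte: ElectrolyteSpec,
    tolerance: float = 1e-6,
    max_iterations: int = 5000,
    phi_init: np.ndarray | None = None,
    omega: float = 1.8,
    warmup_sweeps: int = 0,
) -> PBSolution:
    """Linearized (Debye-Hückel) variant of :func:`solve_nlpb`."""
    return _solve_pb(
        maps, electrolyte, tolerance, max_iterations, True, phi_init,
        omega, 85.0, warmup_sweeps, math.inf,
    )


def write_dx(
    data: np.ndarray, grid: Grid3D, stream: IO[str] | str, name: str = "potential"
) -> None:
    """Export a scalar grid in OpenDX format (APBS-compatible)."""
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_dx(data, grid, fh, name)
        return
    nx, ny, nz = grid.shape
    h = grid.spacing
    stream.write(f"# {name} exported by ioncount\n")
    stream.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
    stream.write("origin {:.6e} {:.6e} {:.6e}\n".format(*grid.origin))
    stream.write(f"delta {h:.6e} 0.000000e+00 0.000000e+00\n")
    stream.write(f"delta 0.000000e+00 {h:.6e} 0.000000e+00\n")
    stream.write(f"delta 0.000000e+00 0.000000e+00 {h:.6e}\n")
    stream.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
    stream.write(
        f"object 3 class array type double rank 0 items {data.size} data follows\n"
    )
    flat = data.ravel(order="C")
    for i in range(0, flat.size, 3):
        stream.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
    stream.write(f'attribute "dep" string "positions"\n')
    stream.write(f'object "{name}" class field\n')
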