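# Methods

## Model

The package treats a macromolecule as a set of point charges with
hard-sphere radii in an implicit-solvent electrolyte, and solves the
mean-field (Poisson–Boltzmann) problem for the dimensionless potential
φ = eψ/kT on a uniform Cartesian grid:

    ∇·(ε(r) ∇φ) = −4π l_B ε_s [ ρ_f(r) + λ(r) Σ_i z_i ρ_b,i e^(−z_i φ) ]

with lengths in Å, fixed charge density ρ_f in e/Å³, bulk ion densities
ρ_b,i in ions/Å³ (mol/L × 6.02214×10⁻⁴), and the Bjerrum length
l_B = e²/(4πε₀ ε_s kT) ≈ 7.19 Å in water (ε_s = 78) at 298.15 K.
Linearizing the Boltzmann term recovers the Debye–Hückel (DH) equation
with κ² = 8π l_B I.

Assumptions inherited from PB theory: ions are point-like (beyond a
single Stern exclusion radius), correlations and ion–ion excluded volume
are neglected, the solvent is a structureless dielectric. These are
known to be adequate for monovalent atmospheres and qualitative for
divalent ones; quantitative energetics in strongly correlated regimes
are outside the model's reliable range.

## Discretization and maps

* Node-centered uniform grid; 7-point stencil; harmonic-mean face
  dielectrics; atom charges spread trilinearly onto the 8 surrounding
  nodes (conserves total charge exactly).
* Solute dielectric region: union of atom spheres inflated by the
  solvent probe radius (default 1.4 Å) — an inflated-sphere
  approximation of the solvent-excluded surface, without re-entrant
  patches. Its effect is bounded by the grid-refinement property test
  (excess counts move < 2% when the spacing halves).
* Ion accessibility λ: 0 inside atom radius + shared Stern radius
  (default 2 Å for all species — whether that radius should be per-ion
  is ambiguous; a shared radius is implemented), 1 elsewhere.
* Boundary condition: Dirichlet values on the box faces from a screened
  Coulomb (DH) superposition over the atoms, using the finite-size
  sphere amplitude q l_B e^(−κ(d−R))/(d(1+κR)) per atom. The same field
  is used as the solver's initial guess, which typically halves the
  sweep count.

## Nonlinear iteration

Damped Newton–Gauss–Seidel: red-black ordered sweeps, one scalar Newton
step per node per visit, with successive over-relaxation (ω = 1.8) and
the per-visit update clipped to 0.5 kT/e *on ion-accessible nodes only*.
The clip is what keeps the sinh-type nonlinearity stable under
over-relaxation; it must not be applied in the ion-free interior, where
the equation is linear and potentials near point charges legitimately
reach thousands of kT/e (clipping there stalls convergence — found the
hard way). Exponentials are capped at |z φ| = 85 during iteration only;
converged solutions in the tested regimes never touch the cap.
Convergence is declared when the largest node update in a sweep falls
below 10⁻⁶ kT/e; non-convergence returns a flagged solution rather than
raising, and the CLI exits with code 2.

A linearized solver (`solve_lpb`) replaces the Boltzmann term by its
tangent at φ=0. Excess-ion integration applied to a linearized solution
uses the linearized density 1 − zφ by default, so counted ions stay
consistent with the field theory that produced the potential; this makes
weak-field identities exact (e.g. N_Na/N_Mg = c_Na/(2 c_Mg) in a mixed
divalent/monovalent bath).

## Excess counts and the two conventions

    N_i = ρ_b,i Σ_nodes ( λ e^(−z_i φ) − 1 ) h³        ("box")
    N_i = ρ_b,i Σ_nodes λ ( e^(−z_i φ) − 1 ) h³        ("atmosphere")

The box convention integrates over the entire simulation volume
including the ion-excluded interior (where the integrand is exactly −1);
it is what a buffer-equilibration experiment measures, since the
molecule's excluded volume genuinely depletes every species. The
atmosphere convention restricts the bulk reference to the ion-accessible
region. They differ per species by exactly ρ_b,i·V_excluded. For
strongly charged macromolecules (hundreds of e) the difference is a few
ions against hundreds and is immaterial. For weakly charged test bodies
it dominates: a −1 e sphere of radius 10 Å at 10 mM has
ρ_b·V_excl ≈ 0.044 ions, which would shift β₊ by −0.04 — so the
weak-field limiting values (β₊ = β₋ = 0.5; one Mg²⁺ per five Na⁺)
are statements about the *diffuse atmosphere* and are reported in the
atmosphere convention. Both conventions are always computed and stored;
the box convention is the default for reporting.

β coefficients are defined as magnitudes, β₊ = Σ_{z>0} z_i N_i/(−q) and
β₋ = Σ_{z<0} z_i N_i/(−q), so that β₊+β₋ = 1 and both lie in [0,1] for
molecules of either sign — for a positive molecule the roles of
accumulation and exclusion swap automatically. Mixed-valence cation
contributions are summed valence-weighted with no further weighting.

## Box size, truncation and closure

The diffuse atmosphere has long tails: analytically (linear regime),
the neutralizing charge outside a cube of half-width 3κ⁻¹ is ~12%, and
~5% outside 4κ⁻¹; only around 6κ⁻¹ does it fall below 1%. The pipeline
therefore defaults to **6 Debye lengths of padding**, at which the
charge-neutrality closure |q + Σ z_i N_i| stays below 1%·|q| in the test
fixtures (strongly charged molecules close better still, their
atmospheres being more compact). The integrator warns whenever the
outermost node shell contributes more than 0.5% of any N_i.

## Geometry conventions

* B-form duplexes: one −1 e site per phosphodiester phosphate (no
  5′-terminal phosphates), so an L-bp duplex carries −2(L−1) e — the
  standard formal-charge bookkeeping that gives −292 e for a 147 bp
  duplex. Helix constants: rise 3.4 Å/bp, twist 36°/bp, phosphate radial
  distance 9.4 Å, strand phase offset 154°; all configurable. Phosphate
  level j sits at height 3.4·j, so the end-to-end span is exactly
  rise·(L−1).
* Protein formal charges at pH ≈ 7.5: Arg/Lys +1, His 0, Asp/Glu −1,
  termini +1/−1. The rule set is data-driven (`ProtonationRule`), so
  alternative protonation conventions are testable. With this rule the
  eight-chain histone octamer bookkeeping lands on +149 e; removing the
  two 25-residue H3 tails (8 positives each) gives +133 e against a
  published +132 e — a ±1 e discrepancy traceable to an unstated
  protonation convention, which we surface rather than force.
* PDB import places formal charges on charged-group center atoms
  (Arg CZ, Lys NZ, Asp CG, Glu CD, termini N/OXT, nucleic-acid P) and
  keeps all heavy atoms with tabulated radii for the excluded volume.

## Synthetic data

The generator emulates a BE-ICP-MS experiment with known ground truth:
C_sample = C_bulk + N_i·C_molecule per element, then multiplicative
Gaussian noise of coefficient of variation 2% — the order of precision
an ICP-MS quality-control series typically shows; the true instrument CV
is not published, so this default is an assumption and is configurable.
The noise enters as a *calibration factor shared by the sample and
flow-through channels* of an element within a replicate (plus an
independent factor on the molecule/phosphorus channel): calibration
drift is common-mode in a same-run difference measurement, which is
precisely why ion counting by concentration differences achieves
few-ion replicate scatter while the absolute QC precision is only ~2%.
Fully independent per-concentration noise would inflate the
per-replicate count SD to tens of ions — an order of magnitude beyond
what such experiments report — and is available separately
(`independent_cv`) for robustness studies. Replicates default to 8
(two repeats on each of four days, mirroring measurement on 2–4
independent days); an optional shared per-day multiplicative offset is
off by default and cancels in the reduction by construction. Negative
generated concentrations are resampled with a warning.

What a green synthetic-recovery test establishes: that the reduction
pipeline inverts the generator's model (ratio arithmetic, replicate
statistics, error propagation) at realistic noise. What it does not
establish: anything about filter losses, instrument calibration drift,
memory effects, or molecule-concentration bias in a real experiment —
those are wet-lab QC concerns the generator deliberately does not model.

Replicate reduction reports per-element means and sample SDs (ddof = 1;
SD is reported as 0 for a single replicate), q = −Σ z_i N̄_i with
quadrature error, and β from mean counts with first-order (delta-method)
propagation. Whether published β uncertainties are per-replicate SDs or
propagated from mean counts is generally ambiguous, so both are emitted
(`beta_plus_sd` vs `beta_plus_replicate_sd`).

## Numerical edge cases and tie-breaks

* Neutral molecule: φ ≡ 0 exactly (zero source, zero boundary); the
  atmosphere-convention counts are exactly 0 and the box convention
  reports exactly the excluded-volume depletion.
* β is undefined (raises) for q = 0.
* Competition ratios require both species' excess positive.
* Grids are at least 17 nodes per axis; a configurable node cap guards
  against accidental huge allocations, and sub-2-Debye-length padding is
  rejected (warned below 3).
* The 1 bp "duplex" has no phosphodiester linkage: it is represented as
  a single neutral site.

## Known limitations

* Mean-field PB: no ion–ion correlations, no size-modified variants; the
  divalent competition numbers are qualitative at high charge density.
* The solvent-excluded region is an inflated-sphere surface, not a true
  re-entrant molecular surface.
* Single-grid solver (no multigrid/focusing hierarchy); large molecules
  at fine spacing are slow.
* The idealized B-form builder places phosphates only — it is a
  formal-charge scaffold, not an atomic model; atomic PQR input is the
  route for full structures.
* A published free-147-bp-DNA Mg:Na ratio of 1.15 alongside counts of
  95.0 Mg²⁺ and 81.0 Na⁺ (quotient ≈ 1.17) presumably reflects
  replicate-wise averaging; the reduction here reports both the ratio of
  mean counts and per-replicate statistics, and does not attempt to
  reconcile the two.
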