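# ioncount

Ion counting around charged biomolecules: a nonlinear Poisson–Boltzmann
(NLPB) pipeline that predicts the composition of the ion atmosphere —
excess ion counts, charge-neutralization fractions, divalent:monovalent
competition — plus the data reduction for buffer-equilibration ICP-MS
(BE-ICP-MS) ion-counting experiments.

## Who this is for

Biophysicists studying the electrostatics of nucleic acids, nucleosomes
and other polyelectrolytes. A charged macromolecule in electrolyte is
always wrapped in a diffuse *ion atmosphere* that exactly neutralizes its
charge q: counterions accumulate and coions are depleted. *How* that
neutralization is split is a direct readout of the molecule's
electrostatic field. For a molecule of low charge density the split is
even; for a strong polyelectrolyte like DNA, counterion accumulation
dominates. BE-ICP-MS measures this split element-by-element; PB theory
predicts it. This package implements both arms so they can be compared
on the same footing.

## The quantities

For each ion species *i* with valence *z_i* and bulk density ρ_b,i, the
excess number per molecule is

    N_i = ρ_b,i ∫ ( λ(r) e^(−z_i φ(r)) − 1 ) dV

where φ is the electrostatic potential in kT/e from the nonlinear PB
equation ∇·(ε∇φ) = −4π l_B ε_s (ρ_f + λ Σ_i z_i ρ_b,i e^(−z_i φ)) and
λ(r) ∈ {0,1} marks the ion-accessible region. Charge neutrality requires
Σ_i z_i N_i = −q. The neutralization fractions

    β₊ = Σ_{z>0} z_i N_i / (−q),    β₋ = Σ_{z<0} z_i N_i / (−q)

satisfy β₊ + β₋ = 1; β₊ = β₋ = 0.5 is the weak-field limit, while
β₊ → 1 signals strong counterion condensation (for a negatively charged
molecule). Experimentally, N_i = (C_i^sample − C_i^bulk) / C_molecule
from equilibrated-sample vs flow-through concentrations.

## Worked example

Count ions around a weakly charged test sphere (−1 e, radius 10 Å) in
10 mM NaBr:

```python
from ioncount import ElectrolyteSpec, build_sphere_molecule
from ioncount.atmosphere import pb_ion_count, beta_from_excess

mol = build_sphere_molecule(10.0, -1.0)
salt = ElectrolyteSpec.monovalent(0.010)          # 10 mM NaBr
solution, excess = pb_ion_count(mol, salt, spacing=4.9,
                                convention="atmosphere")
beta = beta_from_excess(excess)
print({k: round(v, 3) for k, v in excess.n_excess.items()})
print(round(beta.beta_plus, 3), round(beta.beta_minus, 3))
```

prints

```
{'Na': 0.513, 'Br': -0.482}
0.513 0.482
```

i.e. about half an Na⁺ accumulated and half a Br⁻ excluded per unit of
molecule charge — the even split (β ≈ 0.5) expected for a low
charge-density molecule. Rebuilding the sphere with −50 e instead drives
β₊ above 0.8: counterion accumulation takes over as the field strengthens.

The same numbers come from the command line:

```sh
ioncount fixtures --out-dir fixtures/
ioncount pb-count --structure fixtures/weak_sphere.pqr \
    --salt Na:+1:10mM --salt Br:-1:10mM --spacing 4.9 \
    --convention atmosphere --out-dir run1/
```

and the experimental arm reduces a BE-ICP-MS concentration table
(`ioncount simulate` generates synthetic ones with known ground truth):

```sh
ioncount simulate --spec spec.yaml --out table.csv
ioncount reduce --table table.csv --out-dir reduced/
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch, (t1) the net formal charge of the 147 bp
Widom-601 duplex by counting phosphodiester phosphates on the printed
sequence, and (t2) the weak-field limiting β₊ of a −1 e sphere in 10 mM
1:1 salt from the full NLPB + excess-ion pipeline, and writes them as
JSON.

## Layout

- `ioncount.geometry` — charged structures: test spheres, idealized
  B-form duplexes from sequence, PQR I/O, PDB + formal-charge rules
- `ioncount.pb_engine` — grids, dielectric/accessibility/charge maps,
  Debye–Hückel boundaries, nonlinear and linearized PB solvers, OpenDX
  export
- `ioncount.atmosphere` — excess-ion integration, β coefficients,
  competition ratios, assembly ion uptake/release
- `ioncount.icp_reduction` — BE-ICP-MS table reduction with replicate
  statistics and error propagation
- `ioncount.synthetic_data` — synthetic ICP tables with known ground
  truth; packaged reference molecules
- `ioncount.cli` — the `ioncount` command (pb-count / reduce / simulate /
  fixtures)

See `docs/methods.md` for the model, its assumptions and numerical
choices.
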