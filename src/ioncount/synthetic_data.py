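"""Synthetic BE-ICP-MS datasets and reference molecule fixtures.

The generator emulates what a buffer-equilibration ICP-MS experiment
would report for a molecule with known ground-truth excess counts: for
each replicate and element it sets

    C_sample = C_bulk + N_i * C_molecule,

then perturbs the reported concentrations with multiplicative Gaussian
noise of a given coefficient of variation (the instrument's quality-
control precision; default 2%).  The dominant instrument error is
calibration drift, which is common to the sample and flow-through
channels of an element measured in the same run — so the per-element
noise factor is *shared* between the two roles within a replicate and
largely cancels in the concentration difference, while the molecule
(phosphorus) channel carries its own factor.  This correlation structure
is what makes difference-based ion counting far more precise than the
absolute QC figure suggests, and it reproduces replicate scatter of the
order actually reported for such experiments (a few ions per molecule,
not the tens that fully independent 2% errors would imply).  Fully
independent per-concentration noise can be added via ``independent_cv``.

The replicate structure mirrors typical practice — repeated measurements
spread over 2-4 independent days — and an optional shared per-day
multiplicative offset models day effects.  Noiseless output inverts
exactly under the reduction pipeline, which is the basis of the
end-to-end recovery tests.

``make_reference_fixtures`` emits a small set of PQR test molecules
(weak and strong spheres, a 24 bp duplex, the 147 bp Widom-601 duplex)
with a manifest of their expected invariants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .geometry import (
    WIDOM_601,
    Molecule,
    SequenceRecord,
    build_bform_duplex,
    build_sphere_molecule,
    write_pqr,
)

__all__ = ["SyntheticSpec", "simulate_icpms_dataset", "make_reference_fixtures"]


@dataclass
class SyntheticSpec:
    """Ground truth and noise model for one synthetic dataset."""

    true_excess: dict[str, float]          # ions/molecule per element
    bulk_mM: dict[str, float]              # flow-through concentration
    molecule_mM: float = 0.010
    cv: float | Mapping[str, float] = 0.02  # calibration CV per element
    independent_cv: float = 0.0            # extra per-concentration noise
    n_replicates: int = 8                  # e.g. two repeats on four days
    n_days: int = 4
    day_effect_cv: float = 0.0             # shared per-day offset (off)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.molecule_mM <= 0:
            raise ValueError("molecule concentration must be positive")
        if set(self.true_excess) != set(self.bulk_mM):
            raise ValueError("true_excess and bulk_mM must cover the same elements")
        for e, c in self.bulk_mM.items():
            if c <= 0:
                raise ValueError(f"bulk concentration for {e} must be positive")
        if any(v < 0 for v in self._cv_map().values()) or self.day_effect_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.independent_cv < 0:
            raise ValueError("noise CV must be non-negative")

    def _cv_map(self) -> dict[str, float]:
        if isinstance(self.cv, Mapping):
            return {e: float(self.cv.get(e, 0.0)) for e in self.true_excess}
        return {e: float(self.cv) for e in self.true_excess}


def _noisy(rng: np.random.Generator, value: float, cv: float, what: str) -> float:
    """Multiplicative Gaussian perturbation; resample if non-positive."""
    if cv == 0.0:
        return value
    for _ in range(100):
        out = value * (1.0 + cv * rng.standard_normal())
        if out > 0:
            return out
    warnings.warn(f"resampling failed to produce a positive {what}; clamping")
    return abs(value) * 1e-6


def simulate_icpms_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a synthetic ICP table in the reduction dialect.

    Per replicate: the true sample concentration is C_bulk + N_i *
    C_molecule; each element's reported sample and bulk concentrations
    share one multiplicative calibration factor (CV ``spec.cv``), the
    molecule concentration carries its own, and ``independent_cv`` adds
    per-concentration independent noise on top.  Deterministic under a
    fixed seed.  Returns a DataFrame with columns element, role,
    concentration_mM, replicate, day, molecule_conc_mM.
    """
    rng = np.random.default_rng(spec.seed)
    cvs = spec._cv_map()
    mol_cv = float(np.mean(list(cvs.values()))) if cvs else 0.0
    day_factors = (
        1.0 + spec.day_effect_cv * rng.standard_normal(spec.n_days)
        if spec.day_effect_cv > 0
        else np.ones(spec.n_days)
    )
    rows = []
    for rep in range(spec.n_replicates):
        day = rep % spec.n_days
        rep_id = f"r{rep + 1:02d}"
        day_id = f"d{day + 1}"
        c_mol_true = spec.molecule_mM * day_factors[day]
        c_mol = _noisy(rng, c_mol_true, mol_cv, "molecule concentration")
        for element in sorted(spec.true_excess):
            c_bulk_true = spec.bulk_mM[element] * day_factors[day]
            c_sample_true = c_bulk_true + spec.true_excess[element] * c_mol_true
            if c_sample_true <= 0:
                raise ValueError(
                    f"ground truth gives negative sample concentration for {element}"
                )
            calibration = _noisy(rng, 1.0, cvs[element], "calibration factor")
            c_bulk = _noisy(
                rng, c_bulk_true * calibration, spec.independent_cv,
                "bulk concentration",
            )
            c_sample = _noisy(
                rng, c_sample_true * calibration, spec.independent_cv,
                "sample concentration",
            )
            for role, conc in (("sample", c_sample), ("bulk", c_bulk)):
                rows.append(
                    {
                        "element": element,
                        "role": role,
                        "concentration_mM": conc,
                        "replicate": rep_id,
                        "day": day_id,
                        "molecule_conc_mM": c_mol,
                    }
                )
    return pd.DataFrame(rows)


def reference_molecules() -> dict[str, Molecule]:
    """The four packaged test molecules, built programmatically."""
    return {
        "weak_sphere": build_sphere_molecule(10.0, -1.0, 1),
        "strong_sphere": build_sphere_molecule(10.0, -50.0, 1),
        "duplex_24bp": build_bform_duplex(
            SequenceRecord("dna24", "GGTGACGAGTGAGCTACTGGGCGG", "dna")
        ),
        "duplex_601": build_bform_duplex(SequenceRecord("widom601", WIDOM_601, "dna")),
    }


def make_reference_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the reference molecules as PQR plus a YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mols = reference_molecules()
    manifest: dict[str, dict] = {}
    paths: list[Path] = []
    for name, mol in mols.items():
        path = out / f"{name}.pqr"
        write_pqr(mol, str(path))
        paths.append(path)
        manifest[name] = {
            "file": path.name,
            "formal_charge_e": mol.formal_charge,
            "n_atoms": len(mol.atoms),
            "expected": _expected_invariants(name),
        }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"fixtures": manifest}, fh, sort_keys=True)
    paths.append(manifest_path)
    return paths


def _expected_invariants(name: str) -> dict:
    expected = {
        "weak_sphere": {
            "beta_plus_atmosphere": "0.50 +/- 0.02 in dilute 1:1 salt (weak-field limit)",
        },
        "strong_sphere": {
            "beta_plus": "> 0.5 (counterion condensation regime)",
        },
        "duplex_24bp": {
            "formal_charge_e": -46,
            "end_to_end_A": 78.2,
        },
        "duplex_601": {
            "formal_charge_e": -292,
        },
    }
    return expected[name]
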