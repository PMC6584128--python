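"""Reduction of buffer-equilibration ICP-MS concentration tables.

A buffer-equilibration ICP-MS (BE-ICP-MS) experiment equilibrates a
macromolecule-containing sample against bulk buffer across a centrifugal
filter and then measures, per element, the ion concentration in the
retentate (C_sample) and in the flow-through (C_bulk).  The excess
number of ions of species i per molecule is

    N_i = (C_i^sample - C_i^bulk) / C_molecule,

positive for accumulated counterions and negative for excluded coions.
The molecule concentration comes from the phosphorus channel for nucleic
acids and nucleosomes (C_molecule = C_P / phosphates per molecule) or is
supplied externally (A280) for proteins.

Replicates (repeated measurements on independent days) are reduced to
per-element means and standard deviations; the atmosphere charge
q = -sum z_i N_i and the neutralization fractions beta follow with
first-order (delta-method) error propagation, alongside the raw
replicate SD of the per-replicate derived values.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IcpSample",
    "IcpMeasurement",
    "ReducedResult",
    "DEFAULT_VALENCES",
    "excess_from_concentrations",
    "molecule_conc_from_phosphorus",
    "reduce_replicates",
    "read_icp_table",
    "measurements_to_table",
    "write_reduced",
]

#: Formal valences of the elements commonly assayed.
DEFAULT_VALENCES: dict[str, int] = {
    "Li": +1, "Na": +1, "K": +1, "Rb": +1, "Cs": +1,
    "Mg": +2, "Ca": +2, "Sr": +2, "Ba": +2,
    "F": -1, "Cl": -1, "Br": -1, "I": -1,
}

REQUIRED_COLUMNS = (
    "element",
    "role",
    "concentration_mM",
    "replicate",
    "day",
    "molecule_conc_mM",
)


@dataclass
class IcpSample:
    """One element channel of one equilibrated replicate."""

    element: str
    c_sample_mM: float
    c_bulk_mM: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.c_sample_mM < 0 or self.c_bulk_mM < 0:
            raise ValueError("concentrations must be non-negative")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")


@dataclass
class IcpMeasurement:
    """All element channels of one replicate on one day."""

    samples: list[IcpSample]
    c_molecule_mM: float
    replicate: str
    day: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c_molecule_mM <= 0:
            raise ValueError("molecule concentration must be positive")
        if not self.samples:
            raise ValueError("measurement needs at least one element channel")

    def elements(self) -> tuple[str, ...]:
        return tuple(s.element for s in self.samples)

    def excess(self) -> dict[str, float]:
        return {
            s.element: excess_from_concentrations(s, self.c_molecule_mM)
            for s in self.samples
        }


@dataclass
class ReducedResult:
    """Replicate-averaged excess counts with errors and derived quantities."""

    elements: tuple[str, ...]
    valences: dict[str, int]
    n_mean: dict[str, float]
    n_sd: dict[str, float]          # replicate SD (0.0 when n < 2)
    n_replicates: int
    q: float
    q_sd: float                     # quadrature propagation of n_sd
    beta_plus: float
    beta_minus: float
    beta_plus_sd: float             # first-order propagated
    beta_minus_sd: float
    beta_plus_replicate_sd: float   # SD of per-replicate beta values
    beta_minus_replicate_sd: float

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "valences": dict(self.valences),
            "n_mean": dict(self.n_mean),
            "n_sd": dict(self.n_sd),
            "n_replicates": self.n_replicates,
            "q": self.q,
            "q_sd": self.q_sd,
            "beta_plus": self.beta_plus,
            "beta_minus": self.beta_minus,
            "beta_plus_sd": self.beta_plus_sd,
            "beta_minus_sd": self.beta_minus_sd,
            "beta_plus_replicate_sd": self.beta_plus_replicate_sd,
            "beta_minus_replicate_sd": self.beta_minus_replicate_sd,
        }


def excess_from_concentrations(sample: IcpSample, c_molecule_mM: float) -> float:
    """N_i = (C_sample - C_bulk) / C_molecule, signed ions per molecule."""
    if c_molecule_mM <= 0:
        raise ValueError("molecule concentration must be positive")
    return (sample.c_sample_mM - sample.c_bulk_mM) / c_molecule_mM


def molecule_conc_from_phosphorus(
    c_phosphorus_mM: float, phosphates_per_molecule: int
) -> float:
    """Molecule concentration from the ICP-MS phosphorus channel."""
    if phosphates_per_molecule < 1:
        raise ValueError("phosphates_per_molecule must be >= 1")
    return c_phosphorus_mM / phosphates_per_molecule


def _beta_from_counts(
    n: Mapping[str, float], valences: Mapping[str, int]
) -> tuple[float, float, float]:
    """(beta_plus, beta_minus, q) from one set of counts."""
    cat = sum(valences[e] * n[e] for e in n if valences[e] > 0)
    an = sum(valences[e] * n[e] for e in n if valences[e] < 0)
    q = -(cat + an)
    if q == 0:
        raise ValueError("beta undefined: atmosphere closes to zero charge")
    return cat / (-q), an / (-q), q


def reduce_replicates(
    measurements: Sequence[IcpMeasurement],
    valences: Mapping[str, int] | None = None,
) -> ReducedResult:
    """Average excess counts over replicates and derive q and beta.

    Per-element means and sample standard deviations (ddof=1; reported as
    0.0 for a single replicate).  q = -sum z_i mean(N_i) with quadrature
    error; beta from the mean counts with first-order propagation, plus
    the raw SD of the per-replicate beta values.
    """
    if not measurements:
        raise ValueError("no measurements to reduce")
    elements = measurements[0].elements()
    for m in measurements[1:]:
        if set(m.elements()) != set(elements):
            raise ValueError(
                f"inconsistent element sets across replicates: "
                f"{sorted(elements)} vs {sorted(m.elements())}"
            )
    val = dict(DEFAULT_VALENCES)
    if valences:
        val.update(valences)
    missing = [e for e in elements if e not in val]
    if missing:
        raise ValueError(f"no valence known for element(s) {missing}")
    zs = {e: val[e] for e in elements}

    per_rep = [m.excess() for m in measurements]
    n_rep = len(per_rep)
    n_mean = {
        e: float(np.mean([r[e] for r in per_rep])) for e in elements
    }
    n_sd = {
        e: (float(np.std([r[e] for r in per_rep], ddof=1)) if n_rep >= 2 else 0.0)
        for e in elements
    }
    q = -sum(zs[e] * n_mean[e] for e in elements)
    q_sd = float(np.sqrt(sum((zs[e] * n_sd[e]) ** 2 for e in elements)))

    if q == 0:
        # beta is undefined for a neutral atmosphere; report NaN
        nan = float("nan")
        return ReducedResult(
            elements=elements, valences=zs, n_mean=n_mean, n_sd=n_sd,
            n_replicates=n_rep, q=0.0, q_sd=q_sd,
            beta_plus=nan, beta_minus=nan, beta_plus_sd=nan,
            beta_minus_sd=nan, beta_plus_replicate_sd=nan,
            beta_minus_replicate_sd=nan,
        )

    beta_plus, beta_minus, _ = _beta_from_counts(n_mean, zs)

    # first-order propagation: beta_+ = C/(C+A) with C = sum_{z>0} z N,
    # A = -sum_{z<0} z N  =>  dbeta_+/dN_e = z_e*A/(C+A)^2 (cations),
    #                         dbeta_+/dN_e = z_e*C/(C+A)^2 (anions, z_e<0)
    C = sum(zs[e] * n_mean[e] for e in elements if zs[e] > 0)
    A = -sum(zs[e] * n_mean[e] for e in elements if zs[e] < 0)
    tot = C + A
    var_bp = 0.0
    for e in elements:
        if zs[e] > 0:
            grad = zs[e] * A / tot**2
        else:
            grad = zs[e] * C / tot**2
        var_bp += (grad * n_sd[e]) ** 2
    beta_plus_sd = float(np.sqrt(var_bp))
    beta_minus_sd = beta_plus_sd  # beta_- = 1 - beta_+ to first order

    if n_rep >= 2:
        bp_reps = []
        bm_reps = []
        for r in per_rep:
            try:
                bp, bm, _ = _beta_from_counts(r, zs)
            except ValueError:  # single replicate closing to q = 0
                continue
            bp_reps.append(bp)
            bm_reps.append(bm)
        if len(bp_reps) >= 2:
            bp_rep_sd = float(np.std(bp_reps, ddof=1))
            bm_rep_sd = float(np.std(bm_reps, ddof=1))
        else:
            bp_rep_sd = bm_rep_sd = float("nan")
    else:
        bp_rep_sd = bm_rep_sd = 0.0

    return ReducedResult(
        elements=elements,
        valences=zs,
        n_mean=n_mean,
        n_sd=n_sd,
        n_replicates=n_rep,
        q=float(q),
        q_sd=q_sd,
        beta_plus=float(beta_plus),
        beta_minus=float(beta_minus),
        beta_plus_sd=beta_plus_sd,
        beta_minus_sd=beta_minus_sd,
        beta_plus_replicate_sd=bp_rep_sd,
        beta_minus_replicate_sd=bm_rep_sd,
    )


def read_icp_table(stream: IO[str] | str | pd.DataFrame) -> list[IcpMeasurement]:
    """Parse the CSV dialect into one IcpMeasurement per replicate.

    Columns: element, role (sample|bulk), concentration_mM, replicate,
    day, molecule_conc_mM; unknown columns are preserved in the
    measurement metadata.
    """
    if isinstance(stream, pd.DataFrame):
        table = stream.copy()
    else:
        table = pd.read_csv(stream)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ICP table is missing mandatory column(s): {missing}")
    bad_roles = set(table["role"].unique()) - {"sample", "bulk"}
    if bad_roles:
        raise ValueError(f"unknown role value(s) {sorted(bad_roles)}")
    extra_cols = [c for c in table.columns if c not in REQUIRED_COLUMNS]

    measurements: list[IcpMeasurement] = []
    for (rep, day), group in table.groupby(["replicate", "day"], sort=True):
        c_mol = group["molecule_conc_mM"].unique()
        if len(c_mol) != 1:
            raise ValueError(
                f"replicate {rep!r} day {day!r} has inconsistent molecule_conc_mM"
            )
        samples = []
        for element, chan in group.groupby("element", sort=True):
            c_s = chan.loc[chan["role"] == "sample", "concentration_mM"]
            c_b = chan.loc[chan["role"] == "bulk", "concentration_mM"]
            if len(c_s) != 1 or len(c_b) != 1:
                raise ValueError(
                    f"replicate {rep!r} day {day!r} element {element!r}: need "
                    "exactly one 'sample' and one 'bulk' row"
                )
            samples.append(
                IcpSample(str(element), float(c_s.iloc[0]), float(c_b.iloc[0]))
            )
        meta = {}
        if extra_cols:
            meta["extra_columns"] = {
                c: group[c].tolist() for c in extra_cols
            }
        measurements.append(
            IcpMeasurement(
                samples=samples,
                c_molecule_mM=float(c_mol[0]),
                replicate=str(rep),
                day=str(day),
                metadata=meta,
            )
        )
    if not measurements:
        raise ValueError("ICP table contains no measurements")
    return measurements


def measurements_to_table(measurements: Sequence[IcpMeasurement]) -> pd.DataFrame:
    """Inverse of :func:`read_icp_table` (canonical column order)."""
    rows = []
    for m in measurements:
        for s in m.samples:
            for role, conc in (("sample", s.c_sample_mM), ("bulk", s.c_bulk_mM)):
                rows.append(
                    {
                        "element": s.element,
                        "role": role,
                        "concentration_mM": conc,
                        "replicate": m.replicate,
                        "day": m.day,
                        "molecule_conc_mM": m.c_molecule_mM,
                    }
                )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_reduced(result: ReducedResult, stream: IO[str] | str) -> None:
    """Write a ReducedResult as a JSON summary."""
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_reduced(result, fh)
        return
    json.dump(result.to_dict(), stream, indent=2, sort_keys=True)
    stream.write("\n")
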