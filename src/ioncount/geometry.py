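"""Charged-structure construction and I/O.

Molecules enter the Poisson-Boltzmann pipeline as collections of point
atoms carrying a position (Å), a charge (e) and a hard-sphere radius (Å).
Three sources are supported:

* analytic test bodies (charged spheres),
* idealized B-form DNA duplexes built from sequence, with one -1 e site
  per phosphodiester phosphate (the standard formal-charge bookkeeping
  for nucleic acids: a 147 bp duplex carries 2*(147-1) = 292 negative
  charges because the synthetic strands carry no 5'-terminal phosphate),
* PQR files, or PDB files combined with a formal-charge protonation rule.

Formal protein charges follow the usual pH ~7.5 rule: Arg/Lys +1, His 0,
Asp/Glu -1, charged termini (+1 N, -1 C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "SequenceRecord",
    "ProtonationRule",
    "WIDOM_601",
    "HELIX_RISE",
    "HELIX_TWIST_DEG",
    "PHOSPHATE_RADIAL_DISTANCE",
    "build_sphere_molecule",
    "build_bform_duplex",
    "formal_charge_protein",
    "read_pqr",
    "write_pqr",
    "read_fasta",
    "assign_charges_from_pdb",
]

#: 147 bp Widom "601" nucleosome positioning sequence (sense strand).
WIDOM_601 = (
    "CTGGAGAATCCCGGTCTGCAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTACGCGCTGTCCC"
    "CCGCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGTCAGATATATACATCCTGT"
)

# Idealized B-form helix constants (configurable via build_bform_duplex).
HELIX_RISE = 3.4  # Å per base pair
HELIX_TWIST_DEG = 36.0  # degrees per base pair
PHOSPHATE_RADIAL_DISTANCE = 9.4  # Å, phosphate distance from helix axis
_STRAND_PHASE_DEG = 154.0  # angular offset of the second backbone (minor groove)
_PHOSPHATE_RADIUS = 2.0  # Å, hard-sphere radius of a phosphate site

_DNA_ALPHABET = set("ACGT")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class Atom:
    """A point charge with a hard-sphere radius."""

    position: np.ndarray
    charge: float
    radius: float
    name: str = ""
    residue: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if self.radius < 0:
            raise ValueError("atom radius must be non-negative")


@dataclass
class Molecule:
    """A set of atoms plus the integer formal charge they represent."""

    atoms: list[Atom]
    formal_charge: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("molecule must contain at least one atom")
        total = float(np.sum([a.charge for a in self.atoms]))
        if abs(total - self.formal_charge) > 0.01:
            raise ValueError(
                f"formal_charge {self.formal_charge} does not match summed "
                f"atom charges {total:.4f}"
            )

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def total_charge(self) -> float:
        return float(self.charges().sum())

    def charge_centroid(self) -> np.ndarray:
        """Centroid weighted by |charge|; geometric centroid if neutral."""
        q = np.abs(self.charges())
        pos = self.positions()
        if q.sum() <= 0:
            return pos.mean(axis=0)
        return (pos * q[:, None]).sum(axis=0) / q.sum()

    def centered(self) -> "Molecule":
        """Return a copy translated so the charge centroid sits at the origin."""
        shift = self.charge_centroid()
        atoms = [
            Atom(a.position - shift, a.charge, a.radius, a.name, a.residue)
            for a in self.atoms
        ]
        return Molecule(atoms, self.formal_charge, self.label)


@dataclass
class SequenceRecord:
    """A one-letter-coded nucleotide or amino-acid sequence."""

    id: str
    residues: str
    molecule_kind: str = "dna"  # "dna" | "protein"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace(" ", "").replace("\n", "")
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        if self.molecule_kind not in ("dna", "protein"):
            raise ValueError(f"unknown molecule_kind {self.molecule_kind!r}")
        alphabet = _DNA_ALPHABET if self.molecule_kind == "dna" else _PROTEIN_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise ValueError(
                f"invalid {self.molecule_kind} residue code(s): {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ProtonationRule:
    """Formal charges per residue and per terminus at a given pH regime.

    The default reproduces standard bookkeeping at pH 7.5: Arg and Lys
    protonated, His neutral, Asp and Glu deprotonated, both termini charged.
    """

    side_chain: Mapping[str, int] = field(
        default_factory=lambda: {"R": 1, "K": 1, "H": 0, "D": -1, "E": -1}
    )
    n_terminus: int = 1
    c_terminus: int = -1

    def residue_charge(self, code: str) -> int:
        if code not in _PROTEIN_ALPHABET:
            raise ValueError(f"unknown residue code {code!r}")
        return int(self.side_chain.get(code, 0))


def build_sphere_molecule(
    radius: float, total_charge: float, n_surface_points: int = 1,
    include_core: bool = False,
) -> Molecule:
    """Build a charged test sphere.

    With ``n_surface_points == 1`` the sphere is a single central atom of
    the given hard-sphere radius carrying the whole charge.  Otherwise the
    charge is split evenly over a Fibonacci lattice on the sphere surface;
    ``include_core`` then adds a neutral central atom of the full radius so
    the interior stays dielectric-excluded and ion-inaccessible (matching
    the analytic picture of a charged hard sphere).
    """
    if radius <= 0:
        raise ValueError("sphere radius must be positive")
    if n_surface_points < 1:
        raise ValueError("n_surface_points must be >= 1")
    if n_surface_points == 1:
        atoms = [Atom(np.zeros(3), float(total_charge), radius, name="SPH")]
    else:
        n = n_surface_points
        k = np.arange(n)
        # Fibonacci sphere: near-uniform tiling of the surface.
        golden = math.pi * (3.0 - math.sqrt(5.0))
        z = 1.0 - 2.0 * (k + 0.5) / n
        rho = np.sqrt(1.0 - z * z)
        theta = golden * k
        pts = radius * np.stack(
            [rho * np.cos(theta), rho * np.sin(theta), z], axis=1
        )
        q = float(total_charge) / n
        atoms = [Atom(p, q, 1.0, name="SPH") for p in pts]
        if include_core:
            atoms.append(Atom(np.zeros(3), 0.0, radius, name="COR"))
    return Molecule(atoms, int(round(total_charge)), label=f"sphere_{total_charge:+g}e")


def build_bform_duplex(
    sequence: SequenceRecord,
    rise: float = HELIX_RISE,
    twist_deg: float = HELIX_TWIST_DEG,
    phosphate_radius: float = PHOSPHATE_RADIAL_DISTANCE,
) -> Molecule:
    """Place the backbone phosphates of an idealized B-form duplex.

    An L-bp duplex has L-1 phosphodiester linkages per strand, each
    carrying one -1 e phosphate; 5'-terminal phosphates are absent, so the
    formal charge is -2(L-1).  Phosphates sit on two helices of radius
    ``phosphate_radius`` offset by the minor-groove angle, with base-pair
    level j at height ``rise * j``; the helix end-to-end length is
    ``rise * (L-1)``.
    """
    if sequence.molecule_kind != "dna":
        raise ValueError("build_bform_duplex requires a DNA sequence")
    L = len(sequence)
    twist = math.radians(twist_deg)
    phase = math.radians(_STRAND_PHASE_DEG)
    atoms: list[Atom] = []
    # Strand I runs 5'->3' with increasing z: phosphate j sits 5' of bp j+1.
    for j in range(1, L):
        theta = twist * j
        pos = (
            phosphate_radius * math.cos(theta),
            phosphate_radius * math.sin(theta),
            rise * j,
        )
        atoms.append(
            Atom(np.array(pos), -1.0, _PHOSPHATE_RADIUS, name="P",
                 residue=sequence.residues[j])
        )
    # Strand II is antiparallel; its phosphates occupy levels 0 .. L-2.
    for j in range(0, L - 1):
        theta = twist * j + phase
        pos = (
            phosphate_radius * math.cos(theta),
            phosphate_radius * math.sin(theta),
            rise * j,
        )
        atoms.append(
            Atom(np.array(pos), -1.0, _PHOSPHATE_RADIUS, name="P",
                 residue=_complement(sequence.residues[j]))
        )
    if L == 1:
        # A single base pair has no phosphodiester linkage; represent the
        # neutral stub as one uncharged site so the molecule is non-empty.
        atoms = [Atom(np.zeros(3), 0.0, _PHOSPHATE_RADIUS, name="BP",
                      residue=sequence.residues[0])]
    return Molecule(atoms, -2 * (L - 1), label=f"bdna_{sequence.id}")


def _complement(base: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[base]


def formal_charge_protein(
    sequences: Iterable[SequenceRecord],
    ph_rule: ProtonationRule | None = None,
    include_termini: bool = True,
) -> int:
    """Sum formal charges over protein chains.

    Each chain contributes its side-chain charges plus (optionally) one
    charged N- and C-terminus.  Additive over chains and independent of
    chain order.
    """
    rule = ph_rule or ProtonationRule()
    total = 0
    for rec in sequences:
        if rec.molecule_kind != "protein":
            raise ValueError(f"sequence {rec.id!r} is not a protein chain")
        total += sum(rule.residue_charge(c) for c in rec.residues)
        if include_termini:
            total += rule.n_terminus + rule.c_terminus
    return int(total)


# ---------------------------------------------------------------------------
# PQR I/O
# ---------------------------------------------------------------------------

def read_pqr(stream: IO[str] | str) -> Molecule:
    """Read a whitespace-delimited PQR file.

    Accepts the common dialect variants with or without a chain-id column:
    the last five fields of each ATOM/HETATM record are taken as
    x, y, z, charge, radius.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return read_pqr(fh)
    atoms: list[Atom] = []
    label = ""
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        tag = line.split(None, 1)[0]
        if tag == "REMARK":
            if "label:" in line:
                label = line.split("label:", 1)[1].strip()
            continue
        if tag in ("TER", "END"):
            continue
        if tag not in ("ATOM", "HETATM"):
            raise ValueError(f"malformed PQR line {lineno}: unknown record {tag!r}")
        fields = line.split()
        if len(fields) < 8:
            raise ValueError(f"malformed PQR line {lineno}: too few fields")
        try:
            x, y, z, q, r = (float(v) for v in fields[-5:])
        except ValueError as exc:
            raise ValueError(f"malformed PQR line {lineno}: {exc}") from None
        name = fields[2] if len(fields) > 2 else ""
        residue = fields[3] if len(fields) > 3 else ""
        atoms.append(Atom(np.array([x, y, z]), q, r, name=name, residue=residue))
    if not atoms:
        raise ValueError("PQR stream contained no atoms")
    return Molecule(atoms, int(round(sum(a.charge for a in atoms))), label=label)


def write_pqr(molecule: Molecule, stream: IO[str] | str) -> None:
    """Write a Molecule as whitespace-delimited PQR (lossless round trip)."""
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_pqr(molecule, fh)
        return
    if molecule.label:
        stream.write(f"REMARK label: {molecule.label}\n")
    stream.write("REMARK positions A, charge e, radius A\n")
    for i, a in enumerate(molecule.atoms, start=1):
        name = a.name or "X"
        res = a.residue or "UNK"
        stream.write(
            f"ATOM {i:6d} {name:<4s} {res:<4s} {i:5d} "
            f"{a.position[0]:12.4f} {a.position[1]:12.4f} {a.position[2]:12.4f} "
            f"{a.charge:10.4f} {a.radius:8.4f}\n"
        )
    stream.write("END\n")


def read_fasta(stream: IO[str] | str, molecule_kind: str = "dna") -> list[SequenceRecord]:
    """Read sequences from FASTA via Biopython."""
    from Bio import SeqIO

    handle = open(stream) if isinstance(stream, str) else stream
    try:
        return [
            SequenceRecord(rec.id, str(rec.seq), molecule_kind)
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if isinstance(stream, str):
            handle.close()


# ---------------------------------------------------------------------------
# PDB -> formal-charge molecule
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_NUCLEIC_RESIDUES = {"DA", "DC", "DG", "DT", "A", "C", "G", "T", "U", "DU"}
# Atom on which the formal charge of a charged group is centered.
_CHARGE_SITE = {"R": "CZ", "K": "NZ", "D": "CG", "E": "CD"}

DEFAULT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.90, "H": 1.20,
}
_DEFAULT_RADIUS = 1.70


def assign_charges_from_pdb(
    stream: IO[str] | str,
    ph_rule: ProtonationRule | None = None,
    radii_table: Mapping[str, float] | None = None,
    include_termini: bool = True,
    label: str = "",
) -> Molecule:
    """Build a formal-charge Molecule from a PDB file.

    Charges are placed on the charged-group center atoms (Arg CZ, Lys NZ,
    Asp CG, Glu CD, termini, nucleic-acid P); all other heavy atoms enter
    with zero charge and a tabulated radius so the solvent-excluded volume
    is preserved.  The resulting formal charge equals the formal charge of
    the same composition computed from sequence.
    """
    from Bio.PDB import PDBParser

    rule = ph_rule or ProtonationRule()
    radii = dict(DEFAULT_RADII)
    if radii_table:
        radii.update(radii_table)

    parser = PDBParser(QUIET=True)
    handle = open(stream) if isinstance(stream, str) else stream
    try:
        structure = parser.get_structure("mol", handle)
    finally:
        if isinstance(stream, str):
            handle.close()

    model = next(structure.get_models())
    atoms: list[Atom] = []
    for chain in model:
        residues = [r for r in chain if r.id[0] == " "]
        if not residues:
            continue
        protein = [r for r in residues if r.get_resname().strip() in _THREE_TO_ONE]
        for res in residues:
            resname = res.get_resname().strip()
            charges: dict[str, float] = {}
            if resname in _THREE_TO_ONE:
                code = _THREE_TO_ONE[resname]
                q = rule.residue_charge(code)
                if q:
                    site = _CHARGE_SITE.get(code)
                    if site is None or site not in res:
                        raise ValueError(
                            f"residue {resname} {res.id[1]} lacks charge-site atom"
                        )
                    charges[site] = float(q)
                if include_termini and protein and res is protein[0]:
                    if "N" not in res:
                        raise ValueError("N-terminal residue lacks backbone N")
                    charges["N"] = charges.get("N", 0.0) + rule.n_terminus
                if include_termini and protein and res is protein[-1]:
                    site = "OXT" if "OXT" in res else "C"
                    if site not in res:
                        raise ValueError("C-terminal residue lacks carboxyl atom")
                    charges[site] = charges.get(site, 0.0) + rule.c_terminus
            elif resname in _NUCLEIC_RESIDUES:
                # One formal -1 e per phosphate present; 5'-terminal residues
                # deposited without a P atom contribute nothing.
                if "P" in res:
                    charges["P"] = -1.0
            else:
                raise ValueError(f"unknown residue {resname!r} in PDB input")
            for atom in res:
                element = (atom.element or atom.get_name()[0]).upper()
                if element == "H":
                    continue
                atoms.append(
                    Atom(
                        np.asarray(atom.coord, dtype=float),
                        charges.get(atom.get_name(), 0.0),
                        radii.get(element, _DEFAULT_RADIUS),
                        name=atom.get_name(),
                        residue=resname,
                    )
                )
    if not atoms:
        raise ValueError("PDB stream contained no usable atoms")
    total = sum(a.charge for a in atoms)
    return Molecule(atoms, int(round(total)), label=label)
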