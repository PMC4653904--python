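"""Domain types for HTH-DNA complexes.

A :class:`Complex` is one helix-turn-helix protein domain bound to a
standardized double-stranded DNA duplex.  The protein is held as an ordered
residue list (0-based indices, half-open ranges throughout the package; PDB
serial numbers exist only at the I/O boundary), and the DNA as two 5'->3'
strands with an explicit Watson-Crick pairing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = set(AA3_TO_1.values())

DNA_RESNAMES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T",
                "A": "A", "C": "C", "G": "G", "T": "T"}
BASE_TO_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
BACKBONE_CARBONS = ("C1'", "C2'", "C3'", "C4'", "C5'")
GAP = "-"


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite position for atom {self.name}")
        object.__setattr__(self, "position", pos)


@dataclass
class Residue:
    seq_index: int
    aa_code: str
    atoms: list[Atom]

    @property
    def ca(self) -> Atom | None:
        for atom in self.atoms:
            if atom.name == "CA":
                return atom
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass
class Nucleotide:
    seq_index: int
    base: str
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    @property
    def c1(self) -> Atom | None:
        return self.atom("C1'")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def has_full_backbone(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(n in names for n in BACKBONE_CARBONS)


@dataclass
class DnaDuplex:
    """Two antiparallel strands, each ordered 5'->3' on its own chain.

    After standardization both strands have equal length L and ``pairs``
    holds ``(i, L-1-i)``: basepair ``i`` joins ``forward[i]`` with
    ``reverse[L-1-i]``.
    """

    forward: list[Nucleotide]
    reverse: list[Nucleotide]
    pairs: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_basepairs(self) -> int:
        return len(self.pairs)

    def forward_sequence(self) -> str:
        return "".join(nt.base for nt in self.forward)

    def reverse_sequence(self) -> str:
        return "".join(nt.base for nt in self.reverse)

    def basepair(self, i: int) -> tuple[Nucleotide, Nucleotide]:
        fi, ri = self.pairs[i]
        return self.forward[fi], self.reverse[ri]

    def all_atoms(self) -> list[Atom]:
        atoms: list[Atom] = []
        for nt in self.forward:
            atoms.extend(nt.atoms)
        for nt in self.reverse:
            atoms.extend(nt.atoms)
        return atoms

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.all_atoms()])

    def backbone_coords(self) -> np.ndarray:
        """Coordinates of the C1'-C5' backbone carbons, both strands."""
        out = []
        for strand in (self.forward, self.reverse):
            for nt in strand:
                for name in BACKBONE_CARBONS:
                    atom = nt.atom(name)
                    if atom is not None:
                        out.append(atom.position)
        return np.array(out)

    def validate(self) -> None:
        L = len(self.forward)
        if len(self.reverse) != L:
            raise ValueError("strand lengths differ after standardization")
        seen_f, seen_r = set(), set()
        for k, (fi, ri) in enumerate(self.pairs):
            if fi in seen_f or ri in seen_r:
                raise ValueError("pairing is not a bijection")
            seen_f.add(fi)
            seen_r.add(ri)
            if ri != L - 1 - fi:
                raise ValueError("pairing does not respect antiparallel order")
            f, r = self.forward[fi], self.reverse[ri]
            if COMPLEMENT.get(f.base) != r.base:
                raise ValueError(
                    f"basepair {k} not Watson-Crick: {f.base}/{r.base}")


class Pathology(enum.Flag):
    NONE = 0
    SINGLE_STRANDED_DNA = enum.auto()
    MISSING_BACKBONE_ATOMS = enum.auto()
    NONSTANDARD_RESIDUES = enum.auto()


@dataclass(frozen=True)
class PathologyReport:
    flags: Pathology = Pathology.NONE
    details: tuple[str, ...] = ()

    @property
    def admissible(self) -> bool:
        return self.flags == Pathology.NONE


@dataclass
class Complex:
    """One HTH domain with its cognate standardized DNA duplex.

    ``recognition_helix`` is a half-open residue range and ``central_residue``
    an index inside it; both are ``None`` until HTH detection has run.
    """

    structure_id: str
    chain_id: str
    protein: list[Residue]
    duplex: DnaDuplex
    resolution: float | None = None
    recognition_helix: tuple[int, int] | None = None
    central_residue: int | None = None

    def __post_init__(self):
        self._check_annotation()

    def _check_annotation(self) -> None:
        if self.recognition_helix is not None:
            start, stop = self.recognition_helix
            if not (0 <= start < stop <= len(self.protein)):
                raise ValueError("recognition helix range outside protein")
            if self.central_residue is not None and not (
                    start <= self.central_residue < stop):
                raise ValueError("central residue outside recognition helix")

    def protein_sequence(self) -> str:
        return "".join(r.aa_code for r in self.protein)

    def protein_atoms(self) -> list[Atom]:
        atoms: list[Atom] = []
        for res in self.protein:
            atoms.extend(res.atoms)
        return atoms

    def protein_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.protein_atoms()])

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca.position for r in self.protein])

    def helix_ca_coords(self) -> np.ndarray:
        if self.recognition_helix is None:
            raise ValueError("recognition helix not set")
        start, stop = self.recognition_helix
        return np.array([self.protein[i].ca.position
                         for i in range(start, stop)])

    def transformed(self, transform) -> "Complex":
        """Return a copy with every atom position moved by ``transform``."""
        def move_atoms(atoms: list[Atom]) -> list[Atom]:
            return [Atom(a.name, a.element, transform.apply(a.position))
                    for a in atoms]

        protein = [Residue(r.seq_index, r.aa_code, move_atoms(r.atoms))
                   for r in self.protein]
        fwd = [Nucleotide(n.seq_index, n.base, move_atoms(n.atoms))
               for n in self.duplex.forward]
        rev = [Nucleotide(n.seq_index, n.base, move_atoms(n.atoms))
               for n in self.duplex.reverse]
        duplex = DnaDuplex(fwd, rev, list(self.duplex.pairs))
        return Complex(self.structure_id, self.chain_id, protein, duplex,
                       self.resolution, self.recognition_helix,
                       self.central_residue)
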