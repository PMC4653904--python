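"""Protein-DNA atomic contacts in universal coordinates.

A contact is any protein atom within a distance cutoff (default 5 A) of any
DNA atom.  Contacts are reported in each structure's own indices and, through
a unified coordinate system, pooled across structures into per-(residue,
basepair) contact frequencies and per-atom-type contact profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas import UnifiedCoordinateSystem
from .config import DEFAULT_CONFIG, Config
from .model import Complex

# Fixed atom-type dictionary for profile binning; anything else is OTHER.
PROTEIN_ATOM_TYPES = ("N", "CA", "C", "O", "CB")
DNA_ATOM_TYPES = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'",
                  "O3'", "C2'", "C1'")
OTHER = "OTHER"


@dataclass(frozen=True)
class ContactRecord:
    residue_index: int
    basepair_index: int
    strand: str              # 'F' or 'R'
    protein_atom: str
    dna_atom: str
    distance: float


def atomic_contacts(cplx: Complex, cutoff: float | None = None,
                    config: Config = DEFAULT_CONFIG) -> list[ContactRecord]:
    """All protein-DNA atom pairs within the cutoff, via a k-d tree.

    Records are sorted by (residue, basepair, strand, atom names) for
    deterministic output.
    """
    if cutoff is None:
        cutoff = config.contact_cutoff
    p_atoms = []          # (residue index, atom name, position)
    for i, res in enumerate(cplx.protein):
        for atom in res.atoms:
            p_atoms.append((i, atom.name, atom.position))
    d_atoms = []          # (basepair index, strand, atom name, position)
    for j in range(cplx.duplex.n_basepairs):
        f, r = cplx.duplex.basepair(j)
        for nt, strand in ((f, "F"), (r, "R")):
            for atom in nt.atoms:
                d_atoms.append((j, strand, atom.name, atom.position))
    if not p_atoms or not d_atoms:
        return []
    tree = cKDTree(np.array([a[3] for a in d_atoms]))
    records = []
    p_pos = np.array([a[2] for a in p_atoms])
    for (ri, pname, pos), hits in zip(
            p_atoms, tree.query_ball_point(p_pos, cutoff)):
        for h in hits:
            bj, strand, dname, dpos = d_atoms[h]
            dist = float(np.linalg.norm(pos - dpos))
            if dist <= cutoff:
                records.append(ContactRecord(ri, bj, strand, pname, dname,
                                             dist))
    records.sort(key=lambda r: (r.residue_index, r.basepair_index, r.strand,
                                r.protein_atom, r.dna_atom))
    return records


def brute_force_contacts(cplx: Complex, cutoff: float | None = None,
                         config: Config = DEFAULT_CONFIG
                         ) -> list[ContactRecord]:
    """Reference O(N*M) implementation of :func:`atomic_contacts`."""
    if cutoff is None:
        cutoff = config.contact_cutoff
    records = []
    for i, res in enumerate(cplx.protein):
        for patom in res.atoms:
            for j in range(cplx.duplex.n_basepairs):
                f, r = cplx.duplex.basepair(j)
                for nt, strand in ((f, "F"), (r, "R")):
                    for datom in nt.atoms:
                        dist = float(np.linalg.norm(
                            patom.position - datom.position))
                        if dist <= cutoff:
                            records.append(ContactRecord(
                                i, j, strand, patom.name, datom.name, dist))
    records.sort(key=lambda r: (r.residue_index, r.basepair_index, r.strand,
                                r.protein_atom, r.dna_atom))
    return records


def contact_frequency_table(ucs: UnifiedCoordinateSystem,
                            cutoff: float | None = None,
                            config: Config = DEFAULT_CONFIG) -> pd.DataFrame:
    """Universal (residue, basepair) contact frequencies across members.

    Each member contributes at most once per cell: the frequency of a cell
    is the fraction of member structures with at least one atomic contact
    mapping there.  Cells never touched by any member are absent; positions
    a member cannot map (outside its residue/basepair maps) are skipped and
    counted in the ``n_unmapped`` attribute stored in ``df.attrs``.
    """
    counts: dict[tuple[int, int], int] = {}
    n_unmapped = 0
    n_members = len(ucs.members)
    for m in ucs.members:
        cells = set()
        for rec in atomic_contacts(ucs.complexes[m], cutoff, config):
            uri = ucs.residue_maps[m].get(rec.residue_index)
            ubj = ucs.basepair_maps[m].get(rec.basepair_index)
            if uri is None or ubj is None:
                n_unmapped += 1
                continue
            cells.add((uri, ubj))
        for cell in cells:
            counts[cell] = counts.get(cell, 0) + 1
    rows = [{"residue": r, "basepair": b,
             "n_structures": c, "frequency": c / n_members}
            for (r, b), c in sorted(counts.items())]
    df = pd.DataFrame(rows, columns=["residue", "basepair", "n_structures",
                                     "frequency"])
    df.attrs["n_members"] = n_members
    df.attrs["n_unmapped"] = n_unmapped
    return df


def _bin_type(name: str, known: tuple[str, ...]) -> str:
    return name if name in known else OTHER


def atomtype_profile(complexes: list[Complex],
                     cutoff: float | None = None,
                     config: Config = DEFAULT_CONFIG) -> pd.DataFrame:
    """Contact counts by (protein atom type, DNA atom type) over structures.

    Atom names outside the fixed dictionaries are pooled into OTHER; the
    result is a matrix with protein types as rows and DNA types as columns.
    """
    rows = list(PROTEIN_ATOM_TYPES) + [OTHER]
    cols = list(DNA_ATOM_TYPES) + [OTHER]
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for cplx in complexes:
        for rec in atomic_contacts(cplx, cutoff, config):
            table.loc[_bin_type(rec.protein_atom, PROTEIN_ATOM_TYPES),
                      _bin_type(rec.dna_atom, DNA_ATOM_TYPES)] += 1
    return table
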