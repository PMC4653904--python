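"""PDB reading/writing, pathology screening, duplex standardization and
per-domain splitting.

Structures are read with gemmi; only the first model is used (X-ray focus),
the first altloc of each atom is kept, and waters/other heteroatoms are
stripped at read time.  Chains are partitioned into protein and nucleic by
residue identity.  Standardization orders both DNA strands 5'->3', removes
unpaired terminal overhangs and establishes the Watson-Crick pairing
geometrically (complementary bases with C1'-C1' distance 10.5 +/- 1.5 A,
resolved by minimum-cost bipartite matching).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config import DEFAULT_CONFIG, Config
from .model import (AA1_TO_3, AA3_TO_1, BACKBONE_CARBONS, BASE_TO_RESNAME,
                    COMPLEMENT, DNA_RESNAMES, Atom, Complex, DnaDuplex,
                    Nucleotide, Pathology, PathologyReport, Residue)

logger = logging.getLogger(__name__)

_WATER = {"HOH", "WAT", "DOD"}


class PdbParseError(ValueError):
    """Unparseable PDB text (message carries gemmi's line diagnostics)."""


class StandardizationError(ValueError):
    """No consistent duplex pairing could be established."""


@dataclass
class RawStructure:
    """Parsed, classified chains before standardization/splitting."""

    structure_id: str
    resolution: float | None
    protein_chains: dict[str, list[Residue]] = field(default_factory=dict)
    nucleic_chains: dict[str, list[Nucleotide]] = field(default_factory=dict)
    # per protein chain: half-open residue-index ranges from HELIX records
    helix_annotations: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict)


def read_structure(pdb_text: str) -> RawStructure:
    """Parse PDB text into classified protein/nucleic chains.

    First altloc kept; waters and non-polymer heteroatoms dropped; insertion
    codes are honoured through gemmi's residue ordering.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except RuntimeError as exc:
        raise PdbParseError(str(exc)) from exc
    if len(st) == 0:
        raise PdbParseError("no models in structure")
    resolution = st.resolution if st.resolution > 0 else None
    raw = RawStructure(st.name or "UNKNOWN", resolution)

    model = st[0]
    for chain in model:
        protein: list[Residue] = []
        nucleic: list[Nucleotide] = []
        for res in chain:
            name = res.name.strip().upper()
            if name in _WATER:
                continue
            atoms: list[Atom] = []
            seen: set[str] = set()
            for atom in res:
                if atom.name in seen:
                    continue          # first altloc wins
                seen.add(atom.name)
                atoms.append(Atom(atom.name, atom.element.name,
                                  np.array([atom.pos.x, atom.pos.y,
                                            atom.pos.z])))
            names = {a.name for a in atoms}
            if name in DNA_RESNAMES or "C1'" in names:
                nucleic.append(Nucleotide(len(nucleic),
                                          DNA_RESNAMES.get(name, "X"), atoms))
            elif name in AA3_TO_1 or "CA" in names:
                protein.append(Residue(len(protein),
                                       AA3_TO_1.get(name, "X"), atoms))
            # other heteroatoms (ligands, ions) are stripped
        if protein:
            raw.protein_chains[chain.name] = protein
        if nucleic:
            raw.nucleic_chains[chain.name] = nucleic

    # HELIX records -> half-open residue-index ranges per chain
    seqid_index: dict[str, dict[int, int]] = {}
    for chain in model:
        mapping = {}
        idx = 0
        for res in chain:
            name = res.name.strip().upper()
            if name in _WATER or (name not in AA3_TO_1 and
                                  not any(a.name == "CA" for a in res)):
                continue
            mapping[res.seqid.num] = idx
            idx += 1
        seqid_index[chain.name] = mapping
    for helix in st.helices:
        cname = helix.start.chain_name
        mapping = seqid_index.get(cname, {})
        s = mapping.get(helix.start.res_id.seqid.num)
        e = mapping.get(helix.end.res_id.seqid.num)
        if s is not None and e is not None and e >= s:
            raw.helix_annotations.setdefault(cname, []).append((s, e + 1))
    return raw


def screen_pathologies(raw: RawStructure) -> PathologyReport:
    """Report the three pathology classes; empty flags means admissible."""
    flags = Pathology.NONE
    details: list[str] = []
    if len(raw.nucleic_chains) != 2:
        flags |= Pathology.SINGLE_STRANDED_DNA
        details.append(f"{len(raw.nucleic_chains)} nucleic chain(s), need 2")
    for cid, chain in raw.protein_chains.items():
        for res in chain:
            if res.ca is None:
                flags |= Pathology.MISSING_BACKBONE_ATOMS
                details.append(f"protein {cid}:{res.seq_index} lacks CA")
            if res.aa_code not in AA3_TO_1.values():
                flags |= Pathology.NONSTANDARD_RESIDUES
                details.append(f"protein {cid}:{res.seq_index} non-standard")
    for cid, chain in raw.nucleic_chains.items():
        for nt in chain:
            if not nt.has_full_backbone():
                flags |= Pathology.MISSING_BACKBONE_ATOMS
                details.append(f"dna {cid}:{nt.seq_index} missing C1'-C5'")
            if nt.base not in "ACGT":
                flags |= Pathology.NONSTANDARD_RESIDUES
                details.append(f"dna {cid}:{nt.seq_index} non-ACGT base")
    return PathologyReport(flags, tuple(details))


def _is_five_to_three(chain: list[Nucleotide]) -> bool:
    """Geometric 5'->3' test: within a nucleotide the C5'->C3' displacement
    points toward the 3' neighbour, so its projection on the chain direction
    is positive for a 5'->3' listing."""
    if len(chain) < 2:
        return True
    direction = chain[-1].c1.position - chain[0].c1.position
    score = 0.0
    for nt in chain:
        c3, c5 = nt.atom("C3'"), nt.atom("C5'")
        if c3 is not None and c5 is not None:
            score += (c3.position - c5.position) @ direction
    return score >= 0


def standardize_duplex(nucleic_chains: list[list[Nucleotide]],
                       config: Config = DEFAULT_CONFIG) -> DnaDuplex:
    """Standardize two nucleic chains into a paired, overhang-free duplex.

    Coordinates are never altered; nucleotides are only reordered (to 5'->3')
    and unpaired terminal overhangs removed.  Idempotent.
    """
    if len(nucleic_chains) != 2:
        raise StandardizationError(
            f"need exactly 2 nucleic chains, got {len(nucleic_chains)} "
            "(single-stranded DNA)")
    fwd, rev = (list(c) for c in nucleic_chains)
    if not _is_five_to_three(fwd):
        fwd = fwd[::-1]
    if not _is_five_to_three(rev):
        rev = rev[::-1]

    c1f = np.array([nt.c1.position for nt in fwd])
    c1r = np.array([nt.c1.position for nt in rev])
    dist = cdist(c1f, c1r)
    lo = config.pair_c1_distance - config.pair_c1_tolerance
    hi = config.pair_c1_distance + config.pair_c1_tolerance
    comp = np.array([[COMPLEMENT.get(a.base) == b.base for b in rev]
                     for a in fwd])
    allowed = (dist >= lo) & (dist <= hi) & comp
    BIG = 1.0e6
    cost = np.where(allowed, dist, BIG)
    rows, cols = linear_sum_assignment(cost)
    matched = [(int(i), int(j)) for i, j in zip(rows, cols) if allowed[i, j]]
    if not matched:
        raise StandardizationError("no complementary basepairs found")
    matched.sort()
    f_idx = [i for i, _ in matched]
    r_idx = [j for _, j in matched]
    # antiparallel consistency: forward index up, reverse index down
    if any(r_idx[k] <= r_idx[k + 1] for k in range(len(r_idx) - 1)):
        raise StandardizationError("pairing is not consistently antiparallel")
    if f_idx != list(range(f_idx[0], f_idx[-1] + 1)):
        raise StandardizationError("unpaired nucleotide inside the duplex")
    if r_idx != list(range(r_idx[0], r_idx[0] - len(r_idx), -1)):
        raise StandardizationError("unpaired nucleotide inside the duplex")

    new_fwd = [Nucleotide(k, fwd[i].base, fwd[i].atoms)
               for k, i in enumerate(f_idx)]
    new_rev_src = sorted(r_idx)
    new_rev = [Nucleotide(k, rev[j].base, rev[j].atoms)
               for k, j in enumerate(new_rev_src)]
    L = len(new_fwd)
    duplex = DnaDuplex(new_fwd, new_rev, [(i, L - 1 - i) for i in range(L)])
    duplex.validate()
    return duplex


def merge_protein_chains(raw: RawStructure) -> list[Residue]:
    """Concatenate all protein chains N->C in file order, renumbered 0-based."""
    merged: list[Residue] = []
    for chain in raw.protein_chains.values():
        for res in chain:
            merged.append(Residue(len(merged), res.aa_code, res.atoms))
    return merged


def split_domains(raw: RawStructure, duplex: DnaDuplex, assessments,
                  config: Config = DEFAULT_CONFIG) -> list[Complex]:
    """One Complex per detected HTH domain.

    ``assessments`` are passing detection results computed on the merged
    protein chain (see :func:`hthatlas.detect.detect_domains`).  Each domain
    spans its recognition helix plus the bundle helices within the
    tri-helical cutoff of the central residue; the slice is renumbered
    contiguously.  Domains with no DNA contact inside the candidacy cutoff
    are excluded with a logged reason.
    """
    from .detect import assign_helices  # local import avoids a cycle

    protein = merge_protein_chains(raw)
    helices = assign_helices(protein, config)
    chain_label = "".join(raw.protein_chains) or "A"
    dna_xyz = duplex.coords()
    out: list[Complex] = []
    for assessment in assessments:
        if not assessment.passed:
            continue
        cand = assessment.candidate_helix
        central_ca = protein[assessment.central_residue].ca.position
        involved = [cand]
        for helix in helices:
            if helix == cand:
                continue
            ca = np.array([protein[i].ca.position for i in helix.indices()])
            if np.linalg.norm(ca - central_ca, axis=1).min() <= \
                    config.trihelix_cutoff:
                involved.append(helix)
        start = min(h.start for h in involved)
        stop = max(h.stop for h in involved)
        domain = [Residue(k, protein[i].aa_code, protein[i].atoms)
                  for k, i in enumerate(range(start, stop))]
        min_d = min(cdist(res.coords(), dna_xyz).min() for res in domain)
        if min_d >= config.candidacy_cutoff:
            logger.info("domain %d-%d excluded: no DNA within %.1f A",
                        start, stop, config.candidacy_cutoff)
            continue
        out.append(Complex(
            raw.structure_id, chain_label, domain, duplex,
            resolution=raw.resolution,
            recognition_helix=(cand.start - start, cand.stop - start),
            central_residue=assessment.central_residue - start))
    return out


def write_structure(cplx: Complex) -> str:
    """Deterministic PDB serialization: protein chain A, then the two DNA
    strands (chains B and C), each 5'->3'."""
    if not cplx.protein:
        raise ValueError("refusing to write a complex with no protein")
    st = gemmi.Structure()
    st.name = cplx.structure_id
    model = gemmi.Model("1")

    def add_chain(name: str, entries, resname_of) -> None:
        chain = gemmi.Chain(name)
        for k, entry in enumerate(entries):
            res = gemmi.Residue()
            res.name = resname_of(entry)
            res.seqid = gemmi.SeqId(k + 1, " ")
            for atom in entry.atoms:
                a = gemmi.Atom()
                a.name = atom.name
                a.element = gemmi.Element(atom.element)
                a.pos = gemmi.Position(*atom.position)
                a.occ = 1.0
                a.b_iso = 0.0
                res.add_atom(a)
            chain.add_residue(res)
        model.add_chain(chain)

    add_chain("A", cplx.protein, lambda r: AA1_TO_3.get(r.aa_code, "UNK"))
    add_chain("B", cplx.duplex.forward, lambda n: BASE_TO_RESNAME[n.base])
    add_chain("C", cplx.duplex.reverse, lambda n: BASE_TO_RESNAME[n.base])
    st.add_model(model)
    body = st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))
    header = ""
    if cplx.resolution is not None:
        header = (f"REMARK   2 RESOLUTION. {cplx.resolution:7.2f} "
                  "ANGSTROMS.\n")
    return header + body


def read_complex(pdb_text: str, config: Config = DEFAULT_CONFIG) -> Complex:
    """Read a single-domain complex written by :func:`write_structure`."""
    raw = read_structure(pdb_text)
    report = screen_pathologies(raw)
    if not report.admissible:
        raise ValueError(f"pathological structure: {report.details}")
    duplex = standardize_duplex(list(raw.nucleic_chains.values()), config)
    protein = merge_protein_chains(raw)
    chain_label = "".join(raw.protein_chains) or "A"
    return Complex(raw.structure_id, chain_label, protein, duplex,
                   resolution=raw.resolution)
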