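"""Redundancy elimination via recognition-sequence identity.

Two complexes are redundant when the amino-acid sequences around their
central residues match exactly under some small shift.  Each complex yields a
41-symbol window (20 residues each side of the central residue, padded with
GAP where the chain ends); the distance between two windows is the minimum
mismatch count over all shifts of magnitude at most 15 — the bound implied by
requiring the 11-residue window flanking both central residues to lie inside
the overlap.  A column in which either symbol is GAP counts as a mismatch, so
truncated chains never produce spurious zero distances.

Zero-distance pairs form the edges of a redundancy graph; one representative
is retained per connected component (highest degree, then best resolution,
then lexicographic structure id).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .config import DEFAULT_CONFIG, Config
from .model import GAP, Complex

WINDOW = 41
CENTER = 20


@dataclass(frozen=True)
class RecognitionSequence:
    """41 amino-acid symbols centred (index 20) on the central residue."""

    symbols: tuple[str, ...]
    central_offset: int = CENTER

    def __post_init__(self):
        if len(self.symbols) != WINDOW:
            raise ValueError(f"need exactly {WINDOW} symbols")
        if self.symbols[CENTER] == GAP:
            raise ValueError("central symbol cannot be GAP")


def extract_recognition_sequence(cplx: Complex,
                                 config: Config = DEFAULT_CONFIG
                                 ) -> RecognitionSequence:
    """The 41-residue window centred on the central residue, GAP-padded."""
    if cplx.central_residue is None:
        raise ValueError("central residue not set (run detection first)")
    flank = config.recseq_flank
    c = cplx.central_residue
    n = len(cplx.protein)
    symbols = tuple(
        cplx.protein[i].aa_code if 0 <= i < n else GAP
        for i in range(c - flank, c + flank + 1))
    return RecognitionSequence(symbols)


def shifted_distance(a: RecognitionSequence, b: RecognitionSequence,
                     config: Config = DEFAULT_CONFIG) -> tuple[int, int]:
    """Minimum mismatches over allowable shifts; returns (mismatches, shift).

    Shift ``s`` aligns ``a[i]`` with ``b[i - s]``; |s| <= 15 keeps the
    11-residue central windows of both sequences inside the overlap.  Ties
    break toward the smallest |s|, negative before positive.
    """
    max_shift = config.max_shift
    best: tuple[int, int] | None = None
    for s in sorted(range(-max_shift, max_shift + 1),
                    key=lambda s: (abs(s), s > 0)):
        lo = max(0, s)
        hi = min(WINDOW, WINDOW + s)
        mism = sum(
            1 for i in range(lo, hi)
            if a.symbols[i] != b.symbols[i - s]
            or a.symbols[i] == GAP)
        if best is None or mism < best[0]:
            best = (mism, s)
    return best


def build_redundancy_graph(complexes: list[Complex],
                           config: Config = DEFAULT_CONFIG) -> nx.Graph:
    """Graph on complex indices with edges between zero-distance pairs."""
    seqs = [extract_recognition_sequence(c, config) for c in complexes]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(complexes)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            mism, _ = shifted_distance(seqs[i], seqs[j], config)
            if mism == 0:
                graph.add_edge(i, j)
    return graph


def select_representatives(graph: nx.Graph,
                           complexes: list[Complex]) -> list[int]:
    """One retained complex per connected component.

    Disconnected nodes are retained as-is.  Within a component the most
    central node (largest degree) wins; ties go to the best (lowest
    Angstrom) resolution, missing resolutions sorting last, then to the
    lexicographically smallest structure id.
    """
    retained = []
    for component in nx.connected_components(graph):
        def key(i: int):
            res = complexes[i].resolution
            return (-graph.degree[i],
                    res if res is not None else float("inf"),
                    complexes[i].structure_id,
                    i)
        retained.append(min(component, key=key))
    return sorted(retained)
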