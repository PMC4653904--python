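"""HTH domain detection.

Three distance heuristics applied in order decide whether a protein chain
bound to DNA contains a helix-turn-helix domain:

1. *Candidacy* — some alpha-helix has a contiguous five-residue window whose
   mean distance to the DNA (shortest atom-atom distance per residue) is
   under 5 A.
2. *Orientation* — each of those five residues is individually within 6.5 A
   of the DNA.
3. *Tri-helical bundle* — at least three helices are present and the central
   residue (the recognition-helix residue closest to the DNA major axis) has
   a C-alpha within 18 A of residues in at least two other helices.

Helices are taken from PDB HELIX records when supplied, otherwise assigned
geometrically from the C-alpha trace: residue i starts a helical step when
|CA(i)-CA(i+3)| lies in [4.5, 6.5] A and |CA(i)-CA(i+4)| in [5.5, 7.5] A, and
maximal runs of such steps form segments.  All ties break toward the lowest
index so the procedure is deterministic and independent of enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .config import DEFAULT_CONFIG, Config
from .geometry import Line, principal_axis
from .model import Complex, DnaDuplex, Residue


@dataclass(frozen=True)
class HelixSegment:
    """A maximal alpha-helical run; ``start``/``stop`` are half-open."""

    start: int
    stop: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError("helix segment start must be non-negative")
        if self.stop - self.start < 4:
            raise ValueError("helix segments have at least 4 residues")

    @property
    def length(self) -> int:
        return self.stop - self.start

    def indices(self) -> range:
        return range(self.start, self.stop)


@dataclass
class HthAssessment:
    """Full record of the three-step HTH verdict for one chain."""

    verdict: str                               # "pass" or the failing criterion
    candidate_helix: HelixSegment | None = None
    closest_window: tuple[int, ...] = ()
    mean_window_distance: float | None = None
    per_residue_distances: tuple[float, ...] = ()
    central_residue: int | None = None
    helix_neighbor_distances: tuple[float, ...] = ()

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "candidate_helix": (None if self.candidate_helix is None
                                else [self.candidate_helix.start,
                                      self.candidate_helix.stop]),
            "closest_window": list(self.closest_window),
            "mean_window_distance": self.mean_window_distance,
            "per_residue_distances": list(self.per_residue_distances),
            "central_residue": self.central_residue,
            "helix_neighbor_distances": list(self.helix_neighbor_distances),
        }


def assign_helices(protein: list[Residue],
                   config: Config = DEFAULT_CONFIG,
                   known: list[tuple[int, int]] | None = None
                   ) -> list[HelixSegment]:
    """Maximal disjoint alpha-helical runs of a C-alpha trace.

    ``known`` (half-open ranges, e.g. from HELIX records) short-circuits the
    geometric assignment.
    """
    if known is not None:
        return [HelixSegment(s, e) for s, e in sorted(known) if e - s >= 4]
    n = len(protein)
    if n < 4:
        return []
    ca = np.array([r.ca.position for r in protein])
    d13lo, d13hi = config.helix_d13
    d14lo, d14hi = config.helix_d14
    mark = np.zeros(n, dtype=bool)
    for i in range(n - 3):
        d3 = np.linalg.norm(ca[i] - ca[i + 3])
        ok = d13lo <= d3 <= d13hi
        if ok and i + 4 < n:
            d4 = np.linalg.norm(ca[i] - ca[i + 4])
            ok = d14lo <= d4 <= d14hi
        mark[i] = ok
    segments: list[HelixSegment] = []
    i = 0
    while i < n - 3:
        if mark[i]:
            j = i
            while j + 1 < n - 3 and mark[j + 1]:
                j += 1
            segments.append(HelixSegment(i, min(j + 4 + 1, n)))
            i = j + 4 + 1    # skip past the segment: runs stay disjoint
        else:
            i += 1
    return segments


def residue_dna_distance(residue: Residue, duplex: DnaDuplex) -> float:
    """Shortest pairwise distance over all residue atoms and all DNA atoms."""
    if not residue.atoms:
        raise ValueError("residue has no atoms")
    dna = duplex.coords()
    if dna.size == 0:
        raise ValueError("duplex has no atoms")
    return float(cdist(residue.coords(), dna).min())


def _per_residue_distances(protein: list[Residue], indices: range,
                           dna_xyz: np.ndarray) -> np.ndarray:
    return np.array([cdist(protein[i].coords(), dna_xyz).min()
                     for i in indices])


def _best_window(dists: np.ndarray, w: int) -> tuple[int, float]:
    """Start offset and mean of the contiguous w-window minimising the mean."""
    means = np.convolve(dists, np.ones(w) / w, mode="valid")
    start = int(np.argmin(means))     # argmin takes the lowest index on ties
    return start, float(means[start])


def find_candidate_recognition_helix(
        helices: list[HelixSegment], protein: list[Residue],
        duplex: DnaDuplex, config: Config = DEFAULT_CONFIG
) -> tuple[HelixSegment, tuple[int, ...], np.ndarray] | None:
    """The helix whose best five-residue window has mean DNA distance < 5 A.

    Among qualifying helices the smallest window mean wins (ties: lowest
    helix start).  Returns (helix, window residue indices, window distances)
    or ``None``.
    """
    w = config.candidacy_window
    dna_xyz = duplex.coords()
    best: tuple[float, int, HelixSegment, int, np.ndarray] | None = None
    for helix in helices:
        if helix.length < w:
            continue
        dists = _per_residue_distances(protein, helix.indices(), dna_xyz)
        off, mean = _best_window(dists, w)
        if mean < config.candidacy_cutoff:
            key = (mean, helix.start)
            if best is None or key < (best[0], best[1]):
                best = (mean, helix.start, helix, off, dists[off:off + w])
    if best is None:
        return None
    _, _, helix, off, window_d = best
    window = tuple(range(helix.start + off, helix.start + off + w))
    return helix, window, window_d


def check_orientation(window_distances: np.ndarray,
                      config: Config = DEFAULT_CONFIG) -> bool:
    """True when every window residue is within 6.5 A of the DNA (inclusive)."""
    return bool(np.all(np.asarray(window_distances) <= config.orientation_cutoff))


def dna_major_axis(duplex: DnaDuplex) -> Line:
    """Least-squares major axis of the DNA backbone carbons.

    The direction is canonicalized toward increasing forward-strand index.
    """
    if duplex.n_basepairs < 2:
        raise ValueError("need at least 2 basepairs for a major axis")
    axis = principal_axis(duplex.backbone_coords())
    c1_first = duplex.forward[0].c1.position
    c1_last = duplex.forward[-1].c1.position
    if axis.direction @ (c1_last - c1_first) < 0:
        axis = Line(axis.point, -axis.direction)
    return axis


def find_central_residue(helix: HelixSegment, protein: list[Residue],
                         duplex: DnaDuplex) -> int:
    """Helix residue whose CA is closest to the DNA major axis (ties: lowest)."""
    axis = dna_major_axis(duplex)
    ca = np.array([protein[i].ca.position for i in helix.indices()])
    dists = axis.distance(ca)
    return helix.start + int(np.argmin(dists))


def check_trihelical(helices: list[HelixSegment], protein: list[Residue],
                     central_residue: int, candidate: HelixSegment,
                     config: Config = DEFAULT_CONFIG
                     ) -> tuple[bool, tuple[float, ...]]:
    """Bundle check: >= 3 helices, and >= 2 helices other than the candidate
    with a CA within 18 A of the central residue's CA.

    Returns the verdict and the per-other-helix minimum CA-CA distances.
    """
    central_ca = protein[central_residue].ca.position
    neighbor = []
    for helix in helices:
        if helix == candidate:
            continue
        ca = np.array([protein[i].ca.position for i in helix.indices()])
        neighbor.append(float(np.linalg.norm(ca - central_ca, axis=1).min()))
    n_close = sum(d <= config.trihelix_cutoff for d in neighbor)
    ok = len(helices) >= config.min_helices and n_close >= 2
    return ok, tuple(neighbor)


def detect_hth(cplx: Complex, config: Config = DEFAULT_CONFIG,
               known_helices: list[tuple[int, int]] | None = None
               ) -> HthAssessment:
    """Run candidacy -> orientation -> tri-helical checks, short-circuiting.

    On a pass the complex's ``recognition_helix`` and ``central_residue``
    are set in place.
    """
    helices = assign_helices(cplx.protein, config, known=known_helices)
    found = find_candidate_recognition_helix(helices, cplx.protein,
                                             cplx.duplex, config)
    if found is None:
        return HthAssessment(verdict="candidacy")
    helix, window, window_d = found
    base = dict(candidate_helix=helix, closest_window=window,
                mean_window_distance=float(np.mean(window_d)),
                per_residue_distances=tuple(float(d) for d in window_d))
    if not check_orientation(window_d, config):
        return HthAssessment(verdict="orientation", **base)
    central = find_central_residue(helix, cplx.protein, cplx.duplex)
    ok, neighbor = check_trihelical(helices, cplx.protein, central, helix,
                                    config)
    base.update(central_residue=central, helix_neighbor_distances=neighbor)
    if not ok:
        return HthAssessment(verdict="trihelical", **base)
    cplx.recognition_helix = (helix.start, helix.stop)
    cplx.central_residue = central
    cplx._check_annotation()
    return HthAssessment(verdict="pass", **base)


def detect_domains(cplx: Complex, config: Config = DEFAULT_CONFIG
                   ) -> list[HthAssessment]:
    """All passing HTH domains on one chain (multi-domain structures).

    Every helix with a qualifying candidacy window is assessed independently;
    each passing assessment describes one domain.
    """
    helices = assign_helices(cplx.protein, config)
    dna_xyz = cplx.duplex.coords()
    w = config.candidacy_window
    out: list[HthAssessment] = []
    for helix in helices:
        if helix.length < w:
            continue
        dists = _per_residue_distances(cplx.protein, helix.indices(), dna_xyz)
        off, mean = _best_window(dists, w)
        if mean >= config.candidacy_cutoff:
            continue
        window = tuple(range(helix.start + off, helix.start + off + w))
        window_d = dists[off:off + w]
        base = dict(candidate_helix=helix, closest_window=window,
                    mean_window_distance=mean,
                    per_residue_distances=tuple(float(d) for d in window_d))
        if not check_orientation(window_d, config):
            out.append(HthAssessment(verdict="orientation", **base))
            continue
        central = find_central_residue(helix, cplx.protein, cplx.duplex)
        ok, neighbor = check_trihelical(helices, cplx.protein, central,
                                        helix, config)
        base.update(central_residue=central, helix_neighbor_distances=neighbor)
        out.append(HthAssessment(verdict="pass" if ok else "trihelical",
                                 **base))
    return [a for a in out if a.passed]
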