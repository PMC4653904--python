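"""DNA-anchored pairwise structural alignment of HTH-DNA complexes.

The optimal alignment of two complexes minimises the recognition-helix
C-alpha RMSD subject to the DNA backbone RMSD staying under a gate delta
(2 A).  The search is exhaustive over a small, fully constrained candidate
set:

1. Each complex contributes five *canonical matching regions* — contiguous
   5-bp windows of the duplex containing the basepair ``n`` closest to the
   central residue (starts ``n-4`` .. ``n``).
2. Any region of one complex can be superposed on any region of the other in
   two orientations (the mirror symmetry of dsDNA), giving 5 x 5 x 2 = 50
   candidates.  The correspondence is fixed — same backbone atom type, same
   sequential basepair order, 5'->3' direction preserved — so the
   constrained-ICP superposition collapses to a single closed-form
   least-squares step (proper rotations only).
3. Candidates with DNA RMSD >= delta are discarded.
4. For each survivor the recognition helices are mapped under every shift
   and N->C flip leaving at least ``m`` (8) residues overlapping, *without*
   re-superposing (the DNA-derived frame is what makes the constraint
   meaningful); the candidate and mapping with the lowest helix RMSD win.

All ties break deterministically: smallest |shift| (negative first),
unflipped before flipped, candidates in (region_a, region_b, orientation)
order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, Config
from .geometry import RigidTransform, rmsd_between, superpose
from .model import BACKBONE_CARBONS, Complex


class Orientation(enum.Enum):
    FORWARD = "forward"
    FLIPPED = "flipped"


class RegionError(ValueError):
    """The duplex cannot host the five canonical matching regions."""


class UnalignableError(ValueError):
    """No candidate alignment survived the DNA RMSD gate."""


def closest_basepair(cplx: Complex) -> int:
    """Basepair whose nearer C1' atom is closest to the central residue CA.

    Ties break toward the lowest basepair index.
    """
    if cplx.central_residue is None:
        raise ValueError("central residue not set (run detection first)")
    ca = cplx.protein[cplx.central_residue].ca.position
    best_i, best_d = 0, np.inf
    for i in range(cplx.duplex.n_basepairs):
        f, r = cplx.duplex.basepair(i)
        d = min(np.linalg.norm(ca - f.c1.position),
                np.linalg.norm(ca - r.c1.position))
        if d < best_d:
            best_i, best_d = i, d
    return best_i


@dataclass(frozen=True)
class CanonicalMatchingRegion:
    """A 5-bp window with its 50 backbone carbons in canonical order.

    ``forward_atoms``/``reverse_atoms`` are (span, 5, 3) arrays indexed by
    (basepair offset within the region, atom C1'..C5').
    """

    start_bp: int
    span: int
    forward_atoms: np.ndarray
    reverse_atoms: np.ndarray

    def coords(self, flipped: bool = False) -> np.ndarray:
        """Stacked (2*span*5, 3) coordinates in correspondence order.

        FORWARD order: forward strand bp 0..span-1, then reverse strand
        bp 0..span-1 (atoms C1'..C5' within each).  ``flipped`` returns the
        order that corresponds to the other region's FORWARD order under the
        180-degree mirror symmetry: reverse strand in reversed bp order
        first, then forward strand in reversed bp order.
        """
        if not flipped:
            return np.vstack([self.forward_atoms.reshape(-1, 3),
                              self.reverse_atoms.reshape(-1, 3)])
        return np.vstack([self.reverse_atoms[::-1].reshape(-1, 3),
                          self.forward_atoms[::-1].reshape(-1, 3)])


def canonical_matching_regions(cplx: Complex,
                               config: Config = DEFAULT_CONFIG
                               ) -> list[CanonicalMatchingRegion]:
    """The five 5-bp regions starting at n-4 .. n around the anchor bp n."""
    span = config.region_span
    n = closest_basepair(cplx)
    L = cplx.duplex.n_basepairs
    if n - (span - 1) < 0:
        raise RegionError(f"duplex too short on the 5' side of bp {n}")
    if n + (span - 1) > L - 1:
        raise RegionError(f"duplex too short on the 3' side of bp {n}")
    regions = []
    for start in range(n - span + 1, n + 1):
        fa = np.empty((span, 5, 3))
        ra = np.empty((span, 5, 3))
        for k in range(span):
            f, r = cplx.duplex.basepair(start + k)
            for m, name in enumerate(BACKBONE_CARBONS):
                fa[k, m] = f.atom(name).position
                ra[k, m] = r.atom(name).position
        regions.append(CanonicalMatchingRegion(start, span, fa, ra))
    return regions


def region_correspondence(region_a: CanonicalMatchingRegion,
                          region_b: CanonicalMatchingRegion,
                          orientation: Orientation
                          ) -> list[tuple[tuple, tuple]]:
    """Explicit atom-label correspondence for one candidate.

    Returns pairs of ``(basepair index, strand, atom name)`` labels; FORWARD
    maps forward<->forward and reverse<->reverse in identical basepair
    order, FLIPPED maps forward<->reverse with reversed basepair order (both
    preserve 5'->3' directionality and atom type).
    """
    span = region_a.span
    if span != region_b.span:
        raise ValueError("regions must have equal span")
    pairs = []
    for k in range(span):
        for name in BACKBONE_CARBONS:
            a_f = (region_a.start_bp + k, "F", name)
            a_r = (region_a.start_bp + k, "R", name)
            if orientation is Orientation.FORWARD:
                pairs.append((a_f, (region_b.start_bp + k, "F", name)))
            else:
                pairs.append((a_f, (region_b.start_bp + span - 1 - k, "R",
                                    name)))
    for k in range(span):
        for name in BACKBONE_CARBONS:
            a_r = (region_a.start_bp + k, "R", name)
            if orientation is Orientation.FORWARD:
                pairs.append((a_r, (region_b.start_bp + k, "R", name)))
            else:
                pairs.append((a_r, (region_b.start_bp + span - 1 - k, "F",
                                    name)))
    return pairs


@dataclass(frozen=True)
class CandidateAlignment:
    region_a: CanonicalMatchingRegion
    region_b: CanonicalMatchingRegion
    orientation: Orientation
    transform: RigidTransform
    dna_rmsd: float


def enumerate_candidates(cplx_a: Complex, cplx_b: Complex,
                         config: Config = DEFAULT_CONFIG
                         ) -> list[CandidateAlignment]:
    """All |regions_a| x |regions_b| x 2 candidate alignments, scored.

    Each candidate superposes region_a onto region_b under the fixed
    correspondence of its orientation and records the resulting DNA RMSD.
    """
    regions_a = canonical_matching_regions(cplx_a, config)
    regions_b = canonical_matching_regions(cplx_b, config)
    candidates = []
    for ra in regions_a:
        a_fwd = ra.coords(flipped=False)
        for rb in regions_b:
            for orientation in (Orientation.FORWARD, Orientation.FLIPPED):
                b = rb.coords(flipped=(orientation is Orientation.FLIPPED))
                transform, rmsd = superpose(a_fwd, b)
                candidates.append(CandidateAlignment(ra, rb, orientation,
                                                     transform, rmsd))
    return candidates


def gate_candidates(candidates: list[CandidateAlignment],
                    delta: float) -> list[CandidateAlignment]:
    """Keep candidates with DNA RMSD strictly below delta."""
    return [c for c in candidates if c.dna_rmsd < delta]


def helix_rmsd_under_mapping(helix_a: np.ndarray, helix_b: np.ndarray,
                             transform: RigidTransform, min_overlap: int = 8
                             ) -> tuple[float, list[tuple[int, int]],
                                        int, bool]:
    """Minimum CA RMSD over all shift/flip mappings of two helices.

    The helices are *not* re-superposed: ``helix_a`` is moved by the fixed
    DNA-derived ``transform`` and compared against ``helix_b`` under every
    residue mapping with at least ``min_overlap`` aligned residues.  Returns
    (rmsd, residue map as (index_a, index_b) pairs, shift, flipped).
    """
    la, lb = len(helix_a), len(helix_b)
    if la < min_overlap or lb < min_overlap:
        raise ValueError(f"helices must have >= {min_overlap} residues")
    a_moved = transform.apply(np.asarray(helix_a, dtype=float))
    b = np.asarray(helix_b, dtype=float)

    shifts = sorted(range(-(la - min_overlap), lb - min_overlap + 1),
                    key=lambda s: (abs(s), s > 0))
    best: tuple[float, list[tuple[int, int]], int, bool] | None = None
    for flipped in (False, True):
        b_eff = b[::-1] if flipped else b
        for s in shifts:
            i_lo = max(0, -s)
            i_hi = min(la, lb - s)
            if i_hi - i_lo < min_overlap:
                continue
            idx_a = np.arange(i_lo, i_hi)
            idx_b_eff = idx_a + s
            rmsd = rmsd_between(a_moved[idx_a], b_eff[idx_b_eff])
            if best is None or rmsd < best[0] - 1e-12:
                idx_b = (lb - 1 - idx_b_eff) if flipped else idx_b_eff
                mapping = list(zip(idx_a.tolist(), idx_b.tolist()))
                best = (rmsd, mapping, s, flipped)
    return best


@dataclass
class PairwiseAlignment:
    """Final alignment of a pair of complexes.

    ``residue_map``/``basepair_map`` are (index in a, index in b) pairs;
    the basepair map extends the winning region register across the full
    overlap of both duplexes, respecting orientation.
    """

    transform: RigidTransform
    dna_rmsd: float
    helix_rmsd: float
    residue_map: list[tuple[int, int]]
    basepair_map: list[tuple[int, int]]
    orientation: Orientation
    delta: float
    region_a_start: int
    region_b_start: int


def _extend_basepair_map(candidate: CandidateAlignment, la: int, lb: int
                         ) -> list[tuple[int, int]]:
    sa, sb = candidate.region_a.start_bp, candidate.region_b.start_bp
    span = candidate.region_a.span
    if candidate.orientation is Orientation.FORWARD:
        off = sb - sa
        return [(i, i + off) for i in range(max(0, -off), min(la, lb - off))]
    c = sa + sb + span - 1
    return [(i, c - i) for i in range(max(0, c - lb + 1), min(la, c + 1))]


def align_pair(cplx_a: Complex, cplx_b: Complex,
               config: Config = DEFAULT_CONFIG) -> PairwiseAlignment | None:
    """Best alignment of two detected complexes, or ``None`` if unalignable.

    Unalignable means either duplex cannot host the five canonical regions,
    or no candidate's DNA RMSD passes the delta gate.
    """
    try:
        candidates = enumerate_candidates(cplx_a, cplx_b, config)
    except RegionError:
        return None
    survivors = gate_candidates(candidates, config.delta)
    if not survivors:
        return None
    helix_a = cplx_a.helix_ca_coords()
    helix_b = cplx_b.helix_ca_coords()
    best = None
    for cand in survivors:
        rmsd, mapping, _, _ = helix_rmsd_under_mapping(
            helix_a, helix_b, cand.transform, config.min_overlap)
        if best is None or rmsd < best[0] - 1e-12:
            best = (rmsd, mapping, cand)
    helix_rmsd, mapping, cand = best
    start_a = cplx_a.recognition_helix[0]
    start_b = cplx_b.recognition_helix[0]
    residue_map = [(start_a + i, start_b + j) for i, j in mapping]
    bp_map = _extend_basepair_map(cand, cplx_a.duplex.n_basepairs,
                                  cplx_b.duplex.n_basepairs)
    return PairwiseAlignment(
        transform=cand.transform, dna_rmsd=cand.dna_rmsd,
        helix_rmsd=helix_rmsd, residue_map=residue_map, basepair_map=bp_map,
        orientation=cand.orientation, delta=config.delta,
        region_a_start=cand.region_a.start_bp,
        region_b_start=cand.region_b.start_bp)
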