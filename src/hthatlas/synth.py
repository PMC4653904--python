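"""Synthetic HTH-DNA complex generator with ground truth.

Builds idealized B-DNA duplexes (3.4 A rise, 36 deg twist — textbook values)
carrying only the five deoxyribose backbone carbons per nucleotide, and
tri-helical C-alpha-trace protein bundles whose third (recognition) helix is
docked against the major-groove rim of the DNA.  Every emitted complex comes
with a :class:`GroundTruth` record (recognition-helix range, central residue,
anchor basepair, applied transform) so each pipeline stage can be tested
against known answers without any downloaded structures.

Proteins are C-alpha traces plus one side-chain pseudo-atom (CB) per residue;
all distance definitions used by the pipeline involve only CA atoms, DNA
backbone carbons, or minima over all atoms, so this reduced representation
exercises every code path.

Decoy fixtures violating exactly one HTH-detection criterion (candidacy,
orientation, or the tri-helical bundle check) can be produced on demand, as
can complexes whose DNA is sharply bent at the anchor basepair step (used to
exercise outlier handling during atlas construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import RigidTransform
from .model import (AA1_TO_3, BACKBONE_CARBONS, COMPLEMENT, Atom, Complex,
                    DnaDuplex, Nucleotide, Residue)

# Deoxyribose backbone carbon placement: (name, radius A, dphi deg, dz A).
# The C1' radius (5.9 A) together with the inter-strand phase offset GAMMA
# puts paired C1' atoms 10.5 A apart, and the outward dphi spread widens the
# angular separation of the outer backbone across the minor groove.
_BACKBONE_LAYOUT = (
    ("C1'", 5.9, 0.0, 0.0),
    ("C2'", 6.7, 4.0, -0.3),
    ("C3'", 7.3, 9.0, 0.7),
    ("C4'", 7.9, 14.0, 0.2),
    ("C5'", 8.6, 19.0, -0.5),
)
_PAIR_C1_DISTANCE = 10.5
GAMMA_DEG = math.degrees(2.0 * math.asin(_PAIR_C1_DISTANCE / (2 * 5.9)))

# ideal alpha-helix C-alpha trace parameters
_HELIX_RISE = 1.5        # A per residue along the axis
_HELIX_RADIUS = 2.3      # A, CA circle radius
_HELIX_TWIST = 100.0     # deg per residue
_CB_RADIUS = 3.3         # A, side-chain pseudo-atom circle radius

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


@dataclass
class SynthParams:
    """Generator settings; the defaults satisfy every detection criterion."""

    dna_length: int = 20
    dna_rise: float = 3.4
    dna_twist: float = 36.0
    helix_lengths: tuple[int, int, int] = (10, 10, 12)
    dock_distance: float = 2.8   # A, recognition-helix axis to groove rim
    support_offset: float = 9.0  # A, support-helix axes beyond the recognition axis
    bend_angle: float = 0.0     # deg; > 0 kinks the DNA at the anchor bp step
    noise_sigma: float = 0.0    # A, isotropic Gaussian jitter
    seed: int = 0
    sequence: str | None = None  # forward-strand bases; random if None
    dock_bp: int | None = None   # anchor basepair; centred if None

    def __post_init__(self):
        if self.dna_length < 9:
            raise ValueError("dna_length must be >= 9 (5-bp regions around n)")
        if len(self.helix_lengths) != 3 or min(self.helix_lengths) < 5:
            raise ValueError("need three helices of >= 5 residues")


@dataclass
class GroundTruth:
    recognition_helix: tuple[int, int]   # half-open residue range
    central_residue: int
    closest_basepair: int
    transform: RigidTransform = field(default_factory=RigidTransform.identity)


def make_ideal_bdna(sequence: str, params: SynthParams | None = None) -> DnaDuplex:
    """Idealized straight B-DNA duplex for the given forward-strand sequence.

    Each nucleotide carries the five backbone carbons C1'-C5' placed on
    helical cylinders (rise/twist per ``params``); the complementary strand is
    generated antiparallel and the basepair list annotated.
    """
    params = params or SynthParams(dna_length=max(9, len(sequence)))
    sequence = sequence.upper()
    bad = set(sequence) - set(_BASES)
    if bad or not sequence:
        raise ValueError(f"invalid bases in sequence: {sorted(bad) or 'empty'}")
    L = len(sequence)
    rise, twist = params.dna_rise, params.dna_twist

    def atom_pos(bp: int, dphi: float, radius: float, dz: float,
                 strand_gamma: float, mirror: float) -> np.ndarray:
        ang = math.radians(bp * twist + strand_gamma + mirror * dphi)
        return np.array([radius * math.cos(ang), radius * math.sin(ang),
                         bp * rise + mirror * dz])

    forward: list[Nucleotide] = []
    reverse: list[Nucleotide] = []
    for i, base in enumerate(sequence):
        atoms = [Atom(name, "C", atom_pos(i, dphi, r, dz, 0.0, 1.0))
                 for name, r, dphi, dz in _BACKBONE_LAYOUT]
        forward.append(Nucleotide(i, base, atoms))
    for j in range(L):
        p = L - 1 - j                      # paired forward index
        base = COMPLEMENT[sequence[p]]
        atoms = [Atom(name, "C", atom_pos(p, dphi, r, dz, GAMMA_DEG, -1.0))
                 for name, r, dphi, dz in _BACKBONE_LAYOUT]
        reverse.append(Nucleotide(j, base, atoms))
    pairs = [(i, L - 1 - i) for i in range(L)]
    duplex = DnaDuplex(forward, reverse, pairs)
    duplex.validate()
    return duplex


def _ideal_helix(center: np.ndarray, direction: np.ndarray, inward: np.ndarray,
                 n_res: int) -> tuple[np.ndarray, np.ndarray]:
    """CA and CB coordinates of an ideal helix around an axis line.

    ``inward`` fixes the phase: the middle residue's side chain points along
    it (toward the DNA for the recognition helix).
    """
    t_hat = direction / np.linalg.norm(direction)
    e1 = inward - (inward @ t_hat) * t_hat
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(t_hat, e1)
    t_c = (n_res - 1) / 2.0
    ca, cb = [], []
    for t in range(n_res):
        psi = math.radians(_HELIX_TWIST * (t - t_c))
        axis_pt = center + (t - t_c) * _HELIX_RISE * t_hat
        radial = math.cos(psi) * e1 + math.sin(psi) * e2
        ca.append(axis_pt + _HELIX_RADIUS * radial)
        cb.append(axis_pt + _CB_RADIUS * radial)
    return np.array(ca), np.array(cb)


def _loop_path(start: np.ndarray, end: np.ndarray, away: np.ndarray,
               n_res: int) -> np.ndarray:
    """Loop C-alphas on an arc bulging along ``away``, non-helical spacing."""
    pts = []
    for k in range(1, n_res + 1):
        f = k / (n_res + 1)
        bulge = math.sin(math.pi * f) * 5.0
        pts.append(start + f * (end - start) + bulge * away)
    return np.array(pts)


def _min_dists_to_dna(ca: np.ndarray, cb: np.ndarray,
                      dna_xyz: np.ndarray) -> np.ndarray:
    """Per-residue min distance over {CA, CB} x all DNA atoms."""
    d_ca = cdist(ca, dna_xyz).min(axis=1)
    d_cb = cdist(cb, dna_xyz).min(axis=1)
    return np.minimum(d_ca, d_cb)


def _dock_frame(duplex: DnaDuplex, n: int):
    """Anchor point, strand tangent and outward groove direction at bp n."""
    fwd = duplex.forward
    anchor = fwd[n].coords().mean(axis=0)
    lo, hi = max(0, n - 1), min(len(fwd) - 1, n + 1)
    tangent = fwd[hi].coords().mean(axis=0) - fwd[lo].coords().mean(axis=0)
    tangent = tangent / np.linalg.norm(tangent)
    radial = np.array([anchor[0], anchor[1], 0.0])
    radial = radial / np.linalg.norm(radial)
    out = radial + np.array([0.0, 0.0, 1.0])   # radially out and up into the groove
    out = out - (out @ tangent) * tangent
    out = out / np.linalg.norm(out)
    return anchor, tangent, out


def _build_bundle(duplex: DnaDuplex, n: int, params: SynthParams,
                  tilt_deg: float = 0.0, dock_extra: float = 0.0,
                  support_offset: float | None = None):
    """Coordinates of the tri-helical bundle docked at basepair ``n``.

    Returns (segments, recognition CA/CB arrays) where ``segments`` is the
    ordered list of ('helix'|'loop', ca_array, cb_array_or_None).
    """
    anchor, tangent, out = _dock_frame(duplex, n)
    s_off = params.support_offset if support_offset is None else support_offset
    len1, len2, len3 = params.helix_lengths

    rec_dir = tangent
    if tilt_deg:
        tau = math.radians(tilt_deg)
        rec_dir = math.cos(tau) * tangent + math.sin(tau) * out
        rec_dir = rec_dir / np.linalg.norm(rec_dir)
    rec_center = anchor + (params.dock_distance + dock_extra) * out
    rec_ca, rec_cb = _ideal_helix(rec_center, rec_dir, -out, len3)

    c1 = rec_center + s_off * out - 5.0 * tangent
    c2 = rec_center + s_off * out + 5.0 * tangent
    h1_ca, h1_cb = _ideal_helix(c1, tangent, -out, len1)
    h2_ca, h2_cb = _ideal_helix(c2, -tangent, -out, len2)

    side = np.cross(tangent, out)
    loop1 = _loop_path(h1_ca[-1], h2_ca[0], side, 3)
    loop2 = _loop_path(h2_ca[-1], rec_ca[0], side, 3)
    segments = [
        ("helix", h1_ca, h1_cb),
        ("loop", loop1, None),
        ("helix", h2_ca, h2_cb),
        ("loop", loop2, None),
        ("helix", rec_ca, rec_cb),
    ]
    return segments, rec_ca, rec_cb


def _segments_to_residues(segments, rng: np.random.Generator
                          ) -> tuple[list[Residue], tuple[int, int]]:
    """Chain residues from bundle segments; returns recognition-helix range."""
    residues: list[Residue] = []
    rec_range = (0, 0)
    idx = 0
    for kind, ca, cb in segments:
        start = idx
        for t in range(len(ca)):
            aa = _AA20[rng.integers(len(_AA20))]
            atoms = [Atom("CA", "C", ca[t])]
            if cb is not None:
                atoms.append(Atom("CB", "C", cb[t]))
            residues.append(Residue(idx, aa, atoms))
            idx += 1
        if kind == "helix":
            rec_range = (start, idx)     # last helix wins: the recognition helix
    return residues, rec_range


def _axis_nearest(residues: list[Residue], rec_range: tuple[int, int]) -> int:
    # ground truth from the construction axis (the z-axis of the ideal duplex)
    ca = np.array([residues[i].ca.position
                   for i in range(rec_range[0], rec_range[1])])
    return int(np.argmin(np.hypot(ca[:, 0], ca[:, 1])))


def _closest_basepair(central_ca: np.ndarray, duplex: DnaDuplex) -> int:
    # independent inline rule: min over the two C1' atoms of each basepair
    best, best_i = np.inf, 0
    for i in range(duplex.n_basepairs):
        f, r = duplex.basepair(i)
        d = min(np.linalg.norm(central_ca - f.c1.position),
                np.linalg.norm(central_ca - r.c1.position))
        if d < best:
            best, best_i = d, i
    return best_i


def _apply_bend(duplex: DnaDuplex, residues: list[Residue], n: int,
                bend_angle: float, rise: float) -> None:
    """Kink the duplex at the n -> n+1 basepair step.

    Basepairs above the kink *and the protein* (which tracks the groove
    around the anchor) are rotated by ``bend_angle`` about a horizontal axis
    through the step midpoint, so the domain's pose relative to the lower
    DNA arm changes by the full bend angle.
    """
    pivot = np.array([0.0, 0.0, (n + 0.5) * rise])
    axis = np.array([0.0, 0.0, 1.0])
    anchor, _, _ = _dock_frame(duplex, n)
    radial = np.array([anchor[0], anchor[1], 0.0])
    radial /= np.linalg.norm(radial)
    bend_axis = np.cross(axis, radial)
    from scipy.spatial.transform import Rotation
    R = Rotation.from_rotvec(math.radians(bend_angle) * bend_axis).as_matrix()

    def rot(p: np.ndarray) -> np.ndarray:
        return R @ (p - pivot) + pivot

    L = duplex.n_basepairs
    for i in range(n + 1, L):
        fi, ri = duplex.pairs[i]
        for holder, j in ((duplex.forward, fi), (duplex.reverse, ri)):
            nt = holder[j]
            holder[j] = Nucleotide(nt.seq_index, nt.base,
                                   [Atom(a.name, a.element, rot(a.position))
                                    for a in nt.atoms])
    for k, res in enumerate(residues):
        residues[k] = Residue(res.seq_index, res.aa_code,
                              [Atom(a.name, a.element, rot(a.position))
                               for a in res.atoms])


def _finalize(duplex: DnaDuplex, residues: list[Residue],
              rec_range: tuple[int, int], params: SynthParams,
              rng: np.random.Generator, structure_id: str
              ) -> tuple[Complex, GroundTruth]:
    if params.noise_sigma > 0:
        def jitter(atoms: list[Atom]) -> list[Atom]:
            return [Atom(a.name, a.element,
                         a.position + rng.normal(0.0, params.noise_sigma, 3))
                    for a in atoms]
        residues = [Residue(r.seq_index, r.aa_code, jitter(r.atoms))
                    for r in residues]
        duplex = DnaDuplex(
            [Nucleotide(n.seq_index, n.base, jitter(n.atoms))
             for n in duplex.forward],
            [Nucleotide(n.seq_index, n.base, jitter(n.atoms))
             for n in duplex.reverse],
            list(duplex.pairs))

    central = rec_range[0] + _axis_nearest(residues, rec_range)
    cplx = Complex(structure_id, "A", residues, duplex, resolution=2.0,
                   recognition_helix=rec_range, central_residue=central)
    n_bp = _closest_basepair(residues[central].ca.position, duplex)
    truth = GroundTruth(rec_range, central, n_bp)
    return cplx, truth


def make_hth_complex(params: SynthParams | None = None,
                     structure_id: str = "SYN1"
                     ) -> tuple[Complex, GroundTruth]:
    """A tri-helical HTH C-alpha-trace domain docked on idealized B-DNA.

    Default parameters satisfy all three detection criteria; ``bend_angle``
    > 0 kinks the DNA at the anchor basepair step for atlas outlier tests.
    """
    params = params or SynthParams()
    rng = np.random.default_rng(params.seed)
    seq = params.sequence or "".join(
        _BASES[rng.integers(4)] for _ in range(params.dna_length))
    if len(seq) != params.dna_length:
        params = replace(params, dna_length=len(seq))
    duplex = make_ideal_bdna(seq, params)
    n = params.dock_bp if params.dock_bp is not None else params.dna_length // 2
    if not (4 <= n <= params.dna_length - 5):
        raise ValueError("dock_bp must leave 4 bp on both sides")
    segments, _, _ = _build_bundle(duplex, n, params)
    residues, rec_range = _segments_to_residues(segments, rng)
    if params.bend_angle:
        _apply_bend(duplex, residues, n, params.bend_angle, params.dna_rise)
    return _finalize(duplex, residues, rec_range, params, rng, structure_id)


def make_decoy(params: SynthParams | None = None, criterion: str = "candidacy",
               structure_id: str = "DECOY") -> tuple[Complex, GroundTruth]:
    """A complex violating exactly one detection criterion.

    ``criterion`` is one of ``candidacy`` (recognition helix pulled 8 A away
    from the DNA), ``orientation`` (helix tilted so the closest five-residue
    window still averages under 5 A but one residue exceeds 6.5 A), or
    ``trihelical`` (support helices pushed beyond the 18 A bundle cutoff).
    """
    params = params or SynthParams()
    rng = np.random.default_rng(params.seed)
    seq = params.sequence or "".join(
        _BASES[rng.integers(4)] for _ in range(params.dna_length))
    duplex = make_ideal_bdna(seq, params)
    n = params.dock_bp if params.dock_bp is not None else params.dna_length // 2

    if criterion == "candidacy":
        segments, _, _ = _build_bundle(duplex, n, params, dock_extra=8.0)
    elif criterion == "trihelical":
        segments, _, _ = _build_bundle(duplex, n, params, support_offset=26.0)
    elif criterion == "orientation":
        segments = _search_orientation_decoy(duplex, n, params)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    residues, rec_range = _segments_to_residues(segments, rng)
    return _finalize(duplex, residues, rec_range, params, rng, structure_id)


def _search_orientation_decoy(duplex: DnaDuplex, n: int, params: SynthParams):
    """Deterministic search for a tilt whose closest 5-window passes the mean
    criterion (< 5 A) while violating the 6.5 A per-residue cutoff."""
    dna_xyz = duplex.coords()
    w = 5
    for tilt in np.arange(20.0, 62.0, 2.0):
        for extra in np.arange(0.0, 3.6, 0.5):
            segments, rec_ca, rec_cb = _build_bundle(
                duplex, n, params, tilt_deg=tilt, dock_extra=extra)
            d = _min_dists_to_dna(rec_ca, rec_cb, dna_xyz)
            means = np.array([d[i:i + w].mean() for i in range(len(d) - w + 1)])
            i = int(np.argmin(means))
            window = d[i:i + w]
            if window.mean() < 4.85 and window.max() > 6.7:
                return segments
    raise ValueError("no orientation-violating geometry found for params")


def perturb(cplx: Complex, rotation: np.ndarray, translation: np.ndarray,
            noise_sigma: float = 0.0, seed: int = 0
            ) -> tuple[Complex, GroundTruth]:
    """Rigidly move a complex, then add isotropic Gaussian jitter.

    Improper rotations (det -1) are refused.  Deterministic per ``seed``.
    """
    transform = RigidTransform(rotation, translation)   # validates properness
    moved = cplx.transformed(transform)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)

        def jitter(atoms):
            return [Atom(a.name, a.element,
                         a.position + rng.normal(0.0, noise_sigma, 3))
                    for a in atoms]

        moved = Complex(
            moved.structure_id, moved.chain_id,
            [Residue(r.seq_index, r.aa_code, jitter(r.atoms))
             for r in moved.protein],
            DnaDuplex([Nucleotide(x.seq_index, x.base, jitter(x.atoms))
                       for x in moved.duplex.forward],
                      [Nucleotide(x.seq_index, x.base, jitter(x.atoms))
                       for x in moved.duplex.reverse],
                      list(moved.duplex.pairs)),
            moved.resolution, moved.recognition_helix, moved.central_residue)
    central = moved.central_residue
    n_bp = (_closest_basepair(moved.protein[central].ca.position, moved.duplex)
            if central is not None else 0)
    truth = GroundTruth(moved.recognition_helix or (0, 0), central or 0,
                        n_bp, transform)
    return moved, truth


def make_multi_domain_complex(params: SynthParams, dock_bps: list[int],
                              structure_id: str = "SYN2"
                              ) -> tuple[Complex, list[GroundTruth]]:
    """One protein chain carrying several HTH bundles on a shared duplex."""
    rng = np.random.default_rng(params.seed)
    seq = params.sequence or "".join(
        _BASES[rng.integers(4)] for _ in range(params.dna_length))
    duplex = make_ideal_bdna(seq, params)
    residues: list[Residue] = []
    truths: list[GroundTruth] = []
    for n in dock_bps:
        if not (4 <= n <= params.dna_length - 5):
            raise ValueError("dock_bp must leave 4 bp on both sides")
        segments, _, _ = _build_bundle(duplex, n, params)
        offset = len(residues)
        part, rec_range = _segments_to_residues(segments, rng)
        for r in part:
            residues.append(Residue(offset + r.seq_index, r.aa_code, r.atoms))
        rec = (rec_range[0] + offset, rec_range[1] + offset)
        central = rec[0] + _axis_nearest(residues, rec)
        n_bp = _closest_basepair(residues[central].ca.position, duplex)
        truths.append(GroundTruth(rec, central, n_bp))
    cplx = Complex(structure_id, "A", residues, duplex, resolution=2.0)
    return cplx, truths
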