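"""Position weight matrices from curated binding sites, mapped to structure.

Binding sites (experimentally determined DNA sequences a protein binds) are
deduplicated per experiment, placed ungapped on the complex's own duplex
sequence on either strand, and tallied into per-position nucleotide counts.
Laplace smoothing with pseudocount alpha (default 1) turns counts into
probabilities; positions with no data get the uniform non-informative prior.
Each PWM column is then tied to a duplex basepair position so that every
basepair of the structure carries a probability distribution over the four
nucleotides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Complex, reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class BindingSite:
    complex_id: str
    sequence: str
    source: str = ""
    experiment_type: str = ""
    quality: str | None = None
    provenance_id: str | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq or set(seq) - set(BASES):
            raise ValueError(f"invalid binding-site sequence {self.sequence!r}")
        object.__setattr__(self, "sequence", seq)


def read_sites_tsv(path: str | Path) -> list[BindingSite]:
    """TSV columns: complex_id, sequence, source, experiment_type, quality,
    provenance_id (trailing columns optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(BindingSite(
            complex_id=row.complex_id, sequence=row.sequence,
            source=getattr(row, "source", ""),
            experiment_type=getattr(row, "experiment_type", ""),
            quality=getattr(row, "quality", "") or None,
            provenance_id=getattr(row, "provenance_id", "") or None))
    return sites


def dedupe_sites(sites: list[BindingSite]) -> list[BindingSite]:
    """At most one site per (provenance id, sequence).

    The same experiment reported by several repositories collapses to one
    record; distinct experiments reporting the same sequence are retained,
    as are sites without provenance.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for site in sites:
        if site.provenance_id is None:
            out.append(site)
            continue
        key = (site.provenance_id, site.sequence)
        if key not in seen:
            seen.add(key)
            out.append(site)
    return out


@dataclass(frozen=True)
class SitePlacement:
    site: BindingSite
    offset: int
    strand: str           # '+' or '-'
    matches: int
    placed: str           # sequence in reference coordinates


@dataclass
class AlignedBlock:
    reference: str
    placements: list[SitePlacement] = field(default_factory=list)


def align_sites(sites: list[BindingSite], reference: str) -> AlignedBlock:
    """Place each site ungapped on the reference (the duplex forward-strand
    sequence), on the offset and strand maximising matches.

    Ties prefer the forward strand, then the smallest offset.  Sites longer
    than the reference are trimmed to its length with a warning.
    """
    reference = reference.upper()
    L = len(reference)
    block = AlignedBlock(reference)
    for site in sites:
        seq = site.sequence
        if len(seq) > L:
            logger.warning("site %r longer than reference; trimmed to %d nt",
                           seq, L)
            seq = seq[:L]
        best: tuple[int, int, str, str] | None = None   # matches,offset,strand
        for strand in "+-":
            oriented = seq if strand == "+" else reverse_complement(seq)
            for off in range(L - len(seq) + 1):
                m = sum(a == b for a, b in
                        zip(oriented, reference[off:off + len(seq)]))
                if best is None or m > best[0]:
                    best = (m, off, strand, oriented)
        m, off, strand, oriented = best
        block.placements.append(SitePlacement(site, off, strand, m, oriented))
    return block


def exact_block(sites: list[BindingSite], reference: str) -> AlignedBlock:
    """Place pre-registered sites at offset 0 on the forward strand.

    For sites already expressed in reference coordinates (e.g. sequences
    drawn from a PWM of the reference's length) no alignment search is
    needed or wanted.
    """
    block = AlignedBlock(reference.upper())
    for site in sites:
        if len(site.sequence) != len(block.reference):
            raise ValueError("exact placement needs equal lengths")
        m = sum(a == b for a, b in zip(site.sequence, block.reference))
        block.placements.append(SitePlacement(site, 0, "+", m, site.sequence))
    return block


@dataclass
class Pwm:
    """Per-position probability distributions over A, C, G, T.

    ``probs`` is (L, 4) with every row summing to 1; ``support`` holds the
    number of observed nucleotides per column.
    """

    probs: np.ndarray
    support: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if np.abs(self.probs.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def to_text(self) -> str:
        """4 rows (A, C, G, T) x L tab-separated columns."""
        lines = []
        for b, base in enumerate(BASES):
            vals = "\t".join(f"{p:.6f}" for p in self.probs[:, b])
            lines.append(f"{base}\t{vals}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Pwm":
        rows = {}
        for line in text.strip().splitlines():
            parts = line.split("\t")
            rows[parts[0]] = [float(x) for x in parts[1:]]
        probs = np.array([rows[b] for b in BASES]).T
        support = np.zeros(probs.shape[0], dtype=int)
        return cls(probs, support)


def count_matrix(block: AlignedBlock) -> np.ndarray:
    """(L, 4) nucleotide counts from an aligned site block."""
    counts = np.zeros((len(block.reference), 4))
    for placement in block.placements:
        for k, base in enumerate(placement.placed):
            counts[placement.offset + k, _BASE_INDEX[base]] += 1
    return counts


def build_pwm(block: AlignedBlock, alpha: float = 1.0) -> Pwm:
    """Laplace-smoothed empirical frequencies per reference position.

    A column with counts c and total N becomes (c + alpha) / (N + 4 alpha);
    a column with no data at all is the uniform prior (1/4 each).
    """
    counts = count_matrix(block)
    totals = counts.sum(axis=1)
    probs = np.empty_like(counts)
    for i, n in enumerate(totals):
        if n == 0:
            probs[i] = 0.25
        else:
            probs[i] = (counts[i] + alpha) / (n + 4 * alpha)
    return Pwm(probs, totals.astype(int))


@dataclass
class StructurePwmMap:
    """Injective, order-preserving tie between PWM columns and basepairs.

    ``entries`` holds (column, basepair) pairs; basepairs without a column
    report the uniform prior.  With reverse orientation column ``i`` sits on
    basepair ``offset + L - 1 - i`` and its distribution is complement-
    swapped into the forward-strand frame.
    """

    pwm: Pwm
    n_basepairs: int
    offset: int = 0
    orientation: str = "+"
    entries: list[tuple[int, int]] = field(default_factory=list)

    def distribution(self, basepair: int) -> np.ndarray:
        if not (0 <= basepair < self.n_basepairs):
            raise IndexError(f"basepair {basepair} out of range")
        for col, bp in self.entries:
            if bp == basepair:
                probs = self.pwm.probs[col]
                if self.orientation == "-":
                    probs = probs[::-1]      # complement swap: A<->T, C<->G
                return probs.copy()
        return np.full(4, 0.25)


def map_pwm_to_structure(pwm: Pwm, cplx: Complex, offset: int = 0,
                         orientation: str = "+") -> StructurePwmMap:
    """Tie PWM columns to duplex basepair positions."""
    L = cplx.duplex.n_basepairs
    if orientation not in "+-":
        raise ValueError("orientation must be '+' or '-'")
    entries = []
    for col in range(pwm.length):
        bp = (offset + col if orientation == "+"
              else offset + pwm.length - 1 - col)
        if 0 <= bp < L:
            entries.append((col, bp))
    bps = [bp for _, bp in entries]
    if len(set(bps)) != len(bps):
        raise ValueError("mapping is not injective")
    return StructurePwmMap(pwm, L, offset, orientation, entries)


def sample_sites_from_pwm(pwm: Pwm, n: int, seed: int = 0) -> list[str]:
    """Draw ``n`` sequences column-independently; deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = [rng.choice(4, size=n, p=pwm.probs[i] / pwm.probs[i].sum())
            for i in range(pwm.length)]
    return ["".join(BASES[cols[i][k]] for i in range(pwm.length))
            for k in range(n)]
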