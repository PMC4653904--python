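# Methods

This note records the model, the parameter choices, the numerical decisions,
and the known limitations of `hthatlas`.

## Structure model

A `Complex` is one HTH domain bound to one double-stranded DNA fragment:

- **Protein**: a list of residues indexed 0-based N→C. Synthetic fixtures
  carry Cα and a Cβ pseudo-atom per residue; crystal-derived complexes keep
  all atoms. All ranges are half-open `[start, stop)`.
- **DNA**: a `DnaDuplex` with both strands stored 5′→3′ and an explicit
  pairing `(i, L-1-i)`; validation enforces bijective, antiparallel,
  Watson–Crick-complementary pairing. Basepair indices follow the forward
  strand.
- Standardization never moves atoms: it only reorders nucleotides, removes
  unpaired terminal overhangs, and renumbers. Pairing is established
  geometrically: complementary bases whose C1′–C1′ distance is
  10.5 ± 1.5 Å, resolved by minimum-cost bipartite matching, then checked
  for antiparallel monotonicity and interior gaps.

## Detection criteria and parameters

Helices are assigned geometrically when no HELIX records are given: residue
`i` is marked helical when `|Cα(i)−Cα(i+3)| ∈ [4.5, 6.5]` Å and
`|Cα(i)−Cα(i+4)| ∈ [5.5, 7.5]` Å; maximal runs of marks span `[s, e+5)`.

A helix is a DNA-bound recognition helix when, in order:

1. **Candidacy** — the best window of 5 contiguous residues has mean
   minimum-distance-to-DNA strictly below 5 Å (distance = closest atom pair).
2. **Orientation** — every one of those 5 residues is within 6.5 Å
   (inclusive). This rejects helices approaching the DNA end-on.
3. **Tri-helical bundle** — the protein has ≥ 3 helices and the central
   residue's Cα is within 18 Å of at least one residue in each of ≥ 2 other
   helices.

The **central residue** is the helix residue whose Cα is closest to the DNA
major axis (principal axis of the backbone carbons, direction canonicalized
toward increasing forward-strand index). Ties everywhere break toward the
lowest index, making detection deterministic.

## Redundancy

The recognition sequence is the 41-residue window (±20) around the central
residue, GAP-padded at chain ends. The distance between two windows is the
minimum mismatch count over shifts |s| ≤ 15 (the bound that keeps the
11-residue windows flanking both central residues inside the overlap); any
column containing a GAP counts as a mismatch, so truncated chains can never
be spuriously redundant. Zero-distance pairs are edges of a graph; one
representative per connected component survives (max degree, then best
resolution with missing values sorting last, then lexicographic id).

## DNA-anchored alignment

The alignment of two complexes is constrained to superpositions of their
DNA near the protein anchor:

- Anchor basepair `n` = the basepair whose nearer C1′ is closest to the
  central residue's Cα.
- Five **canonical matching regions**: the 5-bp windows starting at
  `n−4 … n` (all contain `n`). Each region contributes 50 backbone carbons
  (C1′–C5′ on both strands).
- 5 × 5 regions × 2 orientations = **50 candidates**. The atom
  correspondence of each candidate is fully fixed (same atom type, same
  sequential order, 5′→3′ preserved; the flipped orientation uses the
  duplex's 180° pseudo-dyad), so iterative closest-point under these
  constraints degenerates to a single closed-form least-squares rotation
  (scipy `Rotation.align_vectors`, proper rotations only).
- The **gate**: candidates with DNA RMSD ≥ δ = 2 Å are discarded; if none
  survive the pair is unalignable.
- The **score**: recognition-helix Cα RMSD under the DNA-derived transform,
  minimized over all residue shifts and N→C flips with ≥ m = 8 overlapping
  residues. The helices are *not* re-superposed — that is what makes the
  DNA constraint binding. Ties break by smallest |shift| (negative first),
  unflipped first, then candidate enumeration order; improvements must
  exceed 1e-12 so the first-enumerated optimum wins exact ties.

## Atlas and unified coordinate system

Pairwise helix RMSDs (sentinel 1e4 for unalignable pairs) feed affinity
propagation (similarity = −distance, damping 0.9, up to 1000 iterations,
convergence window 50, fixed random state). The preference is scanned over
the 5–95 % quantiles of the off-diagonal similarities plus their median; the
winning preference maximizes the largest-cluster size subject to every
member lying within 3.5 Å of its exemplar. The *maximum* member-to-exemplar
distance is used for this bound rather than a median-type statistic because
a single far outlier must be able to invalidate a clustering.

The exemplar of the main cluster anchors the UCS: universal residue and
basepair indices are the exemplar's own indices; each member's alignment to
the exemplar supplies its rigid transform and index maps, and member-to-
member correspondences go transitively through the exemplar. Because
message passing can converge to a merged configuration on small or
degenerate distance matrices, UCS construction additionally evicts any
main-cluster member whose helix RMSD to the exemplar exceeds 3.5 Å,
recording it as an outlier with the numeric reason.

## PWM and contacts

Binding sites are deduplicated per (provenance id, sequence), placed
ungapped on the duplex forward-strand sequence at the offset and strand
maximizing matches, and tallied per position. Probabilities use Laplace
smoothing `(c + α)/(N + 4α)` with α = 1; positions with no data are the
uniform prior. Columns are tied injectively to basepair positions; mapping
through the reverse orientation reverses column order and complement-swaps
the distribution (A↔T, C↔G is index reversal in A,C,G,T order).

Contacts are protein–DNA atom pairs within 5 Å, computed with a k-d tree
and verified against a brute-force oracle. The pooled contact frequency of
a universal (residue, basepair) cell is the fraction of member structures
with at least one contact mapping there — duplicates within one structure
count once.

## Synthetic generator

The generator produces fixtures with exact ground truth; its defaults are
study conditions, fixed before testing:

- **DNA**: idealized straight B-DNA — rise 3.4 Å, twist 36°/bp, C1′ at
  radius 5.9 Å with an inter-strand phase of 2·asin(10.5/11.8) ≈ 125.7°, so
  paired C1′–C1′ distances are exactly 10.5 Å; C2′–C5′ follow an idealized
  backbone layout, mirrored on the reverse strand so the geometric 5′→3′
  test holds on both strands.
- **Protein**: ideal α-helix Cα traces (rise 1.5 Å, radius 2.3 Å,
  100°/residue) with Cβ pseudo-atoms at radius 3.3 Å; three helices
  (10, 10, 12 residues) joined by short arched loops. The recognition helix
  docks along the major-groove rim at 2.8 Å from the groove surface frame;
  the two support helices sit 9 Å further out. These dock parameters were
  chosen geometrically so that the default construction satisfies all three
  detection criteria with ~1 Å margin.
- **Bending**: `bend_angle` kinks the duplex at the anchor basepair step
  and rotates the downstream arm *and* the protein about the kink pivot.
  The complex stays internally consistent and passes detection, but no
  single canonical-region superposition can simultaneously fit the helix of
  a straight-DNA complex, producing ~7 Å helix RMSD — a realistic model of
  DNA-deforming binders that do not share the common frame.
- **Decoys** violate exactly one criterion: candidacy (helix pulled 8 Å
  away), tri-helical (support helices pushed to 26 Å), orientation (a small
  grid search over tilt and extra distance finds a pose whose closest
  window mean stays under ~4.85 Å while one residue exceeds 6.7 Å).
- **Noise**: isotropic Gaussian jitter per atom; `perturb` applies an exact
  rigid motion (improper rotations are refused) plus optional jitter.

### Generator realism limits

The fixtures are Cα/Cβ traces on perfectly regular B-DNA: no side chains,
no sequence-dependent DNA shape, no grooves narrowed by binding, no
crystallographic noise models beyond isotropic jitter, and loops are
schematic arcs. They exercise the geometry of every pipeline stage exactly;
they do not imitate the atom-level texture of crystal structures.

## Numerical choices

- Superposition via scipy `Rotation.align_vectors` (Kabsch with proper
  rotation enforced); degenerate (< 3 points or collinear) inputs raise.
- All tie-breaking is total and documented, so every pipeline stage is
  bit-deterministic for a fixed seed.
- Strict-inequality gates (`<` for candidacy and δ) and inclusive
  orientation (`≤`) follow the criterion definitions.
- Distances use exact Euclidean norms; the contact search uses
  `scipy.spatial.cKDTree` with `query_ball_point` at the exact cutoff
  (boundary pairs at exactly 5 Å are included by both the tree and the
  oracle).

## Limitations

- The UCS residue map covers only the recognition helix (the region the
  alignment actually constrains); other residues have no universal index.
- Redundancy requires full 41-residue windows for a zero distance, so very
  short chains are never merged even if genuinely identical.
- Affinity propagation is not guaranteed to find the optimal partition;
  the preference scan plus the UCS distance bound mitigate but do not
  eliminate this (see the eviction rule above).
- Binding-site placement is ungapped; sites with indels relative to the
  crystal duplex will be placed at their best ungapped register.
- Multi-model (NMR) structures use the first model only.
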