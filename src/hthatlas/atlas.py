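"""Atlas construction: clustering and the unified coordinate system.

Complexes are clustered by affinity propagation on the pairwise
helix-RMSD distance matrix (similarity = negative distance; pairs that fail
to align get a large sentinel distance).  The exemplar of the main cluster
anchors a multiple alignment: every member's pairwise alignment to the
exemplar supplies a rigid transform plus residue/basepair index maps, and
correspondences between any two members are obtained transitively through
the exemplar.  Complexes outside the main cluster (or unalignable to the
exemplar) are retained separately as outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .align import PairwiseAlignment, align_pair
from .config import DEFAULT_CONFIG, Config
from .geometry import RigidTransform
from .model import Complex


@dataclass
class DistanceMatrix:
    """Symmetric pairwise helix-RMSD matrix; unalignable pairs are +inf."""

    values: np.ndarray
    ids: list[str]

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def finite(self, sentinel: float) -> np.ndarray:
        out = self.values.copy()
        out[~np.isfinite(out)] = sentinel
        return out


def pairwise_distance_matrix(complexes: list[Complex],
                             config: Config = DEFAULT_CONFIG
                             ) -> tuple[DistanceMatrix,
                                        dict[tuple[int, int],
                                             PairwiseAlignment]]:
    """Distance (i, j) = final helix RMSD of align_pair(i, j); diagonal 0.

    Also returns the alignments themselves, keyed by (i, j) with i < j, for
    reuse when building the unified coordinate system.
    """
    n = len(complexes)
    if n < 2:
        raise ValueError("need at least 2 complexes")
    values = np.zeros((n, n))
    alignments: dict[tuple[int, int], PairwiseAlignment] = {}
    for i in range(n):
        for j in range(i + 1, n):
            alignment = align_pair(complexes[i], complexes[j], config)
            if alignment is None:
                values[i, j] = values[j, i] = np.inf
            else:
                values[i, j] = values[j, i] = alignment.helix_rmsd
                alignments[(i, j)] = alignment
    return DistanceMatrix(values, [c.structure_id for c in complexes]), \
        alignments


@dataclass
class ClusterResult:
    labels: np.ndarray           # per-complex cluster id
    exemplars: list[int]         # complex index per cluster
    preference: float

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self, cluster: int) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.labels == cluster)]

    def largest_cluster(self) -> int:
        sizes = [len(self.members(k)) for k in range(self.n_clusters)]
        return int(np.argmax(sizes))     # argmax keeps the lowest id on ties


def affinity_propagation(matrix: DistanceMatrix, preference: float,
                         config: Config = DEFAULT_CONFIG) -> ClusterResult:
    """Standard AP message passing on similarities = negated distances.

    Deterministic given preference/damping/iteration limits; raises on
    non-convergence rather than returning a partial result.
    """
    S = -matrix.finite(config.unalignable_distance)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap = AffinityPropagation(
                damping=config.ap_damping, max_iter=config.ap_max_iter,
                convergence_iter=config.ap_convergence_iter,
                affinity="precomputed", preference=preference,
                random_state=0).fit(S)
        except ConvergenceWarning as exc:
            raise RuntimeError(f"affinity propagation did not converge "
                               f"(preference={preference})") from exc
    if len(ap.cluster_centers_indices_) == 0 or np.any(ap.labels_ < 0):
        raise RuntimeError("affinity propagation did not converge "
                           f"(preference={preference})")
    return ClusterResult(ap.labels_.copy(),
                         [int(i) for i in ap.cluster_centers_indices_],
                         preference)


def exemplar_distance_check(matrix: DistanceMatrix,
                            result: ClusterResult) -> float:
    """Largest member-to-exemplar distance within the largest cluster."""
    k = result.largest_cluster()
    exemplar = result.exemplars[k]
    members = result.members(k)
    return float(max(matrix.values[m, exemplar] for m in members))


def tune_preference(matrix: DistanceMatrix,
                    config: Config = DEFAULT_CONFIG
                    ) -> tuple[float, ClusterResult]:
    """Scan a preference grid for the single-large-cluster configuration.

    Grid: the 5%..95% quantiles (step 5) of off-diagonal similarities plus
    their median.  The winning preference maximises the largest-cluster size
    subject to every member of that cluster lying within
    ``cluster_distance_bound`` of its exemplar.  If no preference satisfies
    the bound the best clustering found is returned anyway.
    """
    S = -matrix.finite(config.unalignable_distance)
    off = S[~np.eye(matrix.size, dtype=bool)]
    grid = sorted(set(
        float(np.quantile(off, q / 100.0)) for q in range(5, 100, 5)
    ) | {float(np.median(off))})
    best_valid: tuple[int, float, ClusterResult] | None = None
    best_any: tuple[int, float, ClusterResult] | None = None
    for pref in grid:
        try:
            result = affinity_propagation(matrix, pref, config)
        except RuntimeError:
            continue
        size = len(result.members(result.largest_cluster()))
        entry = (size, pref, result)
        if best_any is None or size > best_any[0]:
            best_any = entry
        if exemplar_distance_check(matrix, result) <= \
                config.cluster_distance_bound:
            if best_valid is None or size > best_valid[0]:
                best_valid = entry
    chosen = best_valid or best_any
    if chosen is None:
        raise RuntimeError("no preference in the grid converged")
    return chosen[1], chosen[2]


@dataclass
class UnifiedCoordinateSystem:
    """Exemplar-anchored multiple alignment of the main cluster.

    Universal indices are the exemplar's own residue/basepair indices.
    ``residue_maps[m]``/``basepair_maps[m]`` map member ``m``'s indices to
    universal ones; ``transforms[m]`` moves member ``m`` onto the exemplar
    frame.  ``outliers`` maps excluded complex indices to reasons.
    """

    complexes: list[Complex]
    exemplar: int
    members: list[int]
    transforms: dict[int, RigidTransform] = field(default_factory=dict)
    residue_maps: dict[int, dict[int, int]] = field(default_factory=dict)
    basepair_maps: dict[int, dict[int, int]] = field(default_factory=dict)
    outliers: dict[int, str] = field(default_factory=dict)

    def universal_position(self, member: int, kind: str,
                           index: int) -> int | None:
        """Exemplar-frame index of a member position, or None if unmapped."""
        if member not in self.members:
            raise KeyError(f"complex {member} is not a UCS member")
        maps = {"residue": self.residue_maps,
                "basepair": self.basepair_maps}[kind]
        return maps[member].get(index)

    def map_between(self, member_a: int, member_b: int, kind: str,
                    index: int) -> int | None:
        """Transitive correspondence member_a -> exemplar -> member_b."""
        uni = self.universal_position(member_a, kind, index)
        if uni is None:
            return None
        maps = {"residue": self.residue_maps,
                "basepair": self.basepair_maps}[kind]
        inverse = {v: k for k, v in maps[member_b].items()}
        return inverse.get(uni)

    def transformed_member(self, member: int) -> Complex:
        """The member complex moved onto the exemplar frame."""
        return self.complexes[member].transformed(self.transforms[member])


def build_unified_coordinates(complexes: list[Complex],
                              cluster: ClusterResult,
                              config: Config = DEFAULT_CONFIG,
                              alignments: dict[tuple[int, int],
                                               PairwiseAlignment] | None = None
                              ) -> UnifiedCoordinateSystem:
    """Anchor every main-cluster member to the exemplar.

    Members of smaller clusters become outliers (kept, with reasons), as do
    main-cluster members that fail to align to the exemplar or whose helix
    RMSD to it exceeds ``cluster_distance_bound`` — the latter guards
    against message-passing getting stuck in a merged configuration on
    small or degenerate distance matrices.
    """
    main = cluster.largest_cluster()
    exemplar = cluster.exemplars[main]
    ucs = UnifiedCoordinateSystem(complexes, exemplar, members=[])
    ex = complexes[exemplar]
    for idx in range(len(complexes)):
        if cluster.labels[idx] != main:
            ucs.outliers[idx] = (f"member of cluster "
                                 f"{int(cluster.labels[idx])}, not the "
                                 "main cluster")
            continue
        if idx == exemplar:
            ucs.members.append(idx)
            ucs.transforms[idx] = RigidTransform.identity()
            ucs.residue_maps[idx] = {i: i for i in range(len(ex.protein))}
            ucs.basepair_maps[idx] = {
                i: i for i in range(ex.duplex.n_basepairs)}
            continue
        alignment = None
        if alignments is not None:
            key = (min(idx, exemplar), max(idx, exemplar))
            stored = alignments.get(key)
            if stored is not None and key[0] == idx:
                alignment = stored
        if alignment is None:
            alignment = align_pair(complexes[idx], ex, config)
        if alignment is None:
            ucs.outliers[idx] = "unalignable to the exemplar"
            continue
        if alignment.helix_rmsd > config.cluster_distance_bound:
            ucs.outliers[idx] = (
                f"helix RMSD to exemplar {alignment.helix_rmsd:.2f} A "
                f"exceeds bound {config.cluster_distance_bound:.2f} A")
            continue
        ucs.members.append(idx)
        ucs.transforms[idx] = alignment.transform
        ucs.residue_maps[idx] = dict(alignment.residue_map)
        ucs.basepair_maps[idx] = dict(alignment.basepair_map)
    return ucs


def build_atlas(complexes: list[Complex], config: Config = DEFAULT_CONFIG
                ) -> tuple[DistanceMatrix, ClusterResult,
                           UnifiedCoordinateSystem]:
    """End-to-end: distances -> tuned AP clustering -> coordinate system."""
    matrix, alignments = pairwise_distance_matrix(complexes, config)
    _, cluster = tune_preference(matrix, config)
    ucs = build_unified_coordinates(complexes, cluster, config, alignments)
    return matrix, cluster, ucs
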