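import numpy as np
import pytest

from hthatlas.atlas import (DistanceMatrix, affinity_propagation,
                            build_atlas, build_unified_coordinates,
                            exemplar_distance_check,
                            pairwise_distance_matrix, tune_preference)
from hthatlas.config import DEFAULT_CONFIG
from hthatlas.detect import detect_hth
from hthatlas.geometry import random_rotation
from hthatlas.model import Complex
from hthatlas.synth import SynthParams, make_hth_complex, perturb


def _copies(base, n, seed=7):
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        moved, _ = perturb(base, random_rotation(rng),
                           rng.uniform(-25.0, 25.0, 3))
        out.append(Complex(f"copy{k}", "A", moved.protein, moved.duplex,
                           resolution=moved.resolution,
                           recognition_helix=moved.recognition_helix,
                           central_residue=moved.central_residue))
    return out


@pytest.fixture(scope="module")
def small_set():
    base, _ = make_hth_complex(SynthParams(seed=1))
    detect_hth(base)
    complexes = _copies(base, 4)
    bent, _ = make_hth_complex(SynthParams(seed=1, bend_angle=60.0))
    detect_hth(bent)
    complexes.append(bent)
    return complexes


def test_distance_matrix_symmetric_zero_diagonal(small_set):
    matrix, alignments = pairwise_distance_matrix(small_set)
    np.testing.assert_allclose(matrix.values, matrix.values.T)
    np.testing.assert_allclose(np.diag(matrix.values), 0.0)
    assert matrix.values[0, 4] > DEFAULT_CONFIG.cluster_distance_bound
    assert set(alignments) == {(i, j) for i in range(5)
                               for j in range(i + 1, 5)}


def test_distance_matrix_requires_two():
    base, _ = make_hth_complex(SynthParams(seed=1))
    with pytest.raises(ValueError):
        pairwise_distance_matrix([base])


def test_unalignable_pairs_get_sentinel(small_set):
    values = np.zeros((2, 2))
    values[0, 1] = values[1, 0] = np.inf
    dm = DistanceMatrix(values, ["a", "b"])
    finite = dm.finite(1e4)
    assert finite[0, 1] == 1e4


def test_affinity_propagation_splits_when_preference_high(small_set):
    matrix, _ = pairwise_distance_matrix(small_set)
    result = affinity_propagation(matrix, preference=0.0)
    assert result.n_clusters == len(small_set)


def test_ucs_evicts_far_members_even_if_ap_merges(small_set):
    """On this degenerate 4+1 matrix AP merges everything; the UCS bound
    must still evict the bent complex."""
    matrix, alignments = pairwise_distance_matrix(small_set)
    _, cluster = tune_preference(matrix)
    ucs = build_unified_coordinates(small_set, cluster,
                                    alignments=alignments)
    assert sorted(ucs.members) == [0, 1, 2, 3]
    assert 4 in ucs.outliers


def test_build_atlas_identifies_outlier_and_exemplar(small_set):
    matrix, cluster, ucs = build_atlas(small_set)
    assert ucs.exemplar in ucs.members
    assert 4 in ucs.outliers
    assert exemplar_distance_check(matrix, cluster) >= 0.0


def test_ucs_maps_and_transforms(small_set):
    _, _, ucs = build_atlas(small_set)
    member = next(m for m in ucs.members if m != ucs.exemplar)
    # zero-noise copies: mapped positions are identities; the residue map
    # covers the recognition helix (26..38 for these fixtures)
    assert ucs.universal_position(member, "residue", 30) == 30
    assert ucs.universal_position(member, "residue", 5) is None
    assert ucs.universal_position(member, "basepair", 3) == 3
    other = next(m for m in ucs.members
                 if m not in (ucs.exemplar, member))
    assert ucs.map_between(member, other, "residue", 30) == 30
    # transformed member coincides with the exemplar structure
    moved = ucs.transformed_member(member)
    ref = ucs.complexes[ucs.exemplar]
    np.testing.assert_allclose(moved.helix_ca_coords(),
                               ref.helix_ca_coords(), atol=1e-6)
    with pytest.raises(KeyError):
        ucs.universal_position(4, "residue", 0)


def test_tune_preference_prefers_valid_clustering():
    base, _ = make_hth_complex(SynthParams(seed=1))
    detect_hth(base)
    complexes = _copies(base, 10)
    bent, _ = make_hth_complex(SynthParams(seed=1, bend_angle=60.0))
    detect_hth(bent)
    complexes.append(bent)
    matrix, _ = pairwise_distance_matrix(complexes)
    pref, cluster = tune_preference(matrix)
    assert exemplar_distance_check(matrix, cluster) <= \
        DEFAULT_CONFIG.cluster_distance_bound
    main = cluster.largest_cluster()
    assert sorted(cluster.members(main)) == list(range(10))
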