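import numpy as np
import pytest

from hthatlas.align import (Orientation, RegionError, align_pair,
                            canonical_matching_regions, closest_basepair,
                            enumerate_candidates, gate_candidates,
                            helix_rmsd_under_mapping)
from hthatlas.detect import detect_hth
from hthatlas.geometry import RigidTransform, random_rotation
from hthatlas.model import Complex, DnaDuplex
from hthatlas.synth import SynthParams, make_hth_complex, perturb


def test_closest_basepair_centred(base_complex, base_truth):
    assert closest_basepair(base_complex) == base_truth.closest_basepair == 10


def test_regions_all_contain_anchor(base_complex):
    n = closest_basepair(base_complex)
    regions = canonical_matching_regions(base_complex)
    assert [r.start_bp for r in regions] == list(range(n - 4, n + 1))
    for r in regions:
        assert r.start_bp <= n <= r.start_bp + r.span - 1


def _truncate_duplex(cplx, n_keep):
    from hthatlas.model import Nucleotide
    duplex = cplx.duplex
    L = duplex.n_basepairs
    fwd = [Nucleotide(k, nt.base, nt.atoms)
           for k, nt in enumerate(duplex.forward[:n_keep])]
    rev = [Nucleotide(k, nt.base, nt.atoms)
           for k, nt in enumerate(duplex.reverse[L - n_keep:])]
    short = DnaDuplex(fwd, rev, [(i, n_keep - 1 - i) for i in range(n_keep)])
    short.validate()
    return Complex(cplx.structure_id, cplx.chain_id, cplx.protein, short,
                   resolution=cplx.resolution,
                   recognition_helix=cplx.recognition_helix,
                   central_residue=cplx.central_residue)


def test_region_error_near_duplex_end(base_complex):
    # anchor bp 10: truncating the duplex to 13 bp leaves only 2 bp 3' of it
    short = _truncate_duplex(base_complex, 13)
    with pytest.raises(RegionError):
        canonical_matching_regions(short)
    assert align_pair(short, base_complex) is None


def test_self_alignment_is_identity(base_complex):
    result = align_pair(base_complex, base_complex)
    assert result.dna_rmsd == pytest.approx(0.0, abs=1e-9)
    assert result.helix_rmsd == pytest.approx(0.0, abs=1e-9)
    assert result.orientation is Orientation.FORWARD
    assert result.region_a_start == result.region_b_start
    np.testing.assert_allclose(result.transform.rotation, np.eye(3),
                               atol=1e-9)
    # identity maps
    assert all(i == j for i, j in result.residue_map)
    assert all(i == j for i, j in result.basepair_map)


def test_strand_swapped_copy_aligns_flipped(base_complex):
    duplex = base_complex.duplex
    L = duplex.n_basepairs
    swapped_duplex = DnaDuplex(list(duplex.reverse), list(duplex.forward),
                               [(i, L - 1 - i) for i in range(L)])
    swapped = Complex("SWAP", "A", base_complex.protein, swapped_duplex,
                      resolution=base_complex.resolution,
                      recognition_helix=base_complex.recognition_helix,
                      central_residue=base_complex.central_residue)
    result = align_pair(base_complex, swapped)
    assert result.orientation is Orientation.FLIPPED
    assert result.dna_rmsd == pytest.approx(0.0, abs=1e-9)
    assert result.helix_rmsd == pytest.approx(0.0, abs=1e-9)
    # basepair i of the original corresponds to basepair L-1-i of the swap
    assert all(j == L - 1 - i for i, j in result.basepair_map)


def test_gate_discards_distorted_dna(base_complex):
    noisy, _ = make_hth_complex(SynthParams(seed=1, noise_sigma=3.0))
    assert align_pair(base_complex, noisy) is None


def test_gate_candidates_strict():
    class Stub:
        def __init__(self, rmsd):
            self.dna_rmsd = rmsd
    kept = gate_candidates([Stub(1.9), Stub(2.0), Stub(2.1)], delta=2.0)
    assert [c.dna_rmsd for c in kept] == [1.9]


def test_candidate_count_and_order(base_complex):
    other, _ = make_hth_complex(SynthParams(seed=2))
    assert detect_hth(other).passed
    candidates = enumerate_candidates(base_complex, other)
    assert len(candidates) == 50
    # enumeration order: region_a outer, region_b middle, orientation inner
    assert candidates[0].orientation is Orientation.FORWARD
    assert candidates[1].orientation is Orientation.FLIPPED
    assert candidates[0].region_a.start_bp == candidates[9].region_a.start_bp


def test_helix_mapping_requires_min_overlap():
    short = np.zeros((5, 3))
    with pytest.raises(ValueError):
        helix_rmsd_under_mapping(short, short, RigidTransform.identity())


def test_helix_mapping_detects_flip(rng):
    helix = rng.normal(0.0, 4.0, (10, 3))
    rmsd, mapping, shift, flipped = helix_rmsd_under_mapping(
        helix, helix[::-1].copy(), RigidTransform.identity())
    assert flipped
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    # a[i] coincides with b[9 - i]: the map reports b's original indices
    assert mapping == [(i, 9 - i) for i in range(10)]


def test_alignment_is_symmetric_in_rmsd(base_complex):
    rng = np.random.default_rng(3)
    moved, _ = perturb(base_complex, random_rotation(rng),
                       rng.uniform(-10, 10, 3))
    ab = align_pair(base_complex, moved)
    ba = align_pair(moved, base_complex)
    assert ab.helix_rmsd == pytest.approx(ba.helix_rmsd, abs=1e-9)
    assert ab.dna_rmsd == pytest.approx(ba.dna_rmsd, abs=1e-9)
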