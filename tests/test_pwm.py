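import numpy as np
import pytest

from hthatlas.pwm import (BindingSite, Pwm, align_sites, build_pwm,
                          count_matrix, dedupe_sites, exact_block,
                          map_pwm_to_structure, read_sites_tsv,
                          sample_sites_from_pwm)


def test_binding_site_validates_sequence():
    with pytest.raises(ValueError):
        BindingSite("x", "ACGU")
    with pytest.raises(ValueError):
        BindingSite("x", "")
    assert BindingSite("x", "acgt").sequence == "ACGT"


def test_dedupe_collapses_same_experiment():
    sites = [BindingSite("x", "ACGT", provenance_id="E1"),
             BindingSite("x", "ACGT", provenance_id="E1"),
             BindingSite("x", "ACGT", provenance_id="E2"),
             BindingSite("x", "ACGT"),
             BindingSite("x", "ACGT")]
    kept = dedupe_sites(sites)
    # one per provenance id plus both provenance-free records
    assert len(kept) == 4


def test_align_sites_places_at_best_offset():
    block = align_sites([BindingSite("x", "GGG")], "AAGGGA")
    placement = block.placements[0]
    assert (placement.offset, placement.strand) == (2, "+")
    assert placement.matches == 3


def test_align_sites_uses_reverse_strand():
    # CCC does not occur forward but its reverse complement GGG does
    block = align_sites([BindingSite("x", "CCC")], "AAGGGA")
    placement = block.placements[0]
    assert placement.strand == "-"
    assert placement.placed == "GGG"
    assert placement.offset == 2


def test_align_sites_trims_overlong(caplog):
    block = align_sites([BindingSite("x", "ACGTACGT")], "ACGT")
    assert len(block.placements[0].placed) == 4


def test_count_and_smoothing_exact_values():
    sites = [BindingSite("x", "AA"), BindingSite("x", "AC"),
             BindingSite("x", "AG")]
    block = exact_block(sites, "TT")
    counts = count_matrix(block)
    np.testing.assert_array_equal(counts[0], [3, 0, 0, 0])
    np.testing.assert_array_equal(counts[1], [1, 1, 1, 0])
    pwm = build_pwm(block, alpha=1.0)
    np.testing.assert_allclose(pwm.probs[0], [4 / 7, 1 / 7, 1 / 7, 1 / 7])
    np.testing.assert_allclose(pwm.probs[1], [2 / 7, 2 / 7, 2 / 7, 1 / 7])
    assert list(pwm.support) == [3, 3]


def test_empty_column_is_uniform():
    block = align_sites([BindingSite("x", "AC")], "ACGT")
    pwm = build_pwm(block)
    np.testing.assert_allclose(pwm.probs[2], 0.25)
    np.testing.assert_allclose(pwm.probs[3], 0.25)
    assert pwm.support[2] == 0


def test_pwm_text_round_trip():
    probs = np.array([[0.4, 0.3, 0.2, 0.1], [0.25, 0.25, 0.25, 0.25]])
    pwm = Pwm(probs, np.array([5, 0]))
    back = Pwm.from_text(pwm.to_text())
    np.testing.assert_allclose(back.probs, probs, atol=1e-6)
    assert pwm.consensus() == "AA"


def test_pwm_rejects_bad_shape():
    with pytest.raises(ValueError):
        Pwm(np.ones((3, 3)), np.zeros(3))
    with pytest.raises(ValueError):
        Pwm(np.full((2, 4), 0.3), np.zeros(2))


def test_map_to_structure_forward_and_reverse(base_complex):
    probs = np.tile(np.array([[0.7, 0.1, 0.1, 0.1]]), (4, 1))
    probs[1] = [0.1, 0.7, 0.1, 0.1]
    pwm = Pwm(probs, np.zeros(4, dtype=int))
    fwd = map_pwm_to_structure(pwm, base_complex, offset=3)
    np.testing.assert_allclose(fwd.distribution(4), probs[1])
    np.testing.assert_allclose(fwd.distribution(10), 0.25)   # unmapped
    rev = map_pwm_to_structure(pwm, base_complex, offset=3, orientation="-")
    # column 1 sits on basepair offset + L - 1 - 1 = 5, complement-swapped
    np.testing.assert_allclose(rev.distribution(5), probs[1][::-1])
    with pytest.raises(IndexError):
        fwd.distribution(99)


def test_map_clips_out_of_range(base_complex):
    pwm = Pwm(np.full((6, 4), 0.25), np.zeros(6, dtype=int))
    mapped = map_pwm_to_structure(pwm, base_complex, offset=17)
    assert [bp for _, bp in mapped.entries] == [17, 18, 19]


def test_sampling_is_deterministic():
    pwm = Pwm(np.array([[0.97, 0.01, 0.01, 0.01]] * 3), np.zeros(3))
    a = sample_sites_from_pwm(pwm, 50, seed=4)
    b = sample_sites_from_pwm(pwm, 50, seed=4)
    assert a == b
    assert sum(s == "AAA" for s in a) > 40
    with pytest.raises(ValueError):
        sample_sites_from_pwm(pwm, 0)


def test_read_sites_tsv(tmp_path):
    path = tmp_path / "sites.tsv"
    path.write_text("complex_id\tsequence\tsource\texperiment_type\t"
                    "quality\tprovenance_id\n"
                    "c1\tACGT\tdbA\tSELEX\thigh\tE1\n"
                    "c1\tAAAA\tdbB\t\t\t\n")
    sites = read_sites_tsv(path)
    assert len(sites) == 2
    assert sites[0].provenance_id == "E1"
    assert sites[1].provenance_id is None
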