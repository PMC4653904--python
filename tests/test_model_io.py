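import numpy as np
import pytest

from hthatlas.model import (Atom, Complex, DnaDuplex, Nucleotide, Pathology,
                            Residue, reverse_complement)
from hthatlas.pdbio import (RawStructure, StandardizationError, read_complex,
                            read_structure, screen_pathologies,
                            standardize_duplex, write_structure)
from hthatlas.synth import SynthParams, make_hth_complex, make_ideal_bdna


def test_reverse_complement():
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AACG") == "CGTT"


def test_atom_rejects_non_finite():
    with pytest.raises(ValueError):
        Atom("CA", "C", np.array([np.nan, 0.0, 0.0]))


def test_duplex_validate_rejects_non_complementary():
    duplex = make_ideal_bdna("ACGTACGTAC")
    bad_rev = [Nucleotide(nt.seq_index, "A", nt.atoms)
               for nt in duplex.reverse]
    broken = DnaDuplex(duplex.forward, bad_rev, list(duplex.pairs))
    with pytest.raises(ValueError):
        broken.validate()


def test_pdb_round_trip_preserves_complex(base_complex):
    text = write_structure(base_complex)
    assert all(len(line) <= 80 for line in text.splitlines())
    back = read_complex(text)
    assert back.resolution == pytest.approx(base_complex.resolution, abs=0.01)
    assert len(back.protein) == len(base_complex.protein)
    assert back.duplex.forward_sequence() == \
        base_complex.duplex.forward_sequence()
    np.testing.assert_allclose(back.protein[0].ca.position,
                               base_complex.protein[0].ca.position, atol=1e-3)
    # idempotent: writing the re-read complex gives identical text
    assert write_structure(back).splitlines()[1:] == text.splitlines()[1:]


def test_read_structure_classifies_chains(base_complex):
    raw = read_structure(write_structure(base_complex))
    assert set(raw.protein_chains) == {"A"}
    assert set(raw.nucleic_chains) == {"B", "C"}
    report = screen_pathologies(raw)
    assert report.admissible


def test_screen_single_stranded():
    raw = RawStructure("X", None)
    raw.nucleic_chains["B"] = []
    report = screen_pathologies(raw)
    assert Pathology.SINGLE_STRANDED_DNA in report.flags
    assert not report.admissible


def test_screen_missing_backbone(base_complex):
    raw = read_structure(write_structure(base_complex))
    nt = raw.nucleic_chains["B"][0]
    raw.nucleic_chains["B"][0] = Nucleotide(
        nt.seq_index, nt.base, [a for a in nt.atoms if a.name != "C3'"])
    report = screen_pathologies(raw)
    assert Pathology.MISSING_BACKBONE_ATOMS in report.flags


def test_screen_nonstandard_residue(base_complex):
    raw = read_structure(write_structure(base_complex))
    res = raw.protein_chains["A"][0]
    raw.protein_chains["A"][0] = Residue(res.seq_index, "X", res.atoms)
    report = screen_pathologies(raw)
    assert Pathology.NONSTANDARD_RESIDUES in report.flags


def test_standardize_reorders_reversed_strand():
    duplex = make_ideal_bdna("ACGTACGTACGT")
    scrambled = [list(reversed(duplex.forward)), list(duplex.reverse)]
    fixed = standardize_duplex(scrambled)
    assert fixed.forward_sequence() == duplex.forward_sequence()
    assert fixed.n_basepairs == duplex.n_basepairs


def test_standardize_handles_strand_order_swap():
    duplex = make_ideal_bdna("ACGTACGTACGT")
    swapped = standardize_duplex([list(duplex.reverse),
                                  list(duplex.forward)])
    swapped.validate()
    assert swapped.n_basepairs == duplex.n_basepairs


def test_standardize_removes_terminal_overhang():
    duplex = make_ideal_bdna("ACGTACGTACGT")
    # drop the reverse-strand mate of the last forward nucleotide
    trimmed_rev = list(duplex.reverse)[1:]
    fixed = standardize_duplex([list(duplex.forward), trimmed_rev])
    assert fixed.n_basepairs == duplex.n_basepairs - 1
    assert fixed.forward_sequence() == duplex.forward_sequence()[:-1]


def test_standardize_rejects_interior_gap():
    duplex = make_ideal_bdna("ACGTACGTACGT")
    rev = list(duplex.reverse)
    del rev[5]
    with pytest.raises(StandardizationError):
        standardize_duplex([list(duplex.forward), rev])


def test_standardize_rejects_single_strand():
    duplex = make_ideal_bdna("ACGTACGTACGT")
    with pytest.raises(StandardizationError):
        standardize_duplex([list(duplex.forward)])


def test_write_refuses_empty_protein(base_complex):
    empty = Complex("X", "A", [], base_complex.duplex)
    with pytest.raises(ValueError):
        write_structure(empty)


def test_complex_annotation_validation(base_complex):
    with pytest.raises(ValueError):
        Complex("X", "A", base_complex.protein, base_complex.duplex,
                recognition_helix=(0, 10_000))
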