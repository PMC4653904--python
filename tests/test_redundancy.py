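import numpy as np
import pytest

from hthatlas.detect import detect_hth
from hthatlas.model import GAP, Complex
from hthatlas.redundancy import (CENTER, WINDOW, RecognitionSequence,
                                 build_redundancy_graph,
                                 extract_recognition_sequence,
                                 select_representatives, shifted_distance)
from hthatlas.synth import SynthParams, make_hth_complex

AAS = "ACDEFGHIKLMNPQRSTVWY"
# long recognition helix so the 41-residue window has no GAP padding
LONG = SynthParams(seed=42, helix_lengths=(30, 30, 45))


def _seq(symbols):
    return RecognitionSequence(tuple(symbols))


def _padded(core: str, left: int) -> list[str]:
    symbols = [GAP] * WINDOW
    for k, ch in enumerate(core):
        symbols[left + k] = ch
    return symbols


def _random_window(rng) -> str:
    return "".join(AAS[rng.integers(len(AAS))] for _ in range(WINDOW))


def test_window_constants():
    assert WINDOW == 41
    assert CENTER == 20


def test_recognition_sequence_rejects_gap_centre():
    symbols = [GAP] * WINDOW
    with pytest.raises(ValueError):
        RecognitionSequence(tuple(symbols))
    with pytest.raises(ValueError):
        RecognitionSequence(("A",) * 40)


def test_identical_full_windows_distance_zero():
    a = _seq(_random_window(np.random.default_rng(0)))
    assert shifted_distance(a, a) == (0, 0)


def test_shift_is_recovered():
    core = _random_window(np.random.default_rng(1))
    a = _seq(core)
    b = _seq(core[3:] + "AAA")       # b[i] == a[i + 3]
    mism, shift = shifted_distance(a, b)
    assert mism == 0
    assert shift == 3


def test_gap_columns_always_count_as_mismatch():
    # identical truncated windows: the GAP columns in the overlap keep the
    # distance positive, so truncation never creates spurious redundancy
    a = _seq(_padded("MKRLAQHGWEVMKRLAQHGWE", 10))
    mism, _ = shifted_distance(a, a)
    assert mism > 0


def test_truncation_cost_shrinks_with_shift():
    # shifting can push GAP columns out of the overlap but each remaining
    # one is still a mismatch
    a = _seq(_padded("MKRLAQHGWEVMKRLAQHGWE", 10))
    mism, shift = shifted_distance(a, a)
    overlap = WINDOW - abs(shift)
    assert mism <= 20            # 20 GAP symbols in the full window
    assert overlap >= WINDOW - 15


def test_extract_recognition_sequence_pads_near_terminus():
    cplx, _ = make_hth_complex(SynthParams(seed=4))
    detect_hth(cplx)
    seq = extract_recognition_sequence(cplx)
    assert len(seq.symbols) == WINDOW
    # default chain has 38 residues, central ~32: right side is padded
    assert seq.symbols[-1] == GAP
    assert seq.symbols[CENTER] == cplx.protein[cplx.central_residue].aa_code


def _identical_complexes(n):
    out = []
    for k in range(n):
        cplx, _ = make_hth_complex(LONG, structure_id=f"S{k}")
        assert detect_hth(cplx).passed
        out.append(cplx)
    return out


def test_redundancy_graph_and_representatives():
    complexes = _identical_complexes(3)
    distinct, _ = make_hth_complex(
        SynthParams(seed=43, helix_lengths=(30, 30, 45)), structure_id="T0")
    assert detect_hth(distinct).passed
    complexes.append(distinct)
    graph = build_redundancy_graph(complexes)
    assert graph.has_edge(0, 1) and graph.has_edge(1, 2)
    assert graph.degree[3] == 0
    reps = select_representatives(graph, complexes)
    assert len(reps) == 2
    assert 3 in reps


def test_representative_tie_breaks_on_resolution():
    complexes = _identical_complexes(3)
    # complete component, equal degrees: best (lowest) resolution wins
    complexes[1] = Complex(complexes[1].structure_id, "A",
                           complexes[1].protein, complexes[1].duplex,
                           resolution=1.2,
                           recognition_helix=complexes[1].recognition_helix,
                           central_residue=complexes[1].central_residue)
    graph = build_redundancy_graph(complexes)
    reps = select_representatives(graph, complexes)
    assert reps == [1]
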