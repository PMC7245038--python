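"""Chimera decomposition: segmentation, tiling, classification."""

import numpy as np
import pytest

from _oracles import best_tiling_score
from conftest import random_seq
from sinekit.chimera import (
    Segment,
    classify_family,
    flag_bipartite_line_tail,
    resolve_tiling,
    segment_against_library,
)
from sinekit.errors import InputError
from sinekit.synthetic import mutate_sequence


def _seg(cons_start, cons_end, score, role="body", donor="d", dstart=1, dend=None):
    return Segment(
        donor, dstart, dend or (cons_end - cons_start + 1), cons_start, cons_end,
        "+", 90.0, score, role,
    )


def test_whole_donor_single_segment():
    rng = np.random.default_rng(71)
    donor = random_seq(rng, 200)
    segs = segment_against_library(donor, {"d": donor}, {"d": "7SL"})
    top = segs[0]
    assert (top.cons_start, top.cons_end) == (1, 200)
    assert (top.donor_start, top.donor_end) == (1, 200)
    assert top.identity == 100.0 and top.role == "head7SL"


def test_two_donor_chimera_breakpoints():
    rng = np.random.default_rng(72)
    da, db = random_seq(rng, 150), random_seq(rng, 120)
    cons = da[:100] + db[:80]
    segs = segment_against_library(cons, {"A": da, "B": db}, {"A": "7SL", "B": "LINE"})
    by_donor = {s.donor: s for s in segs}
    assert by_donor["A"].cons_end == 100
    assert by_donor["B"].cons_start == 101
    assert (by_donor["B"].donor_start, by_donor["B"].donor_end) == (1, 80)


def test_chimera_breakpoints_tolerant_to_substitutions():
    rng = np.random.default_rng(73)
    da, db = random_seq(rng, 150), random_seq(rng, 120)
    cons = mutate_sequence(da[:100] + db[:80], 10 / 180, rng)[0]
    segs = segment_against_library(cons, {"A": da, "B": db}, {"A": "7SL", "B": "LINE"})
    by_donor = {s.donor: s for s in segs}
    assert abs(by_donor["A"].cons_end - 100) <= 5
    assert abs(by_donor["B"].cons_start - 101) <= 5


def test_tiling_keeps_disjoint_and_drops_weaker_overlap():
    a, b = _seg(1, 100, 100), _seg(120, 200, 80)
    chosen = [s for s in resolve_tiling([a, b], min_gap_report=0) if s.role != "unassigned"]
    assert chosen == [a, b]
    c, d = _seg(1, 100, 100), _seg(5, 95, 60)
    chosen = [s for s in resolve_tiling([c, d], min_gap_report=0) if s.role != "unassigned"]
    assert chosen == [c]


def test_tiling_reports_unassigned_gaps():
    tiling = resolve_tiling([_seg(1, 80, 80), _seg(200, 280, 80)], consensus_len=320)
    gaps = [s for s in tiling if s.role == "unassigned"]
    assert [(g.cons_start, g.cons_end) for g in gaps] == [(81, 199), (281, 320)]


def test_tiling_equals_exhaustive_enumeration():
    rng = np.random.default_rng(74)
    for _ in range(25):
        k = int(rng.integers(2, 11))
        segs = [
            _seg(s := int(rng.integers(1, 300)), s + int(rng.integers(25, 100)),
                 int(rng.integers(10, 200)))
            for _ in range(k)
        ]
        got = sum(s.score for s in resolve_tiling(segs, min_gap_report=0))
        want = best_tiling_score([(s.cons_start, s.cons_end, s.score) for s in segs])
        assert got == want


def test_classification_rules():
    head7sl = _seg(1, 96, 96, "head7SL")
    head_trna = _seg(1, 70, 70, "headtRNA")
    body = _seg(100, 160, 60, "body")
    tail = _seg(170, 280, 100, "tailLINE")
    assert classify_family([head7sl, body, tail]).sine_class == "SINE1"
    assert classify_family([head_trna, tail]).sine_class == "SINE2"
    assert classify_family([_seg(1, 90, 90, "head5S"), tail]).sine_class == "SINE3"
    assert classify_family([body, tail]).sine_class == "unclassified"
    arch = classify_family([head7sl, body, tail])
    assert arch.roles == "head7SL-body-tailLINE"


def test_single_line_segment_is_non_sine():
    line = _seg(1, 290, 290, "tailLINE")
    assert classify_family([line], consensus_len=300).sine_class == "non-SINE"
    # same segment covering less than 90% stays unclassified
    short = _seg(1, 200, 200, "tailLINE")
    assert classify_family([short], consensus_len=300).sine_class == "unclassified"


def test_classify_empty_tiling_rejected():
    with pytest.raises(InputError):
        classify_family([_seg(1, 40, 0, "unassigned")])


def test_bipartite_line_tail_flag():
    donors = {"RTE": "A" * 3000}
    five = _seg(150, 216, 67, "tailLINE", "RTE", 60, 126)
    three = _seg(230, 278, 49, "tailLINE", "RTE", 2952, 3000)
    assert flag_bipartite_line_tail([five, three], donors) is True
    assert flag_bipartite_line_tail([five], donors) is False
    # two 5' segments without the 3' terminus do not qualify
    other = _seg(230, 278, 49, "tailLINE", "RTE", 300, 360)
    assert flag_bipartite_line_tail([five, other], donors) is False


def test_planted_five_part_chimera_recovered(donor_library, family_spec):
    """Segmentation + tiling of the default chimera recovers the planted
    role order among decoy donors."""
    donors, roles = donor_library
    cands = segment_against_library(family_spec.consensus, donors, roles)
    tiling = resolve_tiling(cands, consensus_len=len(family_spec.consensus))
    got_roles = [s.role for s in tiling if s.role != "unassigned"]
    assert got_roles == ["head7SL", "head7SL", "body", "tailLINE", "tailLINE"]
    arch = classify_family(tiling, "fam", donors, len(family_spec.consensus))
    assert arch.sine_class == "SINE1"
    assert arch.bipartite_line_tail is True
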