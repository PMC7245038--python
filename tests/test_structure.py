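"""Secondary-structure comparison and pol III promoter-box search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import pair_category
from conftest import random_seq
from sinekit.align import global_align
from sinekit.errors import InputError
from sinekit.structure import (
    HAGFISH_7SL_BOX_A,
    HAGFISH_7SL_BOX_B,
    HUMAN_7SL_BOX_A,
    HUMAN_7SL_BOX_B,
    PairTable,
    box_hamming,
    classify_pair_changes,
    find_promoter_boxes,
    map_pairs_through_alignment,
    parse_dotbracket,
    render_dotbracket,
)


def test_parse_dotbracket_basic():
    assert parse_dotbracket("((..))").pairs == [(1, 6), (2, 5)]
    assert parse_dotbracket("....").pairs == []


@pytest.mark.parametrize("bad", ["(()", "())", "(.[.)", "abc"])
def test_parse_dotbracket_rejects_invalid(bad):
    with pytest.raises(InputError):
        parse_dotbracket(bad)


@st.composite
def nested_structures(draw, max_len=40):
    """Random pseudoknot-free dot-bracket strings."""
    n = draw(st.integers(min_value=0, max_value=max_len))
    out = []
    depth = 0
    for _ in range(n):
        move = draw(st.sampled_from("(().." if depth else "(.."))
        if move == "(":
            depth += 1
        elif move == ")":
            depth -= 1
        out.append(move)
    out.extend(")" * depth)
    return "".join(out)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(nested_structures())
def test_dotbracket_round_trip(s):
    assert render_dotbracket(parse_dotbracket(s)) == s


def test_pair_table_rejects_shared_position():
    with pytest.raises(InputError):
        PairTable(10, [(1, 5), (5, 8)])


def test_map_pairs_identity_alignment():
    rng = np.random.default_rng(91)
    ref = random_seq(rng, 30)
    aln = global_align(ref, ref)
    mapped = map_pairs_through_alignment(PairTable(30, [(2, 29), (5, 20)]), aln)
    assert [(q, f) for _, q, f in mapped] == [((2, 29), "mapped"), ((5, 20), "mapped")]


def test_map_pairs_deletion_gives_deleted_fate():
    ref = "AAAACCCCGGGGTTTTAAAA"
    qry = ref[:4] + ref[10:]  # positions 5..10 deleted
    aln = global_align(ref, qry)
    mapped = map_pairs_through_alignment(PairTable(20, [(6, 18), (2, 19)]), aln)
    fates = {p: f for p, _, f in mapped}
    assert fates[(6, 18)] == "deleted"
    assert fates[(2, 19)] == "mapped"


def test_map_pairs_shifted_by_insertion():
    """An insertion upstream of j shifts the query coordinate by its length."""
    ref = "AAAACCCCGGGGTTTTAAAA"
    qry = ref[:10] + "GGG" + ref[10:]
    aln = global_align(ref, qry)
    mapped = map_pairs_through_alignment(PairTable(20, [(2, 15)]), aln)
    (_, (qi, qj), fate) = mapped[0]
    assert fate == "mapped" and qi == 2 and qj == 18


def test_map_pairs_outside_span_rejected():
    aln = global_align("ACGTACGT", "ACGTACGT")
    with pytest.raises(InputError):
        map_pairs_through_alignment(PairTable(12, [(2, 11)]), aln)


@pytest.mark.parametrize(
    "ref,qry,category",
    [
        ("GC", "GC", "conserved"),
        ("GC", "AU", "compensatory"),
        ("GC", "GA", "half-broken"),
        ("GC", "GU", "wobble-preserving"),
        ("AU", "GU", "wobble-preserving"),  # single change to wobble
        ("CG", "UG", "wobble-preserving"),
        ("AU", "CC", "broken"),
        ("UA", "CG", "compensatory"),
    ],
)
def test_pair_change_categories(ref, qry, category):
    records, _ = classify_pair_changes(ref, qry, [((1, 2), (1, 2), "mapped")])
    assert records[0].category == category


def test_pair_change_full_enumeration_matches_truth_table():
    """All 256 reference/query base combinations agree with the literal
    truth table and yield exactly one category each."""
    for combo in itertools.product("ACGU", repeat=4):
        ref = combo[0] + combo[1]
        qry = combo[2] + combo[3]
        records, summary = classify_pair_changes(ref, qry, [((1, 2), (1, 2), "mapped")])
        assert records[0].category == pair_category(ref, qry)
        assert sum(summary.values()) == 1


def test_pair_change_symmetry_of_conserved_and_compensatory():
    for ref, qry in [("GC", "GC"), ("GC", "AU"), ("AU", "CG")]:
        fwd, _ = classify_pair_changes(ref, qry, [((1, 2), (1, 2), "mapped")])
        rev, _ = classify_pair_changes(qry, ref, [((1, 2), (1, 2), "mapped")])
        assert fwd[0].category == rev[0].category


def test_pair_change_counts_partition_random_fixtures():
    """Summary counts always sum to the mapped non-deleted pairs."""
    rng = np.random.default_rng(92)
    for _ in range(20):
        n = int(rng.integers(30, 80))
        ref = random_seq(rng, n)
        qry_chars = list(ref)
        for p in rng.choice(n, size=n // 8, replace=False):
            qry_chars[p] = "ACGT"[("ACGT".index(qry_chars[p]) + 1) % 4]
        qry = "".join(qry_chars)
        pairs = []
        used = set()
        for _ in range(n // 4):
            i, j = sorted(int(x) + 1 for x in rng.choice(n, size=2, replace=False))
            if i != j and i not in used and j not in used:
                pairs.append((i, j))
                used.update((i, j))
        aln = global_align(ref, qry)
        mapped = map_pairs_through_alignment(PairTable(n, pairs), aln)
        _, summary = classify_pair_changes(ref, qry, mapped)
        n_deleted = sum(1 for _, _, f in mapped if f == "deleted")
        assert sum(v for k, v in summary.items() if k != "deleted") == len(mapped) - n_deleted


def test_box_hamming_paper_motifs():
    assert box_hamming(HAGFISH_7SL_BOX_A, HUMAN_7SL_BOX_A) == 1
    assert box_hamming(HUMAN_7SL_BOX_B, HAGFISH_7SL_BOX_B) == 2
    assert box_hamming("ACGT", "ACGT") == 0
    with pytest.raises(InputError):
        box_hamming("ACG", "ACGT")


def test_find_promoter_boxes_at_expected_positions():
    rng = np.random.default_rng(93)
    head = random_seq(rng, 100)
    head = head[:5] + HAGFISH_7SL_BOX_A + head[15:75] + HAGFISH_7SL_BOX_B + head[86:]
    boxes = find_promoter_boxes(head)
    assert boxes.box_a == (6, 15) and boxes.box_a_distance == 1
    assert boxes.box_b == (76, 86) and boxes.box_b_distance == 2
    assert boxes.box_a_seq == HAGFISH_7SL_BOX_A
    exact = find_promoter_boxes(
        head[:5] + HUMAN_7SL_BOX_A + head[15:], window=5
    )
    assert exact.box_a_distance == 0


def test_find_promoter_boxes_offset_recovered():
    rng = np.random.default_rng(94)
    head = random_seq(rng, 110)
    head = head[:9] + HUMAN_7SL_BOX_A + head[19:80] + HUMAN_7SL_BOX_B + head[91:]
    boxes = find_promoter_boxes(head)
    assert boxes.box_a == (10, 19) and boxes.box_a_distance == 0
    assert boxes.box_b == (81, 91) and boxes.box_b_distance == 0


def test_find_promoter_boxes_short_head_rejected():
    with pytest.raises(InputError):
        find_promoter_boxes("ACGT" * 5)
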