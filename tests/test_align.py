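"""Pairwise and multiple alignment: identities, scores, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import best_global_score
from sinekit.align import global_align, local_align, progressive_msa
from sinekit.errors import InputError
from sinekit.util import revcomp

from conftest import random_seq


@pytest.mark.parametrize(
    "a,b,identity",
    [("ACGT", "ACGT", 100.0), ("ACGT", "ACGA", 75.0), ("AAAA", "AAAA", 100.0)],
)
def test_global_identity_simple(a, b, identity):
    aln = global_align(a, b)
    assert aln.identity == identity
    assert aln.q_span == len(a) and aln.t_span == len(b)


def test_empty_sequence_rejected():
    with pytest.raises(InputError):
        global_align("", "ACGT")
    with pytest.raises(InputError):
        local_align("ACGT", "")


def test_global_identity_matches_planted_divergence():
    """A copy diverged by substitution only aligns gap-free at 100(1-d)."""
    rng = np.random.default_rng(5)
    a = random_seq(rng, 400)
    pos = rng.choice(400, size=20, replace=False)
    chars = list(a)
    for p in pos:
        chars[p] = "ACGT"[("ACGT".index(chars[p]) + 1) % 4]
    b = "".join(chars)
    aln = global_align(a, b)
    assert aln.identity == pytest.approx(100 * 380 / 400, abs=1e-6)
    assert "I" not in aln.ops and "D" not in aln.ops


def test_global_mismatch_count_agrees_with_edlib():
    """Independent cross-check of the alignment distance on diverged copies."""
    edlib = pytest.importorskip("edlib")
    rng = np.random.default_rng(6)
    for _ in range(10):
        a = random_seq(rng, 300)
        chars = list(a)
        for p in rng.choice(300, size=12, replace=False):
            chars[p] = "ACGT"[("ACGT".index(chars[p]) + rng.integers(1, 4)) % 4]
        b = "".join(chars)
        aln = global_align(a, b)
        my_dist = aln.expanded_ops().count("X")
        assert my_dist == edlib.align(a, b, task="distance")["editDistance"]


def test_global_score_equals_exhaustive_enumeration_oracle():
    """On tiny sequences the DP equals brute-force alignment enumeration."""
    rng = np.random.default_rng(7)
    for _ in range(40):
        a = random_seq(rng, int(rng.integers(1, 9)))
        b = random_seq(rng, int(rng.integers(1, 9)))
        assert global_align(a, b).score == best_global_score(a, b)


def test_local_self_alignment_full_span():
    rng = np.random.default_rng(8)
    a = random_seq(rng, 120)
    hits = local_align(a, a)
    top = hits[0]
    assert (top.q_start, top.q_end, top.t_start, top.t_end) == (1, 120, 1, 120)
    assert top.identity == 100.0 and top.strand == "+"


def test_local_reverse_complement_hit_on_minus_strand():
    rng = np.random.default_rng(9)
    a = random_seq(rng, 150)
    hits = local_align(a, revcomp(a))
    top = hits[0]
    assert top.strand == "-"
    assert (top.q_start, top.q_end) == (1, 150)
    assert top.identity == 100.0


def test_local_identity_with_known_substitutions():
    """300-mer with 15 interior substitutions: identity 95 +- rounding."""
    rng = np.random.default_rng(10)
    a = random_seq(rng, 300)
    pos = rng.choice(np.arange(5, 295), size=15, replace=False)
    chars = list(a)
    for p in pos:
        chars[p] = "ACGT"[("ACGT".index(chars[p]) + 2) % 4]
    b = "".join(chars)
    top = local_align(a, b)[0]
    assert top.identity == pytest.approx(95.0, abs=0.5)


def test_local_score_symmetry():
    rng = np.random.default_rng(11)
    a, b = random_seq(rng, 200), random_seq(rng, 150)
    b = b[:50] + a[40:120] + b[50:]  # shared 80-mer
    ha = local_align(a, b)[0]
    hb = local_align(b, a)[0]
    assert ha.score == hb.score
    assert (ha.q_start, ha.q_end) == (hb.t_start, hb.t_end)
    assert (ha.t_start, ha.t_end) == (hb.q_start, hb.q_end)


def test_msa_identical_sequences_gap_free():
    msa = progressive_msa(["ACGTACGTAA"] * 5)
    assert all(row == "ACGTACGTAA" for row in msa)


def test_msa_single_gap_column():
    msa = progressive_msa(["ACGT", "AGT"])
    assert sorted(msa) == ["A-GT", "ACGT"]


def test_msa_requires_two_sequences():
    with pytest.raises(InputError):
        progressive_msa(["ACGT"])


def test_msa_majority_recovers_planted_consensus():
    """Column majorities over 10 copies at 3% divergence equal the truth."""
    from sinekit.refine import column_consensus
    from sinekit.synthetic import mutate_sequence

    rng = np.random.default_rng(12)
    truth = random_seq(rng, 250)
    copies = [mutate_sequence(truth, 0.03, rng)[0] for _ in range(10)]
    msa = progressive_msa(copies)
    cons, support = column_consensus(msa)
    assert cons == truth
    assert np.all(support >= 0.5)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    st.lists(st.text(alphabet="ACGT", min_size=1, max_size=30), min_size=2, max_size=6)
)
def test_msa_rows_recover_inputs(seqs):
    msa = progressive_msa(seqs)
    assert len(set(map(len, msa))) == 1
    for row, seq in zip(msa, seqs):
        assert row.replace("-", "") == seq
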