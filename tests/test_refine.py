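"""Consensus refinement: flanked copies, column consensus, boundaries."""

import numpy as np
import pytest

from conftest import random_seq
from sinekit.align import global_align, progressive_msa
from sinekit.errors import InputError, InsufficientCopiesError, NoElementError
from sinekit.mining import mine_copies, trim_tail_microsatellite
from sinekit.refine import (
    collect_flanked_copies,
    column_consensus,
    detect_boundaries,
    refine_consensus,
)
from sinekit.synthetic import mutate_sequence
from sinekit.util import revcomp


def test_collect_flanked_copies_lengths(family_spec, exact_genome):
    genome, _ = exact_genome
    hits = mine_copies(genome, family_spec.consensus)
    rows = collect_flanked_copies(genome, hits, top_n=10, flank=1000)
    assert len(rows) == 10
    for row, hit in zip(rows, hits[:10]):
        assert len(row) <= hit.length + 2000
        assert len(row) >= hit.length


def test_collect_flanked_copies_clips_at_contig_edge(family_spec, exact_genome):
    genome, _ = exact_genome
    hits = mine_copies(genome, family_spec.consensus)
    first = min(hits, key=lambda h: h.start)
    rows = collect_flanked_copies(genome, [first, hits[0]], top_n=2, flank=10**9)
    assert any(len(r) == len(genome) for r in rows)


def test_collect_flanked_copies_orients_minus_hits(family_spec, exact_genome):
    genome, _ = exact_genome
    hits = mine_copies(genome, family_spec.consensus)
    h = hits[0]
    h_minus = type(h)(
        h.family, h.contig, h.start, h.end, "-", h.score, h.identity,
        h.cons_start, h.cons_end, h.ops,
    )
    fwd = collect_flanked_copies(genome, [h, hits[1]], top_n=2, flank=50)[0]
    rev = collect_flanked_copies(genome, [h_minus, hits[1]], top_n=2, flank=50)[0]
    assert rev == revcomp(fwd)


def test_collect_flanked_copies_needs_two_hits(family_spec, exact_genome):
    genome, _ = exact_genome
    hits = mine_copies(genome, family_spec.consensus)
    with pytest.raises(InsufficientCopiesError):
        collect_flanked_copies(genome, hits[:1])
    with pytest.raises(InputError):
        collect_flanked_copies(genome, hits, top_n=1)


def test_column_consensus_counts_and_ties():
    msa = ["AAG", "AAG", "AAG", "GAG", "GAG"]
    cons, support = column_consensus(msa)
    assert cons == "AAG"
    assert support[0] == pytest.approx(0.6)
    # 2:2 tie breaks alphabetically
    cons_tie, _ = column_consensus(["AT", "AT", "GT", "GT"])
    assert cons_tie == "AT"


def test_column_consensus_drops_gappy_columns():
    msa = ["A-CG", "A-CG", "ATCG", "A-CG"]
    cons, _ = column_consensus(msa)
    assert cons == "ACG"


def _flanked_rows(rng, element, n, flank, divergence):
    rows = []
    for _ in range(n):
        elem = mutate_sequence(element, divergence, rng)[0]
        rows.append(random_seq(rng, flank) + elem + random_seq(rng, flank))
    return rows


def _element_columns(msa_row, flank, elem_len):
    """MSA columns (1-based) of row positions flank+1 .. flank+elem_len."""
    pos = 0
    cols = {}
    for col, ch in enumerate(msa_row, start=1):
        if ch != "-":
            pos += 1
            cols[pos] = col
    return cols[flank + 1], cols[flank + elem_len]


def test_detect_boundaries_exact_copies():
    """Mutation-free copies in random flanks: boundaries within +-3 cols."""
    rng = np.random.default_rng(51)
    element = random_seq(rng, 282)
    rows = _flanked_rows(rng, element, 10, 300, 0.0)
    msa = progressive_msa(rows)
    start, end = detect_boundaries(msa)
    true_start, true_end = _element_columns(msa[0], 300, 282)
    assert abs(start - true_start) <= 3
    assert abs(end - true_end) <= 3


def test_detect_boundaries_diverged_copies():
    rng = np.random.default_rng(52)
    element = random_seq(rng, 282)
    rows = _flanked_rows(rng, element, 10, 300, 0.05)
    msa = progressive_msa(rows)
    start, end = detect_boundaries(msa)
    true_start, true_end = _element_columns(msa[0], 300, 282)
    assert abs(start - true_start) <= 10
    assert abs(end - true_end) <= 10


def test_detect_boundaries_requires_an_element():
    rng = np.random.default_rng(53)
    msa = progressive_msa([random_seq(rng, 400) for _ in range(8)])
    with pytest.raises(NoElementError):
        detect_boundaries(msa)


def test_round_trip_refinement_recovers_consensus(family_spec, exact_genome):
    """plant -> mine -> refine reproduces the planted consensus >= 99%."""
    genome, _ = exact_genome
    hits = mine_copies(genome, family_spec.consensus)
    refined = refine_consensus(genome, hits)
    cons, _ = trim_tail_microsatellite(refined.consensus, family_spec.tail_unit)
    aln = global_align(cons, family_spec.consensus)
    assert aln.identity >= 99.0
    assert abs(len(cons) - len(family_spec.consensus)) <= 6


def test_refinement_idempotent(family_spec, exact_genome):
    """Refining again from the refined consensus changes <= 1% of positions."""
    genome, _ = exact_genome
    hits = mine_copies(genome, family_spec.consensus)
    first = refine_consensus(genome, hits)
    c1, _ = trim_tail_microsatellite(first.consensus, family_spec.tail_unit)
    hits2 = mine_copies(genome, c1)
    second = refine_consensus(genome, hits2)
    c2, _ = trim_tail_microsatellite(second.consensus, family_spec.tail_unit)
    aln = global_align(c1, c2)
    assert aln.identity >= 99.0
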