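"""Pairwise local/global alignment and a small progressive multiple aligner.

All percent identities reported by the pipeline flow through this module.
Identity is computed over aligned columns excluding any column where either
row has a gap (the usual TE-annotation convention); N never matches and is
counted as a mismatch. Default scoring (match +1, mismatch -1, gap open -5,
gap extend -1) favors long contiguous repeat alignments. Gap of length k
costs open + (k-1)*extend. Traceback ties prefer diagonal > up > left so the
output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import InputError
from .util import MASK_CODE, encode, kmer_codes, revcomp


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    """One pairwise alignment between a query `a` and a target `b`.

    Intervals are 1-based inclusive on the forward strand of each input.
    For strand '-', `ops` describe the query aligned against the reverse
    complement of the target interval.
    `ops` is a run-length CIGAR-like string over {=, X, I, D}; I consumes
    query only, D consumes target only.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    score: int
    ops: str
    identity: float

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1

    @property
    def t_span(self) -> int:
        return self.t_end - self.t_start + 1

    def expanded_ops(self) -> str:
        out = []
        num = ""
        for ch in self.ops:
            if ch.isdigit():
                num += ch
            else:
                out.append(ch * int(num))
                num = ""
        return "".join(out)

    def ref_to_query_map(self) -> dict[int, int | None]:
        """Map query ('a'-side) positions to target positions; None = gap.

        Only positions inside the aligned span are present.
        """
        mapping: dict[int, int | None] = {}
        qi, ti = self.q_start, self.t_start
        for op in self.expanded_ops():
            if op in "=X":
                mapping[qi] = ti
                qi += 1
                ti += 1
            elif op == "I":
                mapping[qi] = None
                qi += 1
            else:  # D
                ti += 1
        return mapping


def _rle(ops: list[str]) -> str:
    if not ops:
        return ""
    out = []
    run = 1
    for prev, cur in zip(ops, ops[1:]):
        if cur == prev:
            run += 1
        else:
            out.append(f"{run}{prev}")
            run = 1
    out.append(f"{run}{ops[-1]}")
    return "".join(out)


def _identity(ops: list[str]) -> float:
    matches = sum(1 for o in ops if o == "=")
    cols = sum(1 for o in ops if o in "=X")
    return 100.0 * matches / cols if cols else 0.0


def _check_seq(name: str, s: str) -> None:
    if not s:
        raise InputError(f"{name} is empty")


def global_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> Alignment:
    """End-to-end (Needleman-Wunsch/Gotoh) alignment of a against b."""
    _check_seq("a", a)
    _check_seq("b", b)
    ea, eb = encode(a), encode(b)
    M, X, Y, pM, pX, pY = _kernels.gotoh_global(
        ea, eb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    n, m = len(a), len(b)
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score, state = X[n, m], 1
    if Y[n, m] > score:
        score, state = Y[n, m], 2
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops.append("=" if (ea[i - 1] == eb[j - 1] and ea[i - 1] < 4) else "X")
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops.append("I")
            state = pX[i, j]
            i -= 1
        else:
            ops.append("D")
            state = pY[i, j]
            j -= 1
    ops.reverse()
    return Alignment(1, n, 1, m, "+", int(score), _rle(ops), round(_identity(ops), 6))


def _local_best(ea: np.ndarray, eb: np.ndarray, scoring: Scoring) -> tuple | None:
    M, X, Y, pM, pX, pY, best, bi, bj = _kernels.gotoh_local(
        ea, eb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best <= 0:
        return None
    ops: list[str] = []
    i, j, state = bi, bj, 0
    while True:
        if state == 0:
            ops.append("=" if (ea[i - 1] == eb[j - 1] and ea[i - 1] < 4) else "X")
            p = pM[i, j]
            i -= 1
            j -= 1
            if p == 3:
                break
            state = p
            if state == 0 and M[i, j] <= 0:
                break
        elif state == 1:
            ops.append("I")
            state = pX[i, j]
            i -= 1
        else:
            ops.append("D")
            state = pY[i, j]
            j -= 1
    ops.reverse()
    return int(best), i + 1, bi, j + 1, bj, ops


def local_align(
    a: str,
    b: str,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: int = 20,
    both_strands: bool = True,
    max_hits: int = 64,
) -> list[Alignment]:
    """Non-overlapping (in query) high-scoring local alignments, both strands.

    Iteratively extracts the best Smith-Waterman hit, masks its query
    interval, and repeats until the best score drops below `min_score`.
    """
    _check_seq("a", a)
    _check_seq("b", b)
    ea = encode(a).copy()
    eb_f = encode(b)
    eb_r = encode(revcomp(b))
    m = len(b)
    hits: list[Alignment] = []
    for _ in range(max_hits):
        cand_f = _local_best(ea, eb_f, scoring)
        cand_r = _local_best(ea, eb_r, scoring) if both_strands else None
        cand, strand, is_rev = cand_f, "+", False
        if cand_r is not None and (cand is None or cand_r[0] > cand[0]):
            cand, strand, is_rev = cand_r, "-", True
        if cand is None or cand[0] < min_score:
            break
        score, qs, qe, ts, te, ops = cand
        if is_rev:
            ts, te = m - te + 1, m - ts + 1
        hits.append(
            Alignment(qs, qe, ts, te, strand, score, _rle(ops), round(_identity(ops), 6))
        )
        ea[qs - 1 : qe] = MASK_CODE
    hits.sort(key=lambda h: (-h.score, h.q_start))
    return hits


# ---------------------------------------------------------------------------
# progressive multiple alignment (center-star)
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int = 8) -> set[int]:
    return set(int(c) for c in kmer_codes(encode(seq), k) if c >= 0)


def progressive_msa(seqs: list[str], scoring: Scoring = DEFAULT_SCORING) -> list[str]:
    """Center-star progressive multiple alignment.

    The center sequence (largest summed k-mer similarity to the rest) is
    aligned pairwise against every other sequence; gap patterns are merged
    under the once-a-gap-always-a-gap rule. Each input row is recoverable by
    deleting gap characters.
    """
    if len(seqs) < 2:
        raise InputError("progressive_msa needs at least 2 sequences")
    for s in seqs:
        _check_seq("sequence", s)
    ksets = [_kmer_set(s) for s in seqs]
    sims = [
        sum(len(ksets[i] & ksets[j]) for j in range(len(seqs)) if j != i)
        for i in range(len(seqs))
    ]
    center = int(np.argmax(sims))
    cseq = seqs[center]
    L = len(cseq)

    # For each non-center row: chars inserted before center position i
    # (i in 0..L) and the character aligned to each center position.
    row_ins: list[list[str]] = []
    row_cols: list[list[str]] = []
    others = [i for i in range(len(seqs)) if i != center]
    for idx in others:
        aln = global_align(cseq, seqs[idx], scoring)
        ins: list[str] = ["" for _ in range(L + 1)]
        cols: list[str] = []
        ci = 0  # center positions consumed
        si = 0  # other-sequence positions consumed
        for op in aln.expanded_ops():
            if op in "=X":
                cols.append(seqs[idx][si])
                ci += 1
                si += 1
            elif op == "I":  # center base vs gap
                cols.append("-")
                ci += 1
            else:  # D: other-sequence base inserted relative to center
                ins[ci] += seqs[idx][si]
                si += 1
        row_ins.append(ins)
        row_cols.append(cols)

    master_ins = [max(len(ins[i]) for ins in row_ins) for i in range(L + 1)]

    rows_out: dict[int, str] = {}
    center_parts = []
    for i in range(L + 1):
        center_parts.append("-" * master_ins[i])
        if i < L:
            center_parts.append(cseq[i])
    rows_out[center] = "".join(center_parts)
    for k_i, idx in enumerate(others):
        parts = []
        for i in range(L + 1):
            block = row_ins[k_i][i]
            parts.append(block + "-" * (master_ins[i] - len(block)))
            if i < L:
                parts.append(row_cols[k_i][i])
        rows_out[idx] = "".join(parts)
    return [rows_out[i] for i in range(len(seqs))]
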