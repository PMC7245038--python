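"""Genome-wide search for copies of a family consensus.

The search is seed-and-extend: exact k-mer seeds (default k=12) between the
consensus and the contig are clustered by diagonal, and each candidate
window is verified with a local affine-gap alignment of the consensus
against the window. This stands in for the remote-homology search services
used in classical repeat curation, scaled to the pipeline's needs: at 10%
divergence a 12-mer seed is still expected every ~4 bp of consensus.

Hits touching a contig end are discarded because downstream stages need
flanking sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import DEFAULT_SCORING, Scoring, _identity, _local_best, _rle
from .errors import InputError
from .util import encode, kmer_codes, revcomp


@dataclass
class CopyHit:
    """One genomic occurrence of a family consensus."""

    family: str
    contig: str
    start: int  # 1-based inclusive genomic interval
    end: int
    strand: str
    score: int
    identity: float  # percent over gap-free aligned columns
    cons_start: int  # consensus coverage interval (1-based inclusive)
    cons_end: int
    ops: str = ""
    full_length: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def coverage(self) -> int:
        return self.cons_end - self.cons_start + 1


def _seed_clusters(
    gcodes: np.ndarray, cons_kmers: dict[int, list[int]], cons_len: int, max_diag_gap: int = 30
) -> list[tuple[int, int]]:
    """Candidate genomic windows (0-based half-open) from clustered seeds."""
    cons_code_arr = np.fromiter(cons_kmers.keys(), dtype=np.int64, count=len(cons_kmers))
    if cons_code_arr.size == 0 or gcodes.size == 0:
        return []
    match_pos = np.nonzero(np.isin(gcodes, cons_code_arr))[0]
    seeds = []  # (diag, gpos, cpos)
    for gp in match_pos:
        for cp in cons_kmers[int(gcodes[gp])]:
            seeds.append((int(gp) - cp, int(gp), cp))
    if not seeds:
        return []
    seeds.sort()
    windows = []
    cur = [seeds[0]]
    for s in seeds[1:]:
        prev = cur[-1]
        if s[0] - prev[0] <= max_diag_gap and s[1] - prev[1] <= cons_len:
            cur.append(s)
        else:
            windows.append(cur)
            cur = [s]
    windows.append(cur)
    pad = 40
    out = []
    for w in windows:
        gstart = min(g - c for _, g, c in w) - pad
        gend = max(g + (cons_len - c) for _, g, c in w) + pad
        out.append((max(0, gstart), min(gcodes.size + 100, gend)))
    # merge overlapping windows
    out.sort()
    merged = [out[0]]
    for s, e in out[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def mine_copies(
    genome: str,
    consensus: str,
    family: str = "family",
    contig: str = "contig",
    min_identity: float = 80.0,
    min_len: int = 50,
    k: int = 12,
    scoring: Scoring = DEFAULT_SCORING,
    both_strands: bool = True,
) -> list[CopyHit]:
    """All genomic copies of `consensus` above identity/length thresholds.

    Hits are sorted by score (descending); overlapping hits on the same
    strand are merged to the higher-scoring one.
    """
    if len(consensus) < min_len:
        raise InputError("consensus shorter than min_len")
    if not genome:
        return []
    gcodes_k = kmer_codes(encode(genome), k)
    cons_len = len(consensus)
    hits: list[CopyHit] = []
    strands = [("+", consensus)]
    if both_strands:
        strands.append(("-", revcomp(consensus)))
    for strand, cons in strands:
        ckmers: dict[int, list[int]] = {}
        for i, code in enumerate(kmer_codes(encode(cons), k)):
            if code >= 0:
                ckmers.setdefault(int(code), []).append(i)
        for ws, we in _seed_clusters(gcodes_k, ckmers, cons_len):
            window = genome[ws:we]
            ecs = encode(cons)
            ew = encode(window)
            cand = _local_best(ecs, ew, scoring)
            if cand is None:
                continue
            score, qs, qe, ts, te, ops = cand
            ident = _identity(ops)
            if qe - qs + 1 < min_len or ident < min_identity:
                continue
            gstart, gend = ws + ts, ws + te  # 1-based genomic
            if strand == "-":
                # coverage interval back on the forward consensus
                cs, ce = cons_len - qe + 1, cons_len - qs + 1
            else:
                cs, ce = qs, qe
            if gstart <= 1 or gend >= len(genome):
                continue  # flanks required downstream
            hits.append(
                CopyHit(
                    family=family,
                    contig=contig,
                    start=gstart,
                    end=gend,
                    strand=strand,
                    score=score,
                    identity=round(ident, 4),
                    cons_start=cs,
                    cons_end=ce,
                    ops=_rle(ops),
                )
            )
    hits.sort(key=lambda h: (-h.score, h.start))
    kept: list[CopyHit] = []
    for h in hits:
        clash = any(
            k2.strand == h.strand and not (h.end < k2.start or h.start > k2.end)
            for k2 in kept
        )
        if not clash:
            kept.append(h)
    return kept


def trim_tail_microsatellite(seq: str, unit: str, min_units: int = 3) -> tuple[str, int]:
    """Remove the maximal 3'-terminal tandem run of `unit` (>= min_units).

    A trailing partial unit is allowed at the very 3' end. Returns the
    trimmed sequence and the number of full units removed; idempotent.
    """
    if not unit:
        raise InputError("empty microsatellite unit")
    if not 1 <= len(unit) <= 6:
        raise InputError("unit length must be 1..6")
    u = len(unit)
    best = (0, 0)  # (full units, partial length)
    for p in range(u - 1, -1, -1):
        if p and not seq.endswith(unit[:p]):
            continue
        i = len(seq) - p
        m = 0
        while i >= u and seq[i - u : i] == unit:
            i -= u
            m += 1
        if (m, p) > best:
            best = (m, p)
    m, p = best
    if m < min_units:
        return seq, 0
    return seq[: len(seq) - (m * u + p)], m


def extend_through_tail(
    genome: str, end: int, unit: str, max_total_mismatch: int = 2
) -> int:
    """Advance a hit's 3' end (1-based) through a microsatellite tail run.

    Greedy unit-by-unit scan allowing at most one substituted base per unit
    (confirmed by an exact following unit) and `max_total_mismatch` such
    units overall — planted tails accumulate substitutions at the family
    divergence rate. A short non-unit remnant (a trimmed alignment end) may
    be skipped when an unambiguous run of two exact units follows. Trailing
    partial units are left in place: a microsatellite tail grows in whole
    units, and consuming a lookalike partial would truncate the start of
    the downstream target-site duplication. Returns the new end.
    """
    if not unit:
        return end
    u = len(unit)
    pos = end  # 1-based end; genome[pos:] (0-based) is the unscanned suffix
    mm_budget = max_total_mismatch
    while pos + u <= len(genome):
        block = genome[pos : pos + u]
        mm = sum(1 for a, b in zip(block, unit) if a != b)
        if mm == 0:
            pos += u
            continue
        if mm == 1 and mm_budget > 0 and genome[pos + u : pos + 2 * u] == unit:
            mm_budget -= 1
            pos += u
            continue
        skipped = False
        for off in range(1, u + 3):
            if genome[pos + off : pos + off + 2 * u] == unit * 2:
                pos += off
                skipped = True
                break
        if not skipped:
            break
    return pos


def classify_full_length(
    hit: CopyHit, consensus_len: int, start_tol: int = 5, min_cov: float = 0.95
) -> bool:
    """Full length: coverage starts within `start_tol` bp of consensus
    position 1 and spans >= `min_cov` of the consensus."""
    return (
        hit.cons_start <= 1 + start_tol
        and hit.coverage >= min_cov * consensus_len
    )
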