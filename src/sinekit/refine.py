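"""Consensus refinement from the top-scoring genomic copies.

The procedure mirrors classical repeat-library curation: extract the
top-N copies with generous flanking sequence (defaults: top 10, 1000 bp
flanks), align them, and call the element boundaries as the region where
the copies agree — the flanks are unrelated host sequence, so per-column
agreement collapses outside the element.

Boundary calling: per-column support (frequency of the plurality base among
non-gap rows) is smoothed over a 10-column window; the maximal run with
smoothed support >= 0.7 and gap fraction <= 0.5 is taken, then both ends
are refined against the raw (unsmoothed) per-column values. For 10 random
flank rows the expected support is ~0.4, far below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import DEFAULT_SCORING, Scoring, progressive_msa
from .errors import InputError, InsufficientCopiesError, NoElementError
from .mining import CopyHit
from .util import revcomp

GAP_ORD = ord("-")


def collect_flanked_copies(
    genome: str,
    hits: list[CopyHit],
    top_n: int = 10,
    flank: int = 1000,
) -> list[str]:
    """The `top_n` highest-scoring hits with `flank` bp each side.

    Flanks are clipped at contig ends; minus-strand hits are reverse
    complemented so every returned row reads element-forward.
    """
    if top_n < 2:
        raise InputError("top_n must be >= 2")
    if len(hits) < 2:
        raise InsufficientCopiesError(f"need >= 2 hits, got {len(hits)}")
    chosen = sorted(hits, key=lambda h: (-h.score, h.start))[:top_n]
    rows = []
    for h in chosen:
        s = max(1, h.start - flank)
        e = min(len(genome), h.end + flank)
        seq = genome[s - 1 : e]
        if h.strand == "-":
            seq = revcomp(seq)
        rows.append(seq)
    return rows


def _msa_matrix(msa: list[str]) -> np.ndarray:
    if len(set(len(r) for r in msa)) != 1:
        raise InputError("MSA rows have unequal lengths")
    return np.frombuffer("".join(msa).encode("ascii"), dtype=np.uint8).reshape(
        len(msa), -1
    )


def column_profile(msa: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (plurality base ord, support, gap fraction).

    Support = plurality-base count / non-gap rows (0 where all rows gap).
    Base ties break alphabetically (A < C < G < T).
    """
    mat = _msa_matrix(msa)
    nrow = mat.shape[0]
    counts = np.stack([(mat == ord(b)).sum(axis=0) for b in "ACGT"])
    gap_frac = (nrow - counts.sum(axis=0)) / nrow
    nongap = np.maximum(counts.sum(axis=0), 1)
    best_idx = counts.argmax(axis=0)  # argmax is first max -> alphabetical
    support = counts.max(axis=0) / nongap
    base_ord = np.frombuffer(b"ACGT", dtype=np.uint8)[best_idx]
    return base_ord, support, gap_frac


def column_consensus(
    msa: list[str], max_gap_frac: float = 0.5
) -> tuple[str, np.ndarray]:
    """Majority/plurality consensus over an MSA.

    Columns where more than `max_gap_frac` of rows are gaps are dropped.
    Returns the consensus string and per-emitted-column support fractions.
    """
    if len(msa) < 2:
        raise InputError("column_consensus needs >= 2 rows")
    base_ord, support, gap_frac = column_profile(msa)
    keep = gap_frac <= max_gap_frac
    cons = base_ord[keep].tobytes().decode("ascii")
    return cons, support[keep]


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def detect_boundaries(
    msa: list[str],
    support_min: float = 0.7,
    max_gap_frac: float = 0.5,
    smooth_window: int = 10,
    min_run: int = 30,
) -> tuple[int, int]:
    """Element start/end columns (1-based inclusive) in a flanked-copy MSA.

    Only columns with gap fraction <= `max_gap_frac` are considered:
    high-gap insertion columns are alignment artifacts that the consensus
    never emits, so they must not interrupt the element run.
    """
    if len(msa) < 2:
        raise InputError("detect_boundaries needs >= 2 rows")
    _, support, gap_frac = column_profile(msa)
    emit = np.nonzero(gap_frac <= max_gap_frac)[0]
    if emit.size == 0:
        raise NoElementError("alignment has no low-gap columns")
    sup = support[emit]
    sm = _smooth(sup, smooth_window)
    ok = sm >= support_min
    best_len, best_start = 0, -1
    run_start = None
    for i, v in enumerate(np.append(ok, False)):
        if v and run_start is None:
            run_start = i
        elif not v and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < min_run:
        raise NoElementError("no well-supported element region in the alignment")
    start, end = best_start, best_start + best_len - 1
    raw_ok = sup >= support_min
    # anchor each edge on `anchor` consecutive high-support columns so that
    # isolated lucky flank columns cannot drag the boundary outward, then
    # walk back to the exact edge
    anchor = 5
    for c in range(start, end - anchor + 2):
        if raw_ok[c : c + anchor].all():
            start = c
            break
    for c in range(end, start + anchor - 2, -1):
        if raw_ok[c - anchor + 1 : c + 1].all():
            end = c
            break
    while start > 0 and raw_ok[start - 1]:
        start -= 1
    while end < raw_ok.size - 1 and raw_ok[end + 1]:
        end += 1
    return int(emit[start]) + 1, int(emit[end]) + 1


@dataclass
class RefinedConsensus:
    consensus: str
    support: np.ndarray  # per consensus column
    msa: list[str]
    boundaries: tuple[int, int]  # MSA columns, 1-based inclusive


def refine_consensus(
    genome: str,
    hits: list[CopyHit],
    top_n: int = 10,
    flank: int = 1000,
    scoring: Scoring = DEFAULT_SCORING,
    **boundary_kwargs,
) -> RefinedConsensus:
    """Full refinement: collect flanked copies, align, call boundaries,
    emit the majority-rule consensus of the element region."""
    rows = collect_flanked_copies(genome, hits, top_n=top_n, flank=flank)
    msa = progressive_msa(rows, scoring)
    start, end = detect_boundaries(msa, **boundary_kwargs)
    sub = [row[start - 1 : end] for row in msa]
    cons, support = column_consensus(sub)
    return RefinedConsensus(cons, support, msa, (start, end))
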