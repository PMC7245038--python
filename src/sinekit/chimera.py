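"""Decompose a SINE consensus into donor-derived segments and classify it.

SINEs are composite elements: a small-RNA-derived head (7SL RNA -> SINE1,
tRNA -> SINE2, 5S rRNA -> SINE3) carrying the pol III internal promoter, an
optional deeply conserved central body domain, and a LINE-derived tail that
the partner retrotransposon's machinery recognizes. Segmentation searches
the consensus against a labeled donor library (both strands) and resolves
the candidate segments into a maximum-score non-overlapping tiling by
weighted interval scheduling, tolerating small overlaps at junctions
because homology-defined breakpoints are fuzzy.

Donor roles come from user-supplied metadata (FASTA `role=` fields), never
from inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import DEFAULT_SCORING, Scoring, local_align
from .errors import InputError
from .synthetic import ROLE_MAP

SEGMENT_ROLES = ("head7SL", "headtRNA", "head5S", "body", "tailLINE", "unassigned")
HEAD_CLASS = {"head7SL": "SINE1", "headtRNA": "SINE2", "head5S": "SINE3"}


@dataclass
class Segment:
    donor: str | None
    donor_start: int
    donor_end: int
    cons_start: int  # 1-based inclusive on the consensus
    cons_end: int
    strand: str
    identity: float
    score: int
    role: str

    @property
    def length(self) -> int:
        return self.cons_end - self.cons_start + 1


@dataclass
class Architecture:
    family: str
    roles: str  # e.g. "head7SL-head7SL-body-tailLINE-tailLINE"
    sine_class: str  # SINE1 | SINE2 | SINE3 | non-SINE | unclassified
    bipartite_line_tail: bool = False
    segments: list[Segment] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "roles": self.roles,
            "sine_class": self.sine_class,
            "bipartite_line_tail": self.bipartite_line_tail,
            "segments": [
                {
                    "donor": s.donor,
                    "donor_start": s.donor_start,
                    "donor_end": s.donor_end,
                    "cons_start": s.cons_start,
                    "cons_end": s.cons_end,
                    "strand": s.strand,
                    "identity": s.identity,
                    "score": s.score,
                    "role": s.role,
                }
                for s in self.segments
            ],
        }


def segment_against_library(
    consensus: str,
    donors: dict[str, str],
    donor_roles: dict[str, str],
    min_identity: float = 65.0,
    min_seg_len: int = 25,
    min_score: int = 20,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[Segment]:
    """Candidate donor-derived segments of the consensus, both strands."""
    if not donors:
        raise InputError("donor library is empty")
    candidates: list[Segment] = []
    for label, dseq in donors.items():
        role = ROLE_MAP.get(donor_roles.get(label, ""), "unassigned")
        for aln in local_align(consensus, dseq, scoring, min_score=min_score):
            if aln.q_span < min_seg_len or aln.identity < min_identity:
                continue
            candidates.append(
                Segment(
                    donor=label,
                    donor_start=aln.t_start,
                    donor_end=aln.t_end,
                    cons_start=aln.q_start,
                    cons_end=aln.q_end,
                    strand=aln.strand,
                    identity=aln.identity,
                    score=aln.score,
                    role=role,
                )
            )
    candidates.sort(key=lambda s: (s.cons_start, -s.score))
    return candidates


def resolve_tiling(
    candidates: list[Segment],
    overlap_tol: int = 10,
    min_gap_report: int = 25,
    consensus_len: int | None = None,
) -> list[Segment]:
    """Maximum-total-score subset of mutually compatible segments.

    Segments are compatible when they overlap by at most `overlap_tol` bp
    on the consensus (weighted interval scheduling). Uncovered gaps of at
    least `min_gap_report` bp are reported as role `unassigned`.
    """
    if not candidates:
        return []
    segs = sorted(candidates, key=lambda s: (s.cons_end, s.cons_start))
    n = len(segs)
    best = [0] * n
    prev = [-1] * n
    for i, si in enumerate(segs):
        take = si.score
        back = -1
        for j in range(i - 1, -1, -1):
            if segs[j].cons_end <= si.cons_start + overlap_tol - 1:
                if si.score + best[j] > take:
                    take = si.score + best[j]
                    back = j
        best[i] = take
        prev[i] = back
    end = max(range(n), key=lambda i: (best[i], -segs[i].cons_start))
    chosen = []
    i = end
    while i >= 0:
        chosen.append(segs[i])
        i = prev[i]
    chosen.reverse()
    out = list(chosen)
    if min_gap_report:
        gaps = []
        cursor = 1
        for s in chosen:
            if s.cons_start - cursor >= min_gap_report:
                gaps.append((cursor, s.cons_start - 1))
            cursor = max(cursor, s.cons_end + 1)
        if consensus_len and consensus_len - cursor + 1 >= min_gap_report:
            gaps.append((cursor, consensus_len))
        for gs, ge in gaps:
            out.append(Segment(None, 0, 0, gs, ge, "+", 0.0, 0, "unassigned"))
    out.sort(key=lambda s: (s.cons_start, s.cons_end))
    return out


def flag_bipartite_line_tail(
    tiling: list[Segment], donors: dict[str, str], end_margin: int = 50
) -> bool:
    """Two tail segments from one LINE donor — one from its 5' region, one
    reaching the donor's 3' terminus — mark an internally deleted
    (bipartite) non-autonomous LINE derivative."""
    by_donor: dict[str, list[Segment]] = {}
    for s in tiling:
        if s.role == "tailLINE" and s.donor:
            by_donor.setdefault(s.donor, []).append(s)
    for donor, segs in by_donor.items():
        if len(segs) < 2:
            continue
        dlen = len(donors.get(donor, ""))
        if not dlen:
            continue
        has_5p = any(s.donor_end <= dlen / 2 for s in segs)
        has_3p = any(s.donor_end >= dlen - end_margin for s in segs)
        if has_5p and has_3p:
            return True
    return False


def classify_family(
    tiling: list[Segment],
    family: str = "family",
    donors: dict[str, str] | None = None,
    consensus_len: int | None = None,
) -> Architecture:
    """Assign the SINE class from the 5'-most head segment of the tiling."""
    assigned = [s for s in tiling if s.role != "unassigned"]
    if not assigned:
        raise InputError("empty tiling")
    roles = "-".join(s.role for s in assigned)
    five_most = min(assigned, key=lambda s: (s.cons_start, s.cons_end))
    if (
        len(assigned) == 1
        and five_most.role == "tailLINE"
        and consensus_len
        and five_most.length >= 0.9 * consensus_len
    ):
        sine_class = "non-SINE"
    else:
        sine_class = HEAD_CLASS.get(five_most.role, "unclassified")
    bipartite = flag_bipartite_line_tail(tiling, donors or {})
    return Architecture(family, roles, sine_class, bipartite, list(tiling))
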