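"""RNA secondary-structure comparison and pol III promoter-box search.

The Alu domain — the base-paired structure formed by the 5' and 3' regions
of 7SL RNA and bound by SRP9/14 — is retained by 7SL-derived SINE heads.
When a reference structure (dot-bracket, supplied as input; the package
does no thermodynamic folding) is mapped through an alignment onto a
homologous sequence, each base pair is classified:

  conserved          both bases identical to the reference
  compensatory       both differ, pairing restored as a Watson-Crick pair
  wobble-preserving  pairing kept only through G-U, or a single change to
                     any canonical pair
  half-broken        one base changed, pairing lost
  broken             both changed, pairing lost
  deleted            a partner aligned to a gap

Compensatory substitutions are the classic evidence of structural
constraint. T and U are equivalent throughout.

The pol III internal promoter is located by Hamming distance to canonical
A-box/B-box motifs around their expected positions (6-15 and 76-86 in
human 7SL RNA numbering).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .align import Alignment
from .errors import InputError

# printed promoter decamers/11-mers for the human and hagfish 7SL RNA genes
HUMAN_7SL_BOX_A = "GGCGCGGTGG"
HAGFISH_7SL_BOX_A = "GGCGCAGTGG"
HUMAN_7SL_BOX_B = "AGTTCTGGGCT"
HAGFISH_7SL_BOX_B = "AGCTCTGCGCT"

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

_OPENERS = {"(": ")", "[": "]"}
_CLOSERS = {v: k for k, v in _OPENERS.items()}


@dataclass
class PairTable:
    """Base pairs of a structure: (i, j) with i < j, 1-based, each position
    in at most one pair."""

    length: int
    pairs: list[tuple[int, int]]

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise InputError(f"invalid pair ({i},{j}) for length {self.length}")
            if i in seen or j in seen:
                raise InputError("a position participates in more than one pair")
            seen.update((i, j))
        self.pairs = sorted(self.pairs)


@dataclass
class PairChangeRecord:
    ref_pair: tuple[int, int]
    query_pair: tuple[int | None, int | None]
    ref_bases: str
    query_bases: str
    category: str  # conserved|compensatory|wobble-preserving|half-broken|broken|deleted


@dataclass
class PromoterBoxes:
    box_a: tuple[int, int]
    box_a_seq: str
    box_a_distance: int
    box_b: tuple[int, int]
    box_b_seq: str
    box_b_distance: int


def parse_dotbracket(s: str) -> PairTable:
    """Dot-bracket string -> pair table; '[]' marks a second (e.g. tertiary)
    tier. Unbalanced input is a parse error."""
    stacks: dict[str, list[int]] = {"(": [], "[": []}
    pairs = []
    for pos, ch in enumerate(s, start=1):
        if ch in _OPENERS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            stack = stacks[_CLOSERS[ch]]
            if not stack:
                raise InputError(f"unbalanced {ch!r} at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch not in ".-":
            raise InputError(f"unexpected character {ch!r} in dot-bracket string")
    for opener, stack in stacks.items():
        if stack:
            raise InputError(f"unbalanced {opener!r} at position {stack[-1]}")
    return PairTable(len(s), pairs)


def render_dotbracket(pt: PairTable) -> str:
    """Pair table -> dot-bracket; crossing pairs go to the '[]' tier."""
    chars = ["."] * pt.length
    placed: list[tuple[int, int]] = []

    def crosses(a, b) -> bool:
        return a[0] < b[0] < a[1] < b[1] or b[0] < a[0] < b[1] < a[1]

    tier2 = []
    for p in pt.pairs:
        if any(crosses(p, q) for q in placed):
            tier2.append(p)
        else:
            placed.append(p)
            chars[p[0] - 1], chars[p[1] - 1] = "(", ")"
    for p in tier2:
        if any(crosses(p, q) for q in tier2 if q != p and chars[q[0] - 1] == "["):
            raise InputError("structure needs more than two bracket tiers")
        chars[p[0] - 1], chars[p[1] - 1] = "[", "]"
    return "".join(chars)


def map_pairs_through_alignment(
    pairs: PairTable, aln: Alignment
) -> list[tuple[tuple[int, int], tuple[int | None, int | None], str]]:
    """Map reference-indexed pairs to query coordinates through `aln`.

    The alignment's `a` side is the structure's reference sequence. Returns
    (ref_pair, query_pair, fate) with fate 'mapped' or 'deleted' (either
    partner aligned to a gap).
    """
    mapping = aln.ref_to_query_map()
    out = []
    for i, j in pairs.pairs:
        if i not in mapping or j not in mapping:
            raise InputError(f"pair ({i},{j}) outside the aligned span")
        qi, qj = mapping[i], mapping[j]
        fate = "deleted" if qi is None or qj is None else "mapped"
        out.append(((i, j), (qi, qj), fate))
    return out


def _norm(base: str) -> str:
    b = base.upper()
    return "U" if b == "T" else b


def classify_pair_changes(
    ref_seq: str,
    query_seq: str,
    mapped_pairs: list[tuple[tuple[int, int], tuple[int | None, int | None], str]],
) -> tuple[list[PairChangeRecord], Counter]:
    """Classify each mapped base pair; categories partition non-deleted
    pairs, so the summary counts sum to the number of mapped pairs."""
    records = []
    summary: Counter = Counter()
    for (i, j), (qi, qj), fate in mapped_pairs:
        if not (1 <= i <= len(ref_seq) and 1 <= j <= len(ref_seq)):
            raise InputError("pair index outside the reference sequence")
        r1, r2 = _norm(ref_seq[i - 1]), _norm(ref_seq[j - 1])
        if fate == "deleted":
            cat, q1, q2 = "deleted", "", ""
        else:
            if qi > len(query_seq) or qj > len(query_seq):
                raise InputError("mapped position outside the query sequence")
            q1, q2 = _norm(query_seq[qi - 1]), _norm(query_seq[qj - 1])
            changed = (q1 != r1) + (q2 != r2)
            paired_wc = (q1, q2) in WC_PAIRS
            paired_wobble = (q1, q2) in WOBBLE_PAIRS
            if changed == 0:
                cat = "conserved"
            elif paired_wobble:
                cat = "wobble-preserving"
            elif changed == 1:
                cat = "wobble-preserving" if paired_wc else "half-broken"
            else:
                cat = "compensatory" if paired_wc else "broken"
        summary[cat] += 1
        records.append(
            PairChangeRecord((i, j), (qi, qj), r1 + r2, q1 + q2, cat)
        )
    return records, summary


def box_hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length motifs."""
    if len(a) != len(b):
        raise InputError("motifs must have equal lengths")
    return sum(1 for x, y in zip(a.upper(), b.upper()) if x != y)


def find_promoter_boxes(
    head: str,
    box_a: str = HUMAN_7SL_BOX_A,
    box_b: str = HUMAN_7SL_BOX_B,
    expected: tuple[int, int] = (6, 76),
    window: int = 10,
) -> PromoterBoxes:
    """Locate the pol III A and B boxes in a SINE head.

    Within +-`window` of each expected start the offset minimizing Hamming
    distance to the canonical motif wins; ties go to the position closest
    to the expected start.
    """
    exp_a, exp_b = expected
    if len(head) < exp_b + len(box_b) - 1:
        raise InputError("head shorter than the expected B-box end")

    def best(motif: str, exp: int) -> tuple[int, int]:
        lo = max(1, exp - window)
        hi = min(len(head) - len(motif) + 1, exp + window)
        if hi < lo:
            raise InputError("head too short for the promoter search window")
        ranked = [
            (box_hamming(head[s - 1 : s - 1 + len(motif)], motif), abs(s - exp), s)
            for s in range(lo, hi + 1)
        ]
        d, _, s = min(ranked)
        return s, d

    sa, da = best(box_a, exp_a)
    sb, db = best(box_b, exp_b)
    if sa + len(box_a) - 1 >= sb:
        raise InputError("A box not upstream of B box")
    return PromoterBoxes(
        (sa, sa + len(box_a) - 1),
        head[sa - 1 : sa - 1 + len(box_a)],
        da,
        (sb, sb + len(box_b) - 1),
        head[sb - 1 : sb - 1 + len(box_b)],
        db,
    )
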