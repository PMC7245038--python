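"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment scoring by
exhaustive enumeration of alignments, TSD search by a plain substring-pair
scan, tiling by subset enumeration, and pair-change categories from a
literal truth table.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -1, -5, -1


def affine_score(ops: str, a: str, b: str) -> int:
    """Score an explicit op string (M per column, I/D for gaps) under the
    affine scheme: a gap run of length k costs GAP_OPEN + (k-1)*GAP_EXT."""
    score = 0
    i = j = 0
    prev = None
    for op in ops:
        if op == "M":
            score += MATCH if a[i] == b[j] else MISMATCH
            i += 1
            j += 1
        else:
            score += GAP_EXT if op == prev else GAP_OPEN
            if op == "I":
                i += 1
            else:
                j += 1
        prev = op
    return score


def best_global_score(a: str, b: str) -> int:
    """Exhaustive enumeration of all global alignments (tiny inputs only)."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int, prev: str) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = None
        if i < len(a) and j < len(b):
            s = (MATCH if a[i] == b[j] else MISMATCH) + go(i + 1, j + 1, "M")
            best = s
        if i < len(a):
            s = (GAP_EXT if prev == "I" else GAP_OPEN) + go(i + 1, j, "I")
            best = s if best is None else max(best, s)
        if j < len(b):
            s = (GAP_EXT if prev == "D" else GAP_OPEN) + go(i, j + 1, "D")
            best = s if best is None else max(best, s)
        return best

    return go(0, 0, "")


def best_tsd(
    left: str, right: str, min_len: int, max_mm: int, max_off: int
) -> tuple[int, int] | None:
    """(length, mismatches) of the best-scoring flanking direct repeat under
    score = length - 2*mismatches, ties to smallest offset sum then longest."""
    best = None
    nl = len(left)
    for o_l in range(max_off + 1):
        for o_r in range(max_off + 1):
            limit = min(nl - o_l, len(right) - o_r)
            for length in range(min_len, limit + 1):
                ls = left[nl - o_l - length : nl - o_l]
                rs = right[o_r : o_r + length]
                mm = 0
                for x, y in zip(ls, rs):
                    if x != y:
                        mm += 1
                        if mm > max_mm:
                            break
                if mm > max_mm:
                    continue
                key = (length - 2 * mm, -(o_l + o_r), length, -o_l, -o_r)
                if best is None or key > best[0]:
                    best = (key, (length, mm))
    return best[1] if best else None


def best_tiling_score(intervals: list[tuple[int, int, int]], tol: int = 10) -> int:
    """Max total score over subsets of (start, end, score) intervals whose
    pairwise overlap is <= tol bp, by bitmask enumeration (n <= ~15)."""
    n = len(intervals)
    incompat = [0] * n
    for i, j in itertools.combinations(range(n), 2):
        si, ei, _ = intervals[i]
        sj, ej, _ = intervals[j]
        if min(ei, ej) - max(si, sj) + 1 > tol:
            incompat[i] |= 1 << j
            incompat[j] |= 1 << i
    best = 0
    for mask in range(1 << n):
        total = 0
        ok = True
        m = mask
        i = 0
        while m:
            if m & 1:
                if incompat[i] & mask:
                    ok = False
                    break
                total += intervals[i][2]
            m >>= 1
            i += 1
        if ok and total > best:
            best = total
    return best


# literal pair-change truth table, written from the definitions rather than
# the implementation's control flow
def pair_category(ref: str, qry: str) -> str:
    canonical = {"AU", "UA", "GC", "CG", "GU", "UG"}
    watson_crick = {"AU", "UA", "GC", "CG"}
    n_changed = (ref[0] != qry[0]) + (ref[1] != qry[1])
    if n_changed == 0:
        return "conserved"
    if qry in {"GU", "UG"}:
        return "wobble-preserving"
    if n_changed == 1:
        return "wobble-preserving" if qry in canonical else "half-broken"
    return "compensatory" if qry in watson_crick else "broken"
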