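"""Target-site duplication detection and length profiling.

A retrotransposon insertion duplicates the few bp of host sequence at the
integration site, leaving a direct repeat immediately 5' and 3' of the
element. Detection scans for the best-scoring pair of
(suffix-region substring of the left flank, prefix-region substring of the
right flank) where each repeat sits within `max_offset` bp of the element
boundary. Score = length - 2*mismatches; ties prefer the pair closest to
the boundary (smallest summed offset), then the longer repeat.

Defaults follow the shortest duplication worth reporting for RTE-mobilized
elements (min_len 6) and tolerate a couple of substitutions in older
copies (max_mismatch 2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .util import encode


@dataclass
class TSDCall:
    left_seq: str
    right_seq: str
    length: int
    mismatches: int
    offset_left: int  # bp between left repeat end and the element boundary
    offset_right: int  # bp between the element boundary and right repeat start
    copy_id: str = ""

    @property
    def score(self) -> int:
        return self.length - 2 * self.mismatches


def detect_tsd(
    left_flank: str,
    right_flank: str,
    min_len: int = 6,
    max_mismatch: int = 2,
    max_offset: int = 5,
) -> TSDCall | None:
    """Best direct-repeat pair flanking an insertion, or None.

    `left_flank` is the sequence immediately 5' of the element (the repeat
    is expected near its 3' end); `right_flank` is immediately 3' (repeat
    near its 5' start).
    """
    if len(left_flank) < 30 or len(right_flank) < 30:
        raise InputError("flanks must each be >= 30 bp")
    el = encode(left_flank)
    er = encode(right_flank)
    nl = len(left_flank)
    best = None  # (score, -(oL+oR), length, -oL, call fields)
    for o_l in range(max_offset + 1):
        for o_r in range(max_offset + 1):
            max_len = min(nl - o_l, len(right_flank) - o_r)
            for length in range(min_len, max_len + 1):
                lseg = el[nl - o_l - length : nl - o_l]
                rseg = er[o_r : o_r + length]
                mm = int(np.count_nonzero(lseg != rseg))
                if mm > max_mismatch:
                    continue
                score = length - 2 * mm
                key = (score, -(o_l + o_r), length, -o_l, -o_r)
                if best is None or key > best[0]:
                    best = (
                        key,
                        TSDCall(
                            left_seq=left_flank[nl - o_l - length : nl - o_l],
                            right_seq=right_flank[o_r : o_r + length],
                            length=length,
                            mismatches=mm,
                            offset_left=o_l,
                            offset_right=o_r,
                        ),
                    )
    return best[1] if best else None


def tsd_profile(calls: list[TSDCall]) -> tuple[dict[int, int], tuple[int, ...]]:
    """Length histogram and modal length(s) of a set of TSD calls.

    Ties are reported as a tuple of all tied lengths (ascending).
    """
    if not calls:
        raise InputError("tsd_profile needs at least one call")
    counts = Counter(c.length for c in calls)
    top = max(counts.values())
    modes = tuple(sorted(length for length, n in counts.items() if n == top))
    hist = dict(sorted(counts.items()))
    return hist, modes
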