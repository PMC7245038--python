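"""Copy-to-consensus identity distributions as a relative age proxy.

The modal bin of percent identity between copies and their consensus tracks
the age of a repeat family: a family whose peak sits between 97 and 96%
expanded more recently than one peaking between 83 and 82%. Identities are
raw gap-excluded percentages (no Kimura or CpG correction).

Bin convention: 1-percent bins (lower, upper], labeled "upper-lower"
descending from 100 (an identity of exactly 97 falls in "97-96"). Peak ties
break toward the lower-identity (older) bin — a conservative age estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import InputError
from .mining import CopyHit

_EPS = 1e-9


@dataclass
class IdentityHistogram:
    family: str
    bin_width: float
    labels: list[str]  # descending from "100-99"
    counts: list[int]
    peak_label: str
    peak_bounds: tuple[float, float]  # (lower, upper)
    n: int
    top_k_mean: float  # mean identity of the top-k copies (k <= 10)

    def peak_contains(self, value: float) -> bool:
        """Whether `value` lies in the peak bin, bounds inclusive.

        Closed bounds: a family diverged by exactly d sits on the edge of
        two bins and either neighbour counts as containing 100(1-d).
        """
        lo, up = self.peak_bounds
        return lo - _EPS <= value <= up + _EPS

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.labels, "count": self.counts})


def _bin_index(identity: float, width: float) -> int:
    """Index k such that identity lies in (100-(k+1)w, 100-kw]."""
    k = math.floor((100.0 - identity) / width + _EPS)
    return max(k, 0)


def _fmt(x: float) -> str:
    return f"{x:g}"


def identity_histogram(
    hits: list[CopyHit] | list[float],
    family: str = "family",
    bin_width: float = 1.0,
    top_k: int = 10,
) -> IdentityHistogram:
    """Histogram of copy identities on the descending 1-percent grid."""
    idents = [h.identity if isinstance(h, CopyHit) else float(h) for h in hits]
    if not idents:
        raise InputError("identity_histogram needs at least one copy")
    indices = [_bin_index(i, bin_width) for i in idents]
    kmax = max(indices)
    counts = [0] * (kmax + 1)
    for k in indices:
        counts[k] += 1
    labels = [
        f"{_fmt(100 - k * bin_width)}-{_fmt(100 - (k + 1) * bin_width)}"
        for k in range(kmax + 1)
    ]
    # peak: maximal count; ties break toward the older (larger-k) bin
    peak_k = max(range(kmax + 1), key=lambda k: (counts[k], k))
    k_eff = min(top_k, len(idents))
    top_mean = sum(sorted(idents, reverse=True)[:k_eff]) / k_eff
    return IdentityHistogram(
        family=family,
        bin_width=bin_width,
        labels=labels,
        counts=counts,
        peak_label=labels[peak_k],
        peak_bounds=(100 - (peak_k + 1) * bin_width, 100 - peak_k * bin_width),
        n=len(idents),
        top_k_mean=round(top_mean, 4),
    )


def top_copy_identity(hits: list[CopyHit] | list[float], k: int) -> float:
    """Mean identity of the k highest-identity copies."""
    idents = [h.identity if isinstance(h, CopyHit) else float(h) for h in hits]
    if len(idents) < k:
        raise InputError(f"need >= {k} hits, got {len(idents)}")
    return sum(sorted(idents, reverse=True)[:k]) / k


def concurrency_report(histograms: list[IdentityHistogram]) -> pd.DataFrame:
    """Family pairs whose identity peaks are within one bin of each other.

    Overlapping or adjacent peak bins indicate the two families were
    amplifying concurrently.
    """
    if len(histograms) < 2:
        raise InputError("concurrency_report needs >= 2 histograms")
    rows = []
    for i in range(len(histograms)):
        for j in range(i + 1, len(histograms)):
            a, b = histograms[i], histograms[j]
            dist = abs(a.peak_bounds[1] - b.peak_bounds[1]) / a.bin_width
            rows.append(
                {
                    "family_a": a.family,
                    "family_b": b.family,
                    "peak_a": a.peak_label,
                    "peak_b": b.peak_label,
                    "bin_distance": dist,
                    "concurrent": bool(dist <= 1),
                }
            )
    return pd.DataFrame(rows)
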