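"""Synthetic genome with planted chimeric SINE/LINE insertions.

Every downstream stage of the pipeline is exercised against genomes built
here, where each insertion carries a full ground-truth record: coordinates,
strand, the exact target-site duplication, realized divergence, 5'
truncation, and the number of appended microsatellite tail units.

The mutation model is substitution-only (each site independently replaced by
one of the three alternative bases with probability `divergence`); indels
are behind the `indel_rate` flag and off by default. Substitutions hit the
inserted element (including its microsatellite tail) but not the TSD copies
unless `mutate_tsd` is set, so TSD recovery has a clean upper bound.

Coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapacityError, InputError
from .util import decode, encode, revcomp

BASES = "ACGT"

#: donor role (FASTA `role=` metadata) -> segment role used in decomposition
ROLE_MAP = {
    "7SL": "head7SL",
    "tRNA": "headtRNA",
    "5S": "head5S",
    "body": "body",
    "LINE": "tailLINE",
}


@dataclass(frozen=True)
class SegmentPlan:
    donor: str
    start: int  # 1-based inclusive within the donor
    end: int
    role: str  # head7SL | headtRNA | head5S | body | tail


@dataclass
class FamilySpec:
    """A named consensus assembled from donor slices."""

    name: str
    consensus: str
    segments: list[SegmentPlan]
    tsd_length: int = 17
    tail_unit: str = "AAC"

    def __post_init__(self):
        if self.tsd_length < 0 or self.tsd_length > 50:
            raise InputError("tsd_length must be in 0..50")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "consensus": self.consensus,
            "tsd_length": self.tsd_length,
            "tail_unit": self.tail_unit,
            "segments": [
                {"donor": s.donor, "start": s.start, "end": s.end, "role": s.role}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FamilySpec":
        return cls(
            name=d["name"],
            consensus=d["consensus"],
            segments=[SegmentPlan(s["donor"], s["start"], s["end"], s["role"]) for s in d["segments"]],
            tsd_length=d["tsd_length"],
            tail_unit=d["tail_unit"],
        )


@dataclass
class InsertionTruth:
    family: str
    contig: str
    start: int  # 1-based inclusive, element body incl. microsatellite tail
    end: int
    strand: str
    tsd: str
    divergence: float  # substitutions per site actually applied
    truncation5: int  # bp removed from the 5' end of the consensus
    tail_repeats: int  # microsatellite units appended


def make_background(length: int, gc: float = 0.42, seed: int = 0) -> str:
    """I.i.d. random background sequence with expected GC content `gc`."""
    if length < 1000:
        raise InputError("background length must be >= 1000")
    if not 0 < gc < 1:
        raise InputError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return decode(codes)


def compose_chimera(
    donors: dict[str, str],
    plan: list[SegmentPlan],
    name: str = "chimera",
    tsd_length: int = 17,
    tail_unit: str = "AAC",
) -> FamilySpec:
    """Concatenate donor slices in plan order into a chimeric consensus."""
    parts = []
    for seg in plan:
        if seg.donor not in donors:
            raise InputError(f"unknown donor {seg.donor!r}")
        dseq = donors[seg.donor]
        if not (1 <= seg.start <= seg.end <= len(dseq)):
            raise InputError(
                f"interval {seg.start}..{seg.end} outside donor {seg.donor!r} (len {len(dseq)})"
            )
        parts.append(dseq[seg.start - 1 : seg.end])
    return FamilySpec(name, "".join(parts), list(plan), tsd_length, tail_unit)


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each site independently with probability `rate`.

    Returns the mutated sequence and the realized substitution count. A
    substituted site always changes (one of the three alternative bases).
    """
    if rate <= 0:
        return seq, 0
    codes = encode(seq).copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hit.size:
        shifts = rng.integers(1, 4, size=hit.size).astype(np.uint8)
        codes[hit] = (codes[hit] + shifts) % 4
    return decode(codes), int(hit.size)


def sample_copies(
    consensus: str, n: int, divergence: float, seed: int = 0
) -> tuple[list[str], list[int]]:
    """Mutated copies of a consensus (no genome context); truth = counts."""
    rng = np.random.default_rng(seed)
    copies, counts = [], []
    for _ in range(n):
        s, c = mutate_sequence(consensus, divergence, rng)
        copies.append(s)
        counts.append(c)
    return copies, counts


def plant_family(
    genome: str,
    spec: FamilySpec,
    n: int,
    divergence: float,
    trunc_prob: float = 0.2,
    seed: int = 0,
    contig: str = "chr1",
    tail_max_units: int = 15,
    min_keep: int = 30,
    mutate_tsd: bool = False,
    minus_strand: bool = False,
    indel_rate: float = 0.0,
) -> tuple[str, list[InsertionTruth]]:
    """Plant `n` chimeric insertions at random non-overlapping sites.

    Each insertion duplicates the `tsd_length` bp at the target site, then
    the element body (optionally 5'-truncated, with 0..`tail_max_units`
    tail-unit repeats appended) is mutated at per-site rate `divergence`.
    """
    if n < 0:
        raise InputError("n must be >= 0")
    if not 0 <= divergence < 0.3:
        raise InputError("divergence must be in [0, 0.3)")
    if n == 0:
        return genome, []
    rng = np.random.default_rng(seed)
    tsd_len = spec.tsd_length
    L = len(genome)
    spacing = 2 * tsd_len + 20
    lo, hi = tsd_len + 1, L - 2 * tsd_len - 1
    if hi <= lo or (hi - lo) // spacing < n:
        raise CapacityError(f"genome of {L} bp cannot host {n} insertions")
    sites: list[int] = []
    for _ in range(20):
        cand = np.sort(rng.integers(lo, hi, size=4 * n))
        picked: list[int] = []
        last = -(10**9)
        for x in cand:
            if x - last >= spacing:
                picked.append(int(x))
                last = int(x)
            if len(picked) == n:
                break
        if len(picked) == n:
            sites = picked
            break
    if len(sites) < n:
        raise CapacityError(f"could not place {n} non-overlapping insertions")

    pieces: list[str] = []
    truths: list[InsertionTruth] = []
    prev = 0  # 0-based index into the original genome
    shift = 0  # bases added so far
    unit = spec.tail_unit
    for x in sites:
        boundary = x + tsd_len - 1  # 0-based end (exclusive) of the left TSD
        tsd = genome[x - 1 : boundary] if tsd_len else ""
        core = spec.consensus
        trunc = 0
        if trunc_prob > 0 and len(core) > min_keep and rng.random() < trunc_prob:
            trunc = int(rng.integers(1, len(core) - min_keep + 1))
            core = core[trunc:]
        reps = int(rng.integers(0, tail_max_units + 1)) if unit else 0
        core = core + unit * reps
        core, n_sub = mutate_sequence(core, divergence, rng)
        if indel_rate > 0:
            core = _apply_indels(core, indel_rate, rng)
        strand = "+"
        element = core
        if minus_strand and rng.random() < 0.5:
            strand = "-"
            element = revcomp(core)
        pieces.append(genome[prev:boundary])
        pieces.append(element)
        start = boundary + shift + 1  # 1-based element start in the new genome
        truths.append(
            InsertionTruth(
                family=spec.name,
                contig=contig,
                start=start,
                end=start + len(element) - 1,
                strand=strand,
                tsd=tsd,
                divergence=n_sub / len(core) if core else 0.0,
                truncation5=trunc,
                tail_repeats=reps,
            )
        )
        shift += len(element) + tsd_len
        prev = boundary - tsd_len  # re-emit the target site downstream
    pieces.append(genome[prev:])
    new_genome = "".join(pieces)
    if mutate_tsd and divergence > 0:
        new_genome = _decay_tsds(new_genome, truths, tsd_len, divergence, rng)
    return new_genome, truths


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(ch)
        if rate / 2 <= r < rate:
            out.append(BASES[rng.integers(0, 4)])  # insertion
    return "".join(out)


def _decay_tsds(
    genome: str, truths: list[InsertionTruth], tsd_len: int, rate: float, rng
) -> str:
    chars = list(genome)
    for t in truths:
        for s, e in ((t.start - tsd_len - 1, t.start - 1), (t.end, t.end + tsd_len)):
            seg = "".join(chars[s:e])
            mutated, _ = mutate_sequence(seg, rate, rng)
            chars[s:e] = list(mutated)
    return "".join(chars)


# ---------------------------------------------------------------------------
# default study system: a 5-part chimera over a synthetic donor library
# ---------------------------------------------------------------------------


def make_donor_library(seed: int = 0) -> tuple[dict[str, str], dict[str, str]]:
    """Random donor sequences with role metadata.

    Returns (sequences, roles) where roles values are FASTA-style labels
    (7SL, tRNA, 5S, body, LINE) mapped to segment roles via ROLE_MAP.
    """
    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return "".join(BASES[i] for i in rng.integers(0, 4, size=n))

    seqs = {
        "7SL_syn": rand(300),
        "tRNA_syn": rand(75),
        "5S_syn": rand(120),
        "UCON3_syn": rand(180),
        "RTE_syn": rand(3000),
    }
    roles = {
        "7SL_syn": "7SL",
        "tRNA_syn": "tRNA",
        "5S_syn": "5S",
        "UCON3_syn": "body",
        "RTE_syn": "LINE",
    }
    return seqs, roles


def default_chimera_plan() -> list[SegmentPlan]:
    """Five-part architecture: 7SL head (two slices of one 7SL gene, the
    internal S-domain deleted), a conserved body domain, and a bipartite
    LINE-derived tail (5' UTR slice + 3' terminus of the same LINE)."""
    return [
        SegmentPlan("7SL_syn", 1, 96, "head7SL"),
        SegmentPlan("7SL_syn", 205, 248, "head7SL"),
        SegmentPlan("UCON3_syn", 30, 90, "body"),
        SegmentPlan("RTE_syn", 60, 126, "tail"),
        SegmentPlan("RTE_syn", 2952, 3000, "tail"),
    ]


def make_default_family(
    donors: dict[str, str],
    name: str = "SINE1-1_syn",
    tsd_length: int = 17,
    tail_unit: str = "AAC",
) -> FamilySpec:
    return compose_chimera(donors, default_chimera_plan(), name, tsd_length, tail_unit)
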