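#!/usr/bin/env python
"""Detect target-site duplications around the full-length copies found with
the refined consensus and profile their length distribution."""

from pathlib import Path

from sinekit import io as skio
from sinekit.mining import classify_full_length, extend_through_tail, mine_copies
from sinekit.tsd import detect_tsd, tsd_profile

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"
SIM = Path(__file__).resolve().parents[1] / "scratch" / "sim"
WINDOW = 50


def main() -> None:
    BASE.mkdir(parents=True, exist_ok=True)
    genome = skio.read_fasta(SIM / "genome.fa")["chr1"]
    spec = skio.family_spec_from_json(SIM / "family.json")
    consensus = next(iter(skio.read_fasta(BASE / "refined_consensus.fa").values()))

    hits = mine_copies(genome, consensus, spec.name, "chr1")
    for h in hits:
        h.full_length = classify_full_length(h, len(consensus))
    calls = []
    for h in (h for h in hits if h.full_length):
        end = extend_through_tail(genome, h.end, spec.tail_unit)
        left = genome[max(0, h.start - 1 - WINDOW) : h.start - 1]
        right = genome[end : end + WINDOW]
        if len(left) < 30 or len(right) < 30:
            continue
        call = detect_tsd(left, right)
        if call:
            call.copy_id = f"chr1:{h.start}-{h.end}"
            calls.append(call)
    skio.tsd_calls_to_tsv(calls, BASE / "tsd_calls.tsv")
    hist, modes = tsd_profile(calls)
    print(f"{len(calls)} TSD calls from {sum(h.full_length for h in hits)} full-length copies")
    print("length histogram:", hist)
    print(f"modal TSD length: {modes} (planted: {spec.tsd_length} bp)")
    print(f"calls -> {BASE / 'tsd_calls.tsv'}")


if __name__ == "__main__":
    main()
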