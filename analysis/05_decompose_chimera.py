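#!/usr/bin/env python
"""Tile the refined consensus against the donor library (7SL, tRNA, 5S,
body-domain, and LINE donors), resolve the segment tiling, and classify the
family's architecture and SINE class."""

from pathlib import Path

from sinekit import io as skio
from sinekit.chimera import classify_family, resolve_tiling, segment_against_library

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"
SIM = Path(__file__).resolve().parents[1] / "scratch" / "sim"


def main() -> None:
    BASE.mkdir(parents=True, exist_ok=True)
    consensus = next(iter(skio.read_fasta(BASE / "refined_consensus.fa").values()))
    donors, roles = skio.read_donor_library(SIM / "donors.fa")
    spec = skio.family_spec_from_json(SIM / "family.json")

    candidates = segment_against_library(consensus, donors, roles)
    tiling = resolve_tiling(candidates, consensus_len=len(consensus))
    arch = classify_family(tiling, spec.name, donors, len(consensus))
    skio.architecture_to_json(arch, BASE / "architecture.json")

    print(f"{len(candidates)} candidate segments -> {len(tiling)} tiled")
    for s in tiling:
        donor = s.donor or "-"
        print(
            f"  {s.cons_start:>4}..{s.cons_end:<4} {s.role:<10} {donor:<12} "
            f"donor {s.donor_start}..{s.donor_end} id {s.identity:.1f}%"
        )
    planted = "-".join(p.role if p.role != "tail" else "tailLINE" for p in spec.segments)
    print(f"architecture: {arch.roles}")
    print(f"planted plan: {planted}")
    print(f"class: {arch.sine_class}; bipartite LINE tail: {arch.bipartite_line_tail}")
    print(f"architecture -> {BASE / 'architecture.json'}")


if __name__ == "__main__":
    main()
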