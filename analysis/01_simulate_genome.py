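#!/usr/bin/env python
"""Simulate the study system: a 500 kb background genome carrying 60 copies
of a 5-part chimeric SINE (7SL-derived head in two slices, a conserved body
domain, a bipartite LINE-derived tail) at 3.5% divergence, 17-bp TSDs, and
0-15 AAC tail units per copy. Writes the genome, donor library, seed
consensus, and full ground truth under results/analysis/sim/."""

from pathlib import Path

from sinekit import io as skio
from sinekit.synthetic import (
    make_background,
    make_default_family,
    make_donor_library,
    plant_family,
)

SEED = 20260919
OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    donors, roles = make_donor_library(seed=SEED)
    spec = make_default_family(donors, tsd_length=17)
    genome = make_background(500_000, gc=0.42, seed=SEED + 1)
    genome, truths = plant_family(
        genome, spec, n=60, divergence=0.035, trunc_prob=0.2, seed=SEED + 2
    )
    skio.write_fasta({"chr1": genome}, OUT / "genome.fa")
    skio.write_donor_library(donors, roles, OUT / "donors.fa")
    skio.write_fasta({spec.name: spec.consensus}, OUT / "seeds.fa")
    skio.family_spec_to_json(spec, OUT / "family.json")
    skio.truths_to_bed(truths, OUT / "truth.bed")
    skio.truths_to_tsv(truths, OUT / "truth.tsv")

    n_trunc = sum(t.truncation5 > 0 for t in truths)
    print(f"genome: {len(genome)} bp, consensus: {len(spec.consensus)} bp")
    print(f"planted {len(truths)} copies ({n_trunc} 5'-truncated), TSD 17 bp")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
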