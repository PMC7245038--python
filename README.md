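# sinekit

Characterization of chimeric SINE families: consensus refinement from
genomic copies, target-site-duplication (TSD) profiling, head/body/tail
decomposition against a donor library, identity-based age profiling, and
secondary-structure comparison of 7SL-derived heads.

## Who this is for

Short interspersed elements (SINEs) are non-autonomous retrotransposons
assembled from parts of other sequences: a small-RNA-derived **head**
carrying the RNA polymerase III internal promoter (7SL RNA → SINE1,
tRNA → SINE2, 5S rRNA → SINE3), an optional deeply conserved **body**
domain, and a LINE-derived **tail** recognized by the partner
retrotransposon's machinery. Curating such a family from a genome assembly
means: finding the copies, rebuilding a clean consensus, working out which
donor each piece came from, measuring the TSDs its integration leaves
behind, and dating the family from its copy-divergence distribution.
`sinekit` implements that workflow as a tested library + CLI, and ships a
synthetic-genome generator that plants chimeric insertions with full ground
truth so every stage can be validated end to end.

## The core procedures

- **Consensus refinement** — the top-N (default 10) highest-scoring
  genomic copies are extracted with 1000-bp flanks, multiply aligned
  (center-star, affine-gap pairwise aligner), and the element boundaries
  are called where per-column support ≥ 0.7 and gap fraction ≤ 0.5; the
  majority-rule consensus of that region, with the 3′ microsatellite
  (e.g. `(AAC)n`) trimmed, is the refined family consensus.
- **TSD detection** — the best-scoring direct-repeat pair
  (suffix of the left flank, prefix of the right flank) within 5 bp of the
  element boundaries, scored `length − 2·mismatches`, defaults
  `min_len 6`, `max_mismatch 2`.
- **Chimera decomposition** — Smith–Waterman segmentation of the consensus
  against a role-annotated donor library (both strands), resolved to a
  maximum-score tiling by weighted interval scheduling (≤ 10 bp junction
  overlap tolerated); the SINE class follows from the 5′-most head segment,
  and a bipartite LINE tail (5′ UTR slice + 3′ terminus of one donor) is
  flagged.
- **Age profiling** — copy-to-consensus identity histogram on descending
  1% bins labeled `"97-96"` style; the peak bin is the family's relative
  age, and families whose peaks are within one bin are reported as
  concurrently active.
- **Structure comparison** — a reference secondary structure (dot-bracket,
  supplied as input) is mapped through an alignment onto a homolog and each
  base pair is classified as conserved / compensatory / wobble-preserving /
  half-broken / broken / deleted; pol III A/B promoter boxes are located by
  Hamming distance to canonical motifs.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
genome (bulky intermediates under `scratch/`, tables under
`results/analysis/`):

```sh
python analysis/01_simulate_genome.py   # 500 kb genome, 60 planted copies
python analysis/02_mine_copies.py       # mining from a corrupted draft seed
python analysis/03_refine_consensus.py  # top-10 + 1000 bp flank refinement
python analysis/04_tsd_profile.py
python analysis/05_decompose_chimera.py
python analysis/06_age_profile.py
python analysis/07_structure_comparison.py
```

`03_refine_consensus.py` prints:

```
element boundaries in MSA columns: (1368, 1734)
trimmed 12 microsatellite units from the 3' end
draft seed identity to truth:   97.16%
refined consensus identity:     100.00% (317 bp)
```

i.e. starting from a draft consensus carrying 9 errors, refinement over the
ten best flanked copies recovers the planted 317-bp consensus exactly.
`04_tsd_profile.py` reports the modal TSD length 17 bp (the planted value;
45 calls, 38 of them exactly 17), and `05_decompose_chimera.py` recovers
the planted five-part architecture:

```
architecture: head7SL-head7SL-body-tailLINE-tailLINE
class: SINE1; bipartite LINE tail: True
```

The same pipeline is available as a CLI
(`sinekit simulate | mine | consensus | tsd | decompose | age | structure |
characterize`), e.g.:

```sh
sinekit simulate --length 200000 --n-copies 30 --seed 5 --outdir sim/
sinekit characterize --genome sim/genome.fa --seeds sim/seeds.fa \
    --donors sim/donors.fa --outdir out/
```

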