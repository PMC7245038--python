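# Methods

## Scope and model

`sinekit` characterizes chimeric SINE families against a genome where the
truth is known by construction. The package treats a SINE family as a
consensus sequence assembled from donor slices (head / body / tail), whose
genomic copies are independent, decayed snapshots of that consensus:
each copy may be 5′-truncated, carries a 3′ microsatellite tail of variable
length, is flanked by an exact target-site duplication (TSD) created at
integration, and has accumulated substitutions since. All coordinates are
1-based inclusive internally; BED output is converted to 0-based half-open
at the file boundary.

## Synthetic genome generator

`make_background` draws i.i.d. bases at a configurable GC content
(default 0.42, a typical vertebrate bulk value). `plant_family` inserts
`n` copies at uniformly random, non-overlapping sites. Insertion mechanics:
the `tsd_length` bp at the target site are duplicated, the element
(consensus, optionally truncated, plus 0–15 tail units, default unit
`AAC`) is placed between the two copies, and substitutions are then applied
i.i.d. at the requested per-site rate to the element *including its tail*
but not to the TSD copies — so TSD recovery has a clean upper bound
(`mutate_tsd` enables TSD decay for robustness experiments). A substituted
site always changes, to one of the three alternative bases uniformly
(Jukes–Cantor-like); expected copy identity is therefore exactly
100·(1−d). Indels are behind `indel_rate` and off by default; insertions
are placed on the + strand by default (`minus_strand` randomizes strands;
downstream code handles − strand hits regardless).

Default per-copy decay: truncation probability 0.2 with the truncation
length uniform over the element (the truncation-length distribution of
real SINE copies is not well constrained; uniform is a deliberate modeling
choice), and tail length uniform over 0–15 units.

What the generator does **not** emulate: realistic genome composition
(repeat landscapes, GC isochores, pre-existing repeats), nested or
overlapping insertions, transductions, CpG-accelerated decay, and
insertion-site preference. Passing tests therefore demonstrate the
pipeline's correctness under idealized decay, not its robustness to every
property of real assemblies.

## Alignment engine

All identities flow through one pairwise affine-gap aligner
(Gotoh; numba-jitted kernels with a pure-Python fallback). Scoring
defaults: match +1, mismatch −1, gap open −5, gap extend −1 (a gap of
length k costs −5 −(k−1)); chosen to favor long contiguous repeat
alignments. **Identity is the percentage of matching columns among
aligned, gap-free columns** — the common TE-annotation convention — and
this definition is load-bearing for every percentage the pipeline reports.
`N` never matches (conservative identity). Traceback ties prefer
diagonal > up > left, making output deterministic. `local_align` returns
multiple non-overlapping hits by iteratively masking the query interval of
the best hit and realigning, on both strands.

The multiple aligner is center-star: the sequence with the largest summed
k-mer similarity is the center, every other row is globally aligned to it,
and gap patterns merge under once-a-gap-always-a-gap. This is crude next
to profile HMM aligners, but for ≤ ~20 rows of 70–97% identity (the
refinement regime) column majorities are unaffected.

## Copy mining

Seed-and-extend: exact 12-mer matches between consensus and contig
(both strands) are clustered by diagonal; each candidate window is
verified by local alignment of the consensus against the window. At 10%
divergence an exact 12-mer survives with probability 0.9¹² ≈ 0.28, i.e.
one expected seed every ~4 bp of consensus, so recall is seed-limited only
for extremely decayed or very short fragments. Hits below 80% identity or
50 aligned bp are dropped; overlapping same-strand hits collapse to the
higher score; hits touching a contig end are discarded (downstream stages
need flanks).

Full-length calls require consensus coverage starting within 5 bp of
position 1 and spanning ≥ 95% of the consensus. This is an explicit
operationalization — the classical literature rarely states its criterion
— and both thresholds are parameters.

## Consensus refinement and boundary calling

Top 10 hits by score, each with 1000 bp flanks (clipped at contig ends,
− strand rows reverse-complemented), are star-aligned. Only columns with
gap fraction ≤ 0.5 are considered (high-gap insertion columns are MSA
artifacts that the consensus never emits, so they must not interrupt the
element run). Per-column support (plurality-base frequency among non-gap
rows; ties alphabetical) is smoothed over a 10-column window; the maximal
run with smoothed support ≥ 0.7 is the element if it spans ≥ 30 columns.
Each edge is then anchored on 5 consecutive raw-support columns and walked
outward — without the anchor, one or two coincidentally concordant flank
columns adjacent to the element drag the boundary outward. Thresholds are
set so 10 unrelated flank rows (expected support ≈ 0.4, inflated somewhat
by alignment jiggle) sit far below 0.7. Finally the 3′ microsatellite run
(≥ 3 units, trailing partial allowed) is trimmed from the consensus:
copies carry tails of variable length, and leaked tail columns
desynchronize hit ends and TSD boundaries.

## TSD detection

For each full-length copy the hit end is first advanced through the
genomic tail (unit-by-unit, ≤ 1 substitution per unit confirmed by an
exact following unit, ≤ 2 such units total; a short non-unit remnant can
be skipped when two exact units follow; trailing partial units are *not*
consumed — tails grow in whole units, and eating a look-alike partial
truncates the start of the downstream TSD). Detection then scans all
(left-flank suffix substring, right-flank prefix substring) pairs whose
ends lie within 5 bp of the element boundaries, keeping the pair
maximizing `length − 2·mismatches` (≥ 6 bp, ≤ 2 mismatches), ties to the
smallest summed offset, then the longer repeat. The scan is exhaustive
within its constraints, so it coincides with a brute-force oracle by
construction — the suite verifies that on independently generated cases.
On unrelated 100-bp flanks with `min_len` 10 the false-call rate is under
5% (measured over 1000 trials in the suite).

## Chimera decomposition

Candidate segments (local hits ≥ 65% identity, ≥ 25 bp, both strands, per
donor) are resolved by weighted interval scheduling maximizing summed
alignment score, tolerating ≤ 10 bp overlap at junctions — homology-defined
breakpoints are fuzzy, and real published segment pairs overlap by tens of
bp. Uncovered gaps ≥ 25 bp are reported as `unassigned`. Donor roles
(7SL / tRNA / 5S / body / LINE) are user metadata in FASTA headers, never
inferred. Class: SINE1/2/3 from the role of the 5′-most assigned segment;
`non-SINE` when a single LINE-derived segment covers ≥ 90%; otherwise
`unclassified`. Two tail segments from one LINE donor — one inside its 5′
half, one reaching within 50 bp of its 3′ terminus — set the
bipartite-tail flag (the signature of internally deleted non-autonomous
RTE derivatives).

## Age profiling

Copy identities are binned on a descending 1% grid, bins `(lower, upper]`
labeled `"upper-lower"` (an identity of exactly 97 falls in `"97-96"`).
Peak ties break toward the lower-identity (older) bin — a conservative age
estimate. `peak_contains` uses closed bounds: a family diverged by exactly
d sits on the edge between two bins, and either neighbour legitimately
contains 100·(1−d). Identities are raw and gap-excluded; no Kimura or CpG
correction is applied (out of scope). Families whose peak bins are within
one bin are flagged concurrently active.

## Structure comparison

Reference structures are inputs (dot-bracket; `[]` allowed as a second
tier, e.g. loop–loop tertiary pairs); no thermodynamic folding is
performed. Pairs are mapped through a reference-to-homolog alignment; a
pair losing either partner to a gap is `deleted`. For mapped pairs, with
T≡U: both bases identical → `conserved`; query pair G·U (one or both
changed) → `wobble-preserving`, as is a single change landing on any
canonical pair; both changed onto a Watson–Crick pair → `compensatory`
(G·U is deliberately excluded here — only full Watson–Crick restorations
count as compensatory); single change losing pairing → `half-broken`;
double change losing pairing → `broken`. The categories partition mapped
pairs, which the suite checks by full enumeration of base combinations.
Promoter boxes are located by minimum Hamming distance to canonical A/B
motifs within ±10 bp of their expected starts (6 and 76 in human 7SL
numbering); ties go to the expected position.

## Problem sizes and determinism

The bundled analysis runs a 500 kb genome with 60 copies at 3.5%
divergence; the acceptance script runs the round trip at 2 Mb with 100
copies at 3% divergence and 17-bp TSDs, dating recovery at 500 copies ×
10 seeds × 3 divergence levels, and a 100-copy young family — sizes chosen
so the full reproduction completes in about a minute on a single core
while keeping binomial noise on identity (~1% sd at 300 bp) well inside
the tested tolerances. Everything downstream of the generator is
deterministic; generator outputs are byte-reproducible given a seed.

## Known limitations

- Substitution-only decay by default; alignment around real indels is
  exercised only via the structure-mapping path and the optional
  `indel_rate`.
- The center-star MSA can misplace a few columns at element/flank
  junctions (hence the anchored boundary refinement); boundaries are
  guaranteed only to ±3 columns at 0% divergence, ±10 at 5%.
- Segmentation cannot see donors absent from the supplied library, and
  role metadata is trusted, not verified.
- Identity-based dating is relative; no substitution-rate calibration to
  absolute time is attempted.
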