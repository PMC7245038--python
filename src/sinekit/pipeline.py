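"""End-to-end orchestration: mine -> refine -> re-mine -> TSD -> decompose
-> age, per seed family, with deterministic report files.

`run_characterize` consumes a config mapping (the CLI builds one from
flags) naming a genome, seed consensi, and a donor library — either as
file paths or as in-memory objects. Every stage's defaults can be
overridden through the `params` sub-mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import io as skio
from .age import IdentityHistogram, identity_histogram, top_copy_identity
from .chimera import (
    Architecture,
    classify_family,
    resolve_tiling,
    segment_against_library,
)
from .errors import ConfigError, InsufficientCopiesError, NoElementError
from .mining import (
    CopyHit,
    classify_full_length,
    extend_through_tail,
    mine_copies,
    trim_tail_microsatellite,
)
from .refine import RefinedConsensus, refine_consensus
from .tsd import TSDCall, detect_tsd, tsd_profile

log = logging.getLogger("sinekit")

DEFAULT_PARAMS: dict[str, Any] = {
    "min_identity": 80.0,
    "min_len": 50,
    "top_n": 10,
    "flank": 1000,
    "tsd_min_len": 6,
    "tsd_max_mismatch": 2,
    "tsd_max_offset": 5,
    "tsd_flank_window": 50,
    "bin_width": 1.0,
    "seg_min_identity": 65.0,
    "seg_min_len": 25,
    "tail_unit": "AAC",
    "tail_min_units": 3,
    "full_length_start_tol": 5,
    "full_length_min_cov": 0.95,
}


@dataclass
class FamilyReport:
    family: str
    refined: RefinedConsensus | None
    hits: list[CopyHit]
    n_copies: int
    n_full_length: int
    tsd_calls: list[TSDCall]
    tsd_hist: dict[int, int]
    tsd_modes: tuple[int, ...]
    architecture: Architecture | None
    histogram: IdentityHistogram | None
    top10_identity: float | None
    status: str = "ok"


@dataclass
class ReportBundle:
    families: list[FamilyReport] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (family, reason)


def _require(config: dict, key: str):
    if key not in config or config[key] is None:
        raise ConfigError(key)
    return config[key]


def _load_genome(config: dict) -> dict[str, str]:
    g = _require(config, "genome")
    if isinstance(g, (str, Path)):
        return skio.read_fasta(g)
    return dict(g)


def _load_seeds(config: dict) -> dict[str, str]:
    s = _require(config, "seeds")
    if isinstance(s, (str, Path)):
        return skio.read_fasta(s)
    return dict(s)


def _load_donors(config: dict) -> tuple[dict[str, str], dict[str, str]]:
    d = _require(config, "donors")
    if isinstance(d, (str, Path)):
        return skio.read_donor_library(d)
    seqs, roles = d
    return dict(seqs), dict(roles)


def characterize_family(
    genome: dict[str, str],
    family: str,
    seed_consensus: str,
    donors: dict[str, str],
    donor_roles: dict[str, str],
    params: dict[str, Any],
) -> FamilyReport:
    p = {**DEFAULT_PARAMS, **params}
    log.info("family %s: mining with %d-bp seed consensus", family, len(seed_consensus))
    hits: list[CopyHit] = []
    for contig, seq in genome.items():
        hits.extend(
            mine_copies(
                seq, seed_consensus, family=family, contig=contig,
                min_identity=p["min_identity"], min_len=p["min_len"],
            )
        )
    hits.sort(key=lambda h: (-h.score, h.contig, h.start))
    if len(hits) < 2:
        raise InsufficientCopiesError(f"{family}: {len(hits)} hits")

    # refinement runs on the contig holding the most top hits; flanked rows
    # must come from a single sequence
    refined = None
    for contig in sorted(genome, key=lambda c: -sum(h.contig == c for h in hits[: p["top_n"]])):
        chits = [h for h in hits if h.contig == contig]
        if len(chits) >= 2:
            refined = refine_consensus(
                genome[contig], chits, top_n=p["top_n"], flank=p["flank"]
            )
            break
    if refined is None:
        raise InsufficientCopiesError(f"{family}: no contig with >= 2 hits")
    # exclude the 3' microsatellite from the family consensus: copies carry
    # tails of variable length, so leaked tail columns desynchronize hit
    # ends and downstream TSD boundaries
    consensus, _ = trim_tail_microsatellite(
        refined.consensus, p["tail_unit"], p["tail_min_units"]
    )
    refined.consensus = consensus
    log.info("family %s: refined consensus %d bp", family, len(consensus))

    hits = []
    for contig, seq in genome.items():
        hits.extend(
            mine_copies(
                seq, consensus, family=family, contig=contig,
                min_identity=p["min_identity"], min_len=p["min_len"],
            )
        )
    hits.sort(key=lambda h: (-h.score, h.contig, h.start))
    for h in hits:
        h.full_length = classify_full_length(
            h, len(consensus), p["full_length_start_tol"], p["full_length_min_cov"]
        )
    full = [h for h in hits if h.full_length]

    calls: list[TSDCall] = []
    w = p["tsd_flank_window"]
    for idx, h in enumerate(full):
        seq = genome[h.contig]
        end = extend_through_tail(seq, h.end, p["tail_unit"])
        left = seq[max(0, h.start - 1 - w) : h.start - 1]
        right = seq[end : end + w]
        if len(left) < 30 or len(right) < 30:
            continue
        call = detect_tsd(
            left, right, p["tsd_min_len"], p["tsd_max_mismatch"], p["tsd_max_offset"]
        )
        if call:
            call.copy_id = f"{h.contig}:{h.start}-{h.end}"
            calls.append(call)
    tsd_hist, tsd_modes = tsd_profile(calls) if calls else ({}, ())

    candidates = segment_against_library(
        consensus, donors, donor_roles,
        min_identity=p["seg_min_identity"], min_seg_len=p["seg_min_len"],
    )
    tiling = resolve_tiling(
        candidates, min_gap_report=p["seg_min_len"], consensus_len=len(consensus)
    )
    arch = (
        classify_family(tiling, family, donors, len(consensus))
        if any(s.role != "unassigned" for s in tiling)
        else Architecture(family, "", "unclassified", False, tiling)
    )

    hist = identity_histogram(hits, family, p["bin_width"]) if hits else None
    top10 = top_copy_identity(hits, min(10, len(hits))) if hits else None
    return FamilyReport(
        family=family,
        refined=refined,
        hits=hits,
        n_copies=len(hits),
        n_full_length=len(full),
        tsd_calls=calls,
        tsd_hist=tsd_hist,
        tsd_modes=tsd_modes,
        architecture=arch,
        histogram=hist,
        top10_identity=top10,
    )


def run_characterize(config: dict) -> ReportBundle:
    """Characterize every seed family against a genome and donor library.

    Config keys: genome, seeds, donors (paths or objects); optional outdir,
    params, write_plots.
    """
    genome = _load_genome(config)
    seeds = _load_seeds(config)
    donors, donor_roles = _load_donors(config)
    params = config.get("params", {})
    outdir = config.get("outdir")
    bundle = ReportBundle()
    for family, seed in seeds.items():
        try:
            rep = characterize_family(genome, family, seed, donors, donor_roles, params)
        except (InsufficientCopiesError, NoElementError) as exc:
            log.warning("family %s skipped: %s", family, exc)
            bundle.skipped.append((family, str(exc)))
            continue
        bundle.families.append(rep)
        if outdir:
            _write_family_outputs(rep, Path(outdir), bool(config.get("write_plots")))
    return bundle


def _write_family_outputs(rep: FamilyReport, outdir: Path, plots: bool) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    fam = rep.family
    skio.write_fasta({fam: rep.refined.consensus}, outdir / f"{fam}.consensus.fa")
    skio.hits_to_tsv(rep.hits, outdir / f"{fam}.copies.tsv")
    skio.hits_to_bed(rep.hits, outdir / f"{fam}.copies.bed")
    skio.tsd_calls_to_tsv(rep.tsd_calls, outdir / f"{fam}.tsd.tsv")
    if rep.architecture:
        skio.architecture_to_json(rep.architecture, outdir / f"{fam}.architecture.json")
    if rep.histogram:
        rep.histogram.as_frame().to_csv(outdir / f"{fam}.identity_hist.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"length": k, "count": v} for k, v in sorted(rep.tsd_hist.items())]
    ).to_csv(outdir / f"{fam}.tsd_hist.tsv", sep="\t", index=False)
    if plots and rep.histogram:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(range(len(rep.histogram.counts)), rep.histogram.counts)
        ax.set_xticks(range(len(rep.histogram.labels)))
        ax.set_xticklabels(rep.histogram.labels, rotation=90, fontsize=6)
        ax.set_ylabel("copies")
        ax.set_title(f"{fam} identity distribution")
        fig.tight_layout()
        fig.savefig(outdir / f"{fam}.identity_hist.png", dpi=120)
        plt.close(fig)
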