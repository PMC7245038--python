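"""File-format boundary: FASTA, BED6, TSV, JSON, dot-bracket, Stockholm.

Internal coordinates are 1-based inclusive; BED on disk is 0-based
half-open and converted here. Donor FASTA headers carry `role=` key-value
metadata (e.g. ">RTE_syn role=LINE").
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chimera import Architecture
from .mining import CopyHit
from .synthetic import FamilySpec, InsertionTruth
from .tsd import TSDCall


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description=(descriptions or {}).get(name, ""))
        for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_donor_library(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Donor sequences plus their `role=` metadata."""
    seqs, roles = {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        for token in rec.description.split():
            if token.startswith("role="):
                roles[rec.id] = token.split("=", 1)[1]
    return seqs, roles


def write_donor_library(seqs: dict[str, str], roles: dict[str, str], path: str | Path) -> None:
    write_fasta(seqs, path, descriptions={k: f"role={roles.get(k, 'unknown')}" for k in seqs})


# -- ground truth ------------------------------------------------------------


def truths_to_bed(truths: list[InsertionTruth], path: str | Path) -> None:
    """BED6 (0-based half-open) of planted elements."""
    with open(path, "w") as fh:
        for k, t in enumerate(truths):
            fh.write(
                f"{t.contig}\t{t.start - 1}\t{t.end}\t{t.family}|{k}\t0\t{t.strand}\n"
            )


def truths_to_tsv(truths: list[InsertionTruth], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "family": t.family,
                "contig": t.contig,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "tsd": t.tsd,
                "divergence": round(t.divergence, 6),
                "truncation5": t.truncation5,
                "tail_repeats": t.tail_repeats,
            }
            for t in truths
        ]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[InsertionTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        InsertionTruth(
            family=r.family,
            contig=r.contig,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            tsd=str(r.tsd),
            divergence=float(r.divergence),
            truncation5=int(r.truncation5),
            tail_repeats=int(r.tail_repeats),
        )
        for r in df.itertuples()
    ]


def family_spec_to_json(spec: FamilySpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2) + "\n")


def family_spec_from_json(path: str | Path) -> FamilySpec:
    return FamilySpec.from_dict(json.loads(Path(path).read_text()))


# -- pipeline tables ---------------------------------------------------------


def hits_to_tsv(hits: list[CopyHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "family": h.family,
                "contig": h.contig,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "score": h.score,
                "identity": round(h.identity, 3),
                "cons_start": h.cons_start,
                "cons_end": h.cons_end,
                "full_length": h.full_length,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def hits_to_bed(hits: list[CopyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start - 1}\t{h.end}\t{h.family}\t{h.score}\t{h.strand}\n"
            )


def tsd_calls_to_tsv(calls: list[TSDCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "copy_id": c.copy_id,
                "length": c.length,
                "mismatches": c.mismatches,
                "left_seq": c.left_seq,
                "right_seq": c.right_seq,
                "offset_left": c.offset_left,
                "offset_right": c.offset_right,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def architecture_to_json(arch: Architecture, path: str | Path) -> None:
    Path(path).write_text(json.dumps(arch.to_dict(), indent=2) + "\n")


def msa_to_stockholm(msa: list[str], names: list[str], path: str | Path) -> None:
    width = max(len(n) for n in names) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for name, row in zip(names, msa):
            fh.write(f"{name:<{width}}{row}\n")
        fh.write("//\n")
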