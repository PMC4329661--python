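"""File I/O: FASTA/FASTQ read sets, genomes, ground truth, assignment tables.

Sequence formats go through Bio.SeqIO; tabular formats through pandas.
BLAST tabular (outfmt 6) parsing lives in :mod:`metacompare.recruitment`
next to the alignment types it produces.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .community import RANKS, Genome, Read, ReadSet

#: uniform Phred quality written to simulated FASTQ (Q30)
FASTQ_QUALITY = 30


def _read_records(reads):
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        yield rec, r


def write_fasta(readset: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for rec, _ in _read_records(readset.reads):
            SeqIO.write(rec, fh, "fasta")


def write_fastq(readset: ReadSet, path, quality: int = FASTQ_QUALITY) -> None:
    with open(path, "w") as fh:
        for rec, r in _read_records(readset.reads):
            rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
            SeqIO.write(rec, fh, "fastq")


def read_reads(path, sample_id: str | None = None) -> ReadSet:
    """Load a FASTA or FASTQ file (by extension) as a ReadSet."""
    fmt = "fastq" if str(path).lower().endswith(("fastq", "fq")) else "fasta"
    reads = [Read(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(path, fmt)]
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ReadSet(sample_id=sample_id, reads=reads)


def write_genomes_fasta(genomes, path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            SeqIO.write(SeqRecord(Seq(g.sequence), id=g.id, description=""), fh, "fasta")


def read_genomes_fasta(path, taxonomy: dict | None = None) -> list:
    """Load a multi-FASTA of reference genomes; optional id→lineage map."""
    taxonomy = taxonomy or {}
    return [
        Genome(id=rec.id, sequence=str(rec.seq), taxon_lineage=dict(taxonomy.get(rec.id, {})))
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_truth_tsv(readset: ReadSet, path) -> None:
    """Ground-truth provenance table: read_id, truth_genome, truth_start, is_duplicate_of."""
    df = pd.DataFrame(
        {
            "read_id": [r.id for r in readset.reads],
            "truth_genome": [r.truth_genome or "" for r in readset.reads],
            "truth_start": [r.truth_start if r.truth_start is not None else -1 for r in readset.reads],
            "is_duplicate_of": [r.is_duplicate_of or "" for r in readset.reads],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str}, keep_default_na=False)


def write_taxonomy_tsv(genomes, path) -> None:
    """Genome taxonomy table: genome_id plus one column per rank."""
    rows = []
    for g in genomes:
        row = {"genome_id": g.id}
        row.update({rank: g.taxon_lineage.get(rank, "") for rank in RANKS})
        rows.append(row)
    pd.DataFrame(rows, columns=["genome_id", *RANKS]).to_csv(path, sep="\t", index=False)


def read_taxonomy_tsv(path) -> dict:
    """Load a taxonomy table as {genome_id: {rank: name}} (empty cells dropped)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        out[row["genome_id"]] = {
            rank: row[rank] for rank in RANKS if rank in df.columns and row[rank]
        }
    return out
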