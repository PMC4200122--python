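"""Readers and writers for the pipeline's tabular and sequence formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrich import HomologyHit
from .quantify import LIBRARIES, ExpressionMatrix

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_counts_tsv(path) -> ExpressionMatrix:
    """Counts TSV with header: transcript_id, length, silk, venom, cephalothorax."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", *LIBRARIES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.set_index("transcript_id")
    lengths = df["length"] if "length" in df.columns else None
    return ExpressionMatrix(counts=df[list(LIBRARIES)].astype(float), lengths=lengths)


def write_counts_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.counts.copy()
    if matrix.lengths is not None:
        df.insert(0, "length", matrix.lengths)
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq_pairs(path1, path2):
    """Paired FASTQ (Phred+33) as silkshift ReadPair records."""
    from .preprocess import ReadPair

    pairs = []
    for r1, r2 in zip(SeqIO.parse(str(path1), "fastq"), SeqIO.parse(str(path2), "fastq")):
        pairs.append(
            ReadPair(
                read_id=r1.id,
                seq1=str(r1.seq),
                qual1=tuple(r1.letter_annotations["phred_quality"]),
                seq2=str(r2.seq),
                qual2=tuple(r2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def write_fastq_pairs(pairs, path1, path2) -> None:
    recs1, recs2 = [], []
    for p in pairs:
        r1 = SeqRecord(Seq(p.seq1), id=p.read_id, description="")
        r1.letter_annotations["phred_quality"] = list(p.qual1)
        r2 = SeqRecord(Seq(p.seq2), id=p.read_id, description="")
        r2.letter_annotations["phred_quality"] = list(p.qual2)
        recs1.append(r1)
        recs2.append(r2)
    SeqIO.write(recs1, str(path1), "fastq")
    SeqIO.write(recs2, str(path2), "fastq")


def read_hits_tsv(path) -> dict[str, list[HomologyHit]]:
    """BLAST outfmt-6-like TSV, with optional trailing ``taxon`` and ``db`` columns.

    Query coordinates are converted from 1-based inclusive (BLAST convention)
    to 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    ncol = df.shape[1]
    cols = OUTFMT6_COLUMNS + ["taxon", "db"][: max(0, ncol - 12)]
    df.columns = cols[:ncol]
    hits: dict[str, list[HomologyHit]] = {}
    for row in df.itertuples(index=False):
        qstart, qend = int(row.qstart), int(row.qend)
        if qstart > qend:
            qstart, qend = qend, qstart
        hit = HomologyHit(
            query=str(row.qseqid),
            subject=str(row.sseqid),
            evalue=float(row.evalue),
            bitscore=float(row.bitscore),
            qstart=qstart - 1,
            qend=qend,
            taxon=str(row.taxon) if "taxon" in df.columns and pd.notna(row.taxon) else None,
            database=str(row.db) if "db" in df.columns and pd.notna(row.db) else None,
        )
        hits.setdefault(hit.query, []).append(hit)
    return hits


def read_go_map(path) -> dict[str, set[str]]:
    """Two-column TSV (transcript_id, term) to per-transcript term sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "term"])
    out: dict[str, set[str]] = {}
    for t, term in zip(df["transcript_id"], df["term"]):
        out.setdefault(str(t), set()).add(str(term))
    return out


def read_slim_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "slim_term"])
    return dict(zip(df["term"].astype(str), df["slim_term"].astype(str)))


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
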