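"""Readers and writers for the file formats the pipeline touches.

FASTA goes through Bio.SeqIO; tabular formats through pandas. GFF3 is
parsed with a small column/attribute reader covering the subset consumed
here (CDS/gene/tRNA rows carrying a ``product`` attribute).

Coordinate convention: every reader converts to 0-based half-open at the
boundary; every writer converts back to the format's native convention
(GFF3 and BLAST tabular: 1-based inclusive).
"""

from __future__ import annotations

import urllib.parse
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ContigRecord,
    GeneAnnotation,
    MdaRecord,
    RecruitmentHit,
    TranscriptHit,
)

_ACGTN = set("ACGTN")

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _normalize_sequence(seq: str) -> str:
    seq = seq.upper()
    if set(seq) <= _ACGTN:
        return seq
    return "".join(c if c in _ACGTN else "N" for c in seq)


def read_contigs(fasta_path: str | Path, sag_id: str = "") -> list[ContigRecord]:
    """Read a FASTA assembly into :class:`ContigRecord` objects.

    Sequences are uppercased and non-ACGTN characters collapsed to N.
    Duplicate contig ids raise; an empty file warns and returns [].
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        records.append(
            ContigRecord(rec.id, _normalize_sequence(str(rec.seq)), sag_id=sag_id)
        )
    if not records:
        warnings.warn(f"no FASTA records in {fasta_path}", stacklevel=2)
    return records


def write_contigs(records: Iterable[ContigRecord], fasta_path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.contig_id, description="") for r in records]
    SeqIO.write(seqs, str(fasta_path), "fasta")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item or "=" not in item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = urllib.parse.unquote(value.strip())
    return out


def read_annotations(gff_path: str | Path) -> list[GeneAnnotation]:
    """Read gene/CDS and tRNA features from GFF3.

    CDS/gene rows become feature_kind="gene"; tRNA rows feature_kind="tRNA".
    Rows of other types are skipped. Coordinates converted from GFF3's
    1-based inclusive to 0-based half-open.
    """
    feats: list[GeneAnnotation] = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype in ("CDS", "gene"):
                kind = "gene"
            elif ftype == "tRNA":
                kind = "tRNA"
            else:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{gff_path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise ValueError(f"{gff_path}:{lineno}: start {start} > end {end}")
            if strand not in ("+", "-"):
                raise ValueError(f"{gff_path}:{lineno}: unknown strand {strand!r}")
            attributes = _parse_gff_attributes(attrs)
            feats.append(
                GeneAnnotation(
                    contig_id=seqid,
                    start=start - 1,
                    end=end,
                    strand=strand,
                    feature_kind=kind,
                    product=attributes.get("product", ""),
                    gene_id=attributes.get("ID", ""),
                )
            )
    return feats


def write_annotations(features: Iterable[GeneAnnotation], gff_path: str | Path) -> None:
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = "tRNA" if f.feature_kind == "tRNA" else "CDS"
            attrs = []
            if f.gene_id:
                attrs.append(f"ID={f.gene_id}")
            if f.product:
                attrs.append(f"product={urllib.parse.quote(f.product, safe=' ')}")
            fh.write(
                "\t".join(
                    [
                        f.contig_id, "ventphage", ftype,
                        str(f.start + 1), str(f.end), ".", f.strand, ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


def read_recruitment(tsv_path: str | Path) -> list[RecruitmentHit]:
    """Read a 12-column BLAST tabular hit table into RecruitmentHit objects.

    Minus-strand hits (sstart > send) are normalized so start < end with
    ``reverse=True``; coordinates become 0-based half-open.
    """
    try:
        df = pd.read_csv(tsv_path, sep="\t", header=None, comment="#",
                         dtype={0: str, 1: str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    if df.shape[1] < 12:
        raise ValueError(f"{tsv_path}: expected 12 tab-separated columns, "
                         f"got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = BLAST_COLUMNS
    if not pd.api.types.is_numeric_dtype(df["pident"]):
        raise ValueError(f"{tsv_path}: non-numeric identity column")
    hits: list[RecruitmentHit] = []
    for row in df.itertuples(index=False):
        sstart, send = int(row.sstart), int(row.send)
        reverse = sstart > send
        lo, hi = (send, sstart) if reverse else (sstart, send)
        hits.append(
            RecruitmentHit(
                read_id=str(row.qseqid),
                contig_id=str(row.sseqid),
                identity_pct=float(row.pident),
                start=lo - 1,
                end=hi,
                aln_len=int(row.length),
                reverse=reverse,
            )
        )
    return hits


def write_recruitment(hits: Iterable[RecruitmentHit], tsv_path: str | Path) -> None:
    rows = []
    for h in hits:
        sstart, send = h.start + 1, h.end
        if h.reverse:
            sstart, send = send, sstart
        rows.append(
            [h.read_id, h.contig_id, h.identity_pct, h.aln_len, 0, 0,
             1, h.aln_len, sstart, send, 1e-30, 100.0]
        )
    pd.DataFrame(rows, columns=BLAST_COLUMNS).to_csv(
        tsv_path, sep="\t", header=False, index=False
    )


def read_mda(tsv_path: str | Path) -> list[MdaRecord]:
    """Read an MDA kinetics table (header: sag_id, cp_hours, recovery_frac)."""
    df = pd.read_csv(tsv_path, sep="\t")
    required = {"sag_id", "cp_hours", "recovery_frac"}
    if not required <= set(df.columns):
        raise ValueError(f"{tsv_path}: missing columns {sorted(required - set(df.columns))}")
    return [
        MdaRecord(str(r.sag_id), float(r.cp_hours), float(r.recovery_frac))
        for r in df.itertuples(index=False)
    ]


def write_mda(records: Iterable[MdaRecord], tsv_path: str | Path) -> None:
    pd.DataFrame(
        [(r.sag_id, r.cp_hours, r.recovery_frac) for r in records],
        columns=["sag_id", "cp_hours", "recovery_frac"],
    ).to_csv(tsv_path, sep="\t", index=False)


def read_transcript_hits(tsv_path: str | Path) -> list[TranscriptHit]:
    """Read transcript-to-ORF hits.

    Accepts either the 12-column BLAST tabular dialect (identity column
    holds % amino-acid identity) or a plain 3-column table
    (fragment, orf, aa_identity_pct), headerless in both cases.
    """
    try:
        df = pd.read_csv(tsv_path, sep="\t", header=None, comment="#", dtype={0: str, 1: str})
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] not in (3, 12):
        raise ValueError(f"{tsv_path}: expected 3 or 12 columns, got {df.shape[1]}")
    return [
        TranscriptHit(str(row[0]), str(row[1]), float(row[2]))
        for row in df.itertuples(index=False)
    ]


def write_transcript_hits(hits: Iterable[TranscriptHit], tsv_path: str | Path) -> None:
    pd.DataFrame(
        [(h.fragment_id, h.orf_id, h.aa_identity_pct) for h in hits]
    ).to_csv(tsv_path, sep="\t", header=False, index=False)


def write_bed(intervals: Sequence[tuple], bed_path: str | Path) -> None:
    """Write (contig, start, end[, name[, score]]) tuples as BED (0-based half-open)."""
    with open(bed_path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(rows: Sequence[tuple], path: str | Path) -> None:
    """Write (contig, start, end, value) rows as bedGraph."""
    with open(path, "w") as fh:
        for contig, start, end, value in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{value:.6g}\n")
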