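"""Per-ORF expression from metatranscriptomic fragment recruitment.

Fragments are kept at a 95% amino-acid identity cutoff (inclusive), a
multi-mapping fragment keeps only its best-identity hit (ties broken by
ORF id), and counts are normalized to FPKM — Fragments per ORF Kilobase
per Million Mapped fragments:

    fpkm = count / ((length_bp / 1000) x (total_mapped / 1e6))

where total mapped fragments is the number of hits surviving the
identity filter over the analyzed ORF set. The identity
sum(fpkm x length_kb x total_millions) = total holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import Counter

from .model import OrfRecord, TranscriptHit


@dataclass(frozen=True, slots=True)
class FpkmEntry:
    orf_id: str
    fragment_count: int
    fpkm: float


@dataclass(frozen=True, slots=True)
class ProphageExpression:
    """Expression status of one called prophage region."""

    candidate_name: str
    n_genes: int
    n_expressed: int
    status: str  # "fully_transcribed", "expressed", or "silent"


def filter_hits(
    transcript_hits: list[TranscriptHit], min_aa_identity: float = 95.0
) -> list[TranscriptHit]:
    """Keep hits at or above the amino-acid identity cutoff; a fragment
    hitting multiple ORFs keeps only its best-identity hit (ties go to
    the first ORF id)."""
    best: dict[str, TranscriptHit] = {}
    for hit in transcript_hits:
        if hit.aa_identity_pct < min_aa_identity:
            continue
        cur = best.get(hit.fragment_id)
        if (
            cur is None
            or hit.aa_identity_pct > cur.aa_identity_pct
            or (hit.aa_identity_pct == cur.aa_identity_pct and hit.orf_id < cur.orf_id)
        ):
            best[hit.fragment_id] = hit
    return list(best.values())


def fpkm_table(
    filtered_hits: list[TranscriptHit], orf_records: list[OrfRecord]
) -> list[FpkmEntry]:
    """FPKM per ORF; ORFs with zero hits are included with fpkm 0.

    A zero total (no surviving hits) yields an all-zero table with a
    warning rather than an error.
    """
    total = len(filtered_hits)
    counts = Counter(h.orf_id for h in filtered_hits)
    known = {o.orf_id for o in orf_records}
    unknown = set(counts) - known
    if unknown:
        raise ValueError(f"hits reference unknown ORFs: {sorted(unknown)[:5]}")
    if total == 0:
        warnings.warn("no fragments survived the identity filter", stacklevel=2)
        return [FpkmEntry(o.orf_id, 0, 0.0) for o in orf_records]
    out = []
    for o in orf_records:
        count = counts.get(o.orf_id, 0)
        fpkm = count / ((o.length_bp / 1000.0) * (total / 1e6))
        out.append(FpkmEntry(o.orf_id, count, fpkm))
    return out


def prophage_expression(
    candidate_name: str,
    prophage_orf_ids: set[str],
    table: list[FpkmEntry],
) -> ProphageExpression:
    """Classify a prophage as fully transcribed (all genes fpkm > 0),
    expressed (≥1 gene fpkm > 0) or silent."""
    entries = [e for e in table if e.orf_id in prophage_orf_ids]
    n_genes = len(entries)
    n_expressed = sum(1 for e in entries if e.fpkm > 0)
    if n_genes and n_expressed == n_genes:
        status = "fully_transcribed"
    elif n_expressed >= 1:
        status = "expressed"
    else:
        status = "silent"
    return ProphageExpression(candidate_name, n_genes, n_expressed, status)


def write_fpkm_table(table: list[FpkmEntry], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("orf_id\tfragment_count\tfpkm\n")
        for e in table:
            fh.write(f"{e.orf_id}\t{e.fragment_count}\t{e.fpkm:.6g}\n")


def write_expression_summary(rows: list[ProphageExpression], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("candidate\tn_genes\tn_expressed\tstatus\n")
        for r in rows:
            fh.write(f"{r.candidate_name}\t{r.n_genes}\t{r.n_expressed}\t{r.status}\n")
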