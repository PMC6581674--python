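"""Prophage region calling by multi-evidence combination.

A candidate region is a dense cluster of viral marker genes (at least
``min_markers`` markers, consecutive markers never more than
``marker_window_bp`` apart), spanning from the first to the last marker
gene and extended to abut the nearest tRNA within ``trna_link_bp`` on
either side — tRNAs are common prophage integration sites. Evidence
classes collected per candidate:

* ``markers`` — the marker-gene cluster itself (always present);
* ``trna_flank`` — a tRNA within linking distance of a boundary;
* ``composition_anomaly`` — overlap with a GC-skew/tetramer anomaly
  interval by at least half of the smaller interval;
* ``mobility_gene`` — an integrase/recombinase/transposase inside the
  region;
* ``host_flanking`` — recognizable (non-marker, non-hypothetical) host
  genes on both sides, direct evidence of chromosomal integration.

A candidate is called ``prophage`` when it carries at least two evidence
classes including markers and its SAG is not an MDA lytic-suspect
outlier; otherwise it stays ``unresolved``. Lytic suspicion is never a
region call — it is reported at SAG level by the MDA diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .composition import AnomalyInterval
from .markers import MarkerHit, match_viral_keywords
from .model import ContigRecord, GeneAnnotation, overlap_len


@dataclass(frozen=True)
class CallerParams:
    min_markers: int = 3
    marker_window_bp: int = 10_000
    trna_link_bp: int = 5_000
    min_region_len: int = 5_000
    mobility_terms: tuple[str, ...] = ("integrase", "recombinase", "transposase")
    flank_bp: int = 10_000
    min_flank_genes: int = 2

    def __post_init__(self) -> None:
        for name in ("min_markers", "marker_window_bp", "trna_link_bp",
                     "min_region_len", "flank_bp", "min_flank_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ProphageCandidate:
    contig_id: str
    start: int
    end: int
    marker_gene_count: int
    evidence: frozenset[str] = frozenset({"markers"})
    lifestyle_call: str = "unresolved"
    sag_id: str = ""

    def __post_init__(self) -> None:
        if "markers" not in self.evidence:
            raise ValueError("candidate must carry marker evidence")
        if self.end <= self.start:
            raise ValueError("empty candidate region")


def _marker_clusters(
    marker_genes: list[GeneAnnotation], params: CallerParams
) -> list[list[GeneAnnotation]]:
    """Maximal runs of marker genes where ≥min_markers fall within some
    marker_window_bp span; returned clusters are the union of all
    qualifying (overlapping) runs."""
    genes = sorted(marker_genes, key=lambda g: (g.start, g.end))
    n = len(genes)
    m = params.min_markers
    if n < m:
        return []
    qualifying: list[tuple[int, int]] = []  # index ranges [i, j]
    for i in range(n - m + 1):
        j = i + m - 1
        # extend the run as far as markers stay within the window of the run
        while j + 1 < n and genes[j + 1].end - genes[i].start <= params.marker_window_bp:
            j += 1
        if genes[i + m - 1].end - genes[i].start <= params.marker_window_bp:
            qualifying.append((i, j))
    if not qualifying:
        return []
    # merge overlapping index ranges into maximal clusters
    merged: list[list[int]] = []
    for i, j in sorted(qualifying):
        if merged and i <= merged[-1][1] + 1 and genes[i].start - genes[merged[-1][1]].end <= params.marker_window_bp:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    return [genes[i : j + 1] for i, j in merged]


def call_candidate_regions(
    contig: ContigRecord,
    annotations: list[GeneAnnotation],
    marker_hits: list[MarkerHit],
    params: CallerParams | None = None,
) -> list[ProphageCandidate]:
    """Cluster marker genes into candidate prophage regions.

    The region spans first-to-last marker gene, then each boundary is
    extended to abut the nearest tRNA within ``trna_link_bp`` (gaining
    ``trna_flank`` evidence). Candidates shorter than ``min_region_len``
    after extension are dropped.
    """
    p = params or CallerParams()
    contig_anns = [a for a in annotations if a.contig_id == contig.contig_id]
    trnas = [a for a in contig_anns if a.feature_kind == "tRNA"]
    marker_genes = [
        h.annotation for h in marker_hits if h.annotation.contig_id == contig.contig_id
    ]
    out: list[ProphageCandidate] = []
    for cluster in _marker_clusters(marker_genes, p):
        start = min(g.start for g in cluster)
        end = max(g.end for g in cluster)
        evidence = {"markers"}
        upstream = [t for t in trnas if t.end <= start and start - t.end <= p.trna_link_bp]
        if upstream:
            start = max(t.end for t in upstream)
            evidence.add("trna_flank")
        downstream = [t for t in trnas if t.start >= end and t.start - end <= p.trna_link_bp]
        if downstream:
            end = min(t.start for t in downstream)
            evidence.add("trna_flank")
        if end - start < p.min_region_len:
            continue
        out.append(
            ProphageCandidate(
                contig_id=contig.contig_id,
                start=start,
                end=end,
                marker_gene_count=len(cluster),
                evidence=frozenset(evidence),
                sag_id=contig.sag_id,
            )
        )
    return out


def _is_hypothetical(product: str) -> bool:
    text = product.strip().lower()
    return text == "" or "hypothetical" in text or "uncharacterized" in text


def collect_evidence(
    candidate: ProphageCandidate,
    annotations: list[GeneAnnotation],
    anomaly_intervals: list[AnomalyInterval],
    params: CallerParams | None = None,
) -> ProphageCandidate:
    """Add mobility-gene, composition-anomaly and host-flanking evidence."""
    p = params or CallerParams()
    evidence = set(candidate.evidence)
    contig_anns = [
        a for a in annotations
        if a.contig_id == candidate.contig_id and a.feature_kind == "gene"
    ]
    inside = [
        a for a in contig_anns
        if overlap_len(a.start, a.end, candidate.start, candidate.end) > 0
    ]
    for a in inside:
        tokens = set(a.product.lower().replace("-", " ").split())
        if tokens & set(p.mobility_terms):
            evidence.add("mobility_gene")
            break

    for iv in anomaly_intervals:
        if iv.contig_id != candidate.contig_id:
            continue
        ov = overlap_len(iv.start, iv.end, candidate.start, candidate.end)
        smaller = min(iv.end - iv.start, candidate.end - candidate.start)
        if smaller > 0 and ov >= 0.5 * smaller:
            evidence.add("composition_anomaly")
            break

    def _host_genes(lo: int, hi: int) -> int:
        count = 0
        for a in contig_anns:
            if overlap_len(a.start, a.end, lo, hi) <= 0:
                continue
            if overlap_len(a.start, a.end, candidate.start, candidate.end) > 0:
                continue
            if _is_hypothetical(a.product):
                continue
            if match_viral_keywords(a.product):
                continue
            count += 1
        return count

    left = _host_genes(candidate.start - p.flank_bp, candidate.start)
    right = _host_genes(candidate.end, candidate.end + p.flank_bp)
    if left >= p.min_flank_genes and right >= p.min_flank_genes:
        evidence.add("host_flanking")

    return replace(candidate, evidence=frozenset(evidence))


def classify_lifestyle(
    candidates: list[ProphageCandidate],
    mda_outlier_flags: dict[str, bool] | None = None,
) -> list[ProphageCandidate]:
    """Set lifestyle_call: prophage when ≥2 evidence classes (incl.
    markers) and the SAG is not an MDA lytic outlier; else unresolved."""
    flags = mda_outlier_flags or {}
    out = []
    for c in candidates:
        is_outlier = flags.get(c.sag_id, False)
        call = (
            "prophage"
            if len(c.evidence) >= 2 and "markers" in c.evidence and not is_outlier
            else "unresolved"
        )
        out.append(replace(c, lifestyle_call=call))
    return out


def candidates_to_bed_rows(candidates: list[ProphageCandidate]) -> list[tuple]:
    return [
        (c.contig_id, c.start, c.end, f"{c.sag_id or 'sag'}:candidate{i+1}",
         c.marker_gene_count)
        for i, c in enumerate(candidates)
    ]


def write_evidence_table(candidates: list[ProphageCandidate], tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write(
            "sag_id\tcontig_id\tstart\tend\tlength\tmarker_gene_count\t"
            "evidence\tlifestyle_call\n"
        )
        for c in candidates:
            fh.write(
                f"{c.sag_id}\t{c.contig_id}\t{c.start}\t{c.end}\t{c.end - c.start}\t"
                f"{c.marker_gene_count}\t{','.join(sorted(c.evidence))}\t"
                f"{c.lifestyle_call}\n"
            )
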