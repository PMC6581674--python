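"""Domain types shared across the pipeline.

All in-memory coordinates are 0-based half-open. File formats keep their
native conventions (GFF3 and BLAST tabular are 1-based inclusive); the
conversion happens exactly once, in :mod:`ventphage.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True, slots=True)
class ContigRecord:
    """One assembly contig of a single amplified genome (SAG).

    ``sequence`` is uppercase over {A,C,G,T,N}; any other IUPAC character
    is collapsed to N at read time and excluded from k-mer statistics.
    """

    contig_id: str
    sequence: str
    sag_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """A gene/CDS or tRNA feature on a contig (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    strand: str
    feature_kind: str  # "gene" or "tRNA"
    product: str = ""
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.gene_id or self.product!r}: bad interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.feature_kind not in ("gene", "tRNA"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class RecruitmentHit:
    """One metagenomic read-to-contig alignment, orientation-normalized.

    ``start``/``end`` are 0-based half-open subject coordinates with
    ``start < end``; ``reverse`` records the original minus-strand
    orientation (file dialect: sstart > send).
    """

    read_id: str
    contig_id: str
    identity_pct: float
    start: int
    end: int
    aln_len: int
    reverse: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"hit {self.read_id!r}: identity {self.identity_pct}")
        if self.aln_len < 1:
            raise ValueError(f"hit {self.read_id!r}: aln_len {self.aln_len}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"hit {self.read_id!r}: bad interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True, slots=True)
class MdaRecord:
    """Per-SAG multiple displacement amplification kinetics.

    ``cp_hours`` is the MDA critical point: the time for the reaction to
    reach half of its maximal DNA-stain fluorescence, a proxy for template
    abundance. ``recovery_frac`` is the estimated genome recovery in [0,1].
    """

    sag_id: str
    cp_hours: float
    recovery_frac: float

    def __post_init__(self) -> None:
        if not self.cp_hours > 0:
            raise ValueError(f"SAG {self.sag_id!r}: cp_hours must be positive")
        if not (0.0 <= self.recovery_frac <= 1.0):
            raise ValueError(f"SAG {self.sag_id!r}: recovery outside [0,1]")


@dataclass(frozen=True, slots=True)
class TranscriptHit:
    """One metatranscriptomic fragment-to-ORF hit (amino-acid identity %)."""

    fragment_id: str
    orf_id: str
    aa_identity_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.aa_identity_pct <= 100.0):
            raise ValueError(
                f"fragment {self.fragment_id!r}: identity {self.aa_identity_pct}"
            )


@dataclass(frozen=True, slots=True)
class OrfRecord:
    """An ORF with its length and (optionally) prophage membership."""

    orf_id: str
    length_bp: int
    contig_id: str = ""
    start: int = 0
    end: int = 0
    is_prophage_gene: bool = False

    def __post_init__(self) -> None:
        if self.length_bp < 3:
            raise ValueError(f"ORF {self.orf_id!r}: length {self.length_bp} < 3")


def overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent half-open intervals."""
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
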