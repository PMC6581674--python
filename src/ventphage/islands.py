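"""Metagenomic-island calling from fragment recruitment.

A metagenomic island is a genome region poorly recruited by community
metagenome reads: reads never exceed 75% identity there and cover less
than half of the region. Operationally, per-base coverage is computed
from hits with identity strictly above ``id_threshold`` only, and a
window is an island window when that high-identity coverage fraction is
below ``cov_threshold``. Overlapping/adjacent island windows are merged
and short merged islands dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import RecruitmentHit, merge_intervals


@dataclass(frozen=True)
class CoverageIdentityTrack:
    contig_id: str
    hi_covered: np.ndarray  # bool, per base: covered by a hit with identity > threshold
    max_identity: np.ndarray  # float, per base: max identity over all hits (0 uncovered)
    id_threshold: float

    def __len__(self) -> int:
        return len(self.hi_covered)


@dataclass(frozen=True, slots=True)
class IslandCall:
    contig_id: str
    start: int
    end: int
    hi_coverage_frac: float
    max_identity_in_region: float


def build_track(
    hits: list[RecruitmentHit], contig_length: int,
    contig_id: str = "", id_threshold: float = 75.0,
) -> CoverageIdentityTrack:
    """Per-base max identity and high-identity (> id_threshold) coverage."""
    hi = np.zeros(contig_length, dtype=bool)
    max_id = np.zeros(contig_length, dtype=np.float64)
    for h in hits:
        if h.end > contig_length or h.start < 0:
            raise ValueError(
                f"hit {h.read_id!r} [{h.start},{h.end}) exceeds contig bounds "
                f"(length {contig_length})"
            )
        np.maximum(max_id[h.start:h.end], h.identity_pct, out=max_id[h.start:h.end])
        if h.identity_pct > id_threshold:
            hi[h.start:h.end] = True
    return CoverageIdentityTrack(contig_id, hi, max_id, id_threshold)


def call_islands(
    track: CoverageIdentityTrack,
    window: int = 1000,
    step: int = 500,
    cov_threshold: float = 0.50,
    min_len: int = 2000,
) -> list[IslandCall]:
    """Windows with high-identity coverage fraction < cov_threshold are
    island windows; merged islands shorter than min_len are dropped; the
    reported coverage fraction is recomputed over the merged interval."""
    length = len(track)
    if window >= length:
        spans = [(0, length)]
    else:
        starts = list(range(0, length - window + 1, step))
        if starts[-1] + window < length:
            starts.append(length - window)
        spans = [(s, s + window) for s in starts]

    cum = np.concatenate([[0], np.cumsum(track.hi_covered.astype(np.int64))])
    island_windows = [
        (s, e) for s, e in spans if (cum[e] - cum[s]) / (e - s) < cov_threshold
    ]
    merged = merge_intervals(island_windows)
    out: list[IslandCall] = []
    for s, e in merged:
        if e - s < min_len:
            continue
        frac = (cum[e] - cum[s]) / (e - s)
        out.append(
            IslandCall(
                track.contig_id, s, e,
                hi_coverage_frac=float(frac),
                max_identity_in_region=float(track.max_identity[s:e].max()),
            )
        )
    return out


def islands_to_bed_rows(islands: list[IslandCall]) -> list[tuple]:
    return [
        (i.contig_id, i.start, i.end,
         f"island_{n+1}", f"{i.hi_coverage_frac:.3f}")
        for n, i in enumerate(islands)
    ]


def track_to_bedgraph_rows(track: CoverageIdentityTrack) -> list[tuple]:
    """Run-length-encode the per-base max-identity track as bedGraph rows."""
    vals = track.max_identity
    if len(vals) == 0:
        return []
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(vals)]])
    return [
        (track.contig_id, int(s), int(e), float(vals[s]))
        for s, e in zip(starts, ends)
    ]


def recruitment_plot_rows(
    hits: list[RecruitmentHit], min_display_identity: float = 50.0
) -> list[tuple]:
    """Read midpoint vs identity rows for a recruitment-plot export;
    hits at or below ``min_display_identity`` are omitted (display
    filter only — island calling always sees all hits)."""
    return [
        (h.contig_id, (h.start + h.end) // 2, h.identity_pct)
        for h in hits
        if h.identity_pct > min_display_identity
    ]
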