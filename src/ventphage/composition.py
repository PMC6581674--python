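"""Windowed GC skew and tetranucleotide-frequency anomaly profiles.

Foreign DNA — prophages in particular — often deviates from the host's
oligonucleotide composition. Two window statistics are computed along a
contig:

* GC skew: (G − C) / (G + C) per window, in [−1, 1].
* Tetramer anomaly: the Manhattan (L1) distance between each window's
  256-dimensional tetranucleotide frequency vector and the whole-contig
  vector, standardized to a z-score across valid windows.

Windows containing more than 10% N are marked invalid and excluded from
all statistics. Tetramers are counted single-stranded on the given
strand by default (canonical collapsing with reverse complements is
available as a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import merge_intervals

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

MAX_N_FRAC = 0.10


@dataclass(frozen=True, slots=True)
class WindowProfile:
    contig_id: str
    start: int
    end: int
    value: float
    valid: bool = True
    zero_denominator: bool = False


@dataclass(frozen=True, slots=True)
class AnomalyInterval:
    contig_id: str
    start: int
    end: int
    signal_kind: str  # "gc_skew" or "tetramer"
    peak_score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty anomaly interval")


def _encode(sequence: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and anything else (N) to -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def _windows(length: int, window: int, step: int) -> list[tuple[int, int]]:
    if length <= window:
        return [(0, length)]
    starts = list(range(0, length - window + 1, step))
    # make sure the tail of the contig is covered
    if starts[-1] + window < length:
        starts.append(length - window)
    return [(s, s + window) for s in starts]


def gc_skew_profile(
    sequence: str, contig_id: str = "", window: int = 1000, step: int = 500
) -> list[WindowProfile]:
    """Per-window GC skew (G−C)/(G+C).

    Windows with no G or C get value 0 and a zero-denominator flag;
    windows with >10% N are invalid. A sequence shorter than the window
    yields a single whole-sequence window (with a warning).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if len(sequence) < window:
        warnings.warn(
            f"sequence shorter than window ({len(sequence)} < {window}); "
            "using one whole-sequence window",
            stacklevel=2,
        )
    codes = _encode(sequence)
    profiles: list[WindowProfile] = []
    for s, e in _windows(len(sequence), window, step):
        win = codes[s:e]
        n_frac = np.mean(win < 0) if len(win) else 1.0
        g = int(np.sum(win == 2))
        c = int(np.sum(win == 1))
        if g + c == 0:
            profiles.append(
                WindowProfile(contig_id, s, e, 0.0, valid=n_frac <= MAX_N_FRAC,
                              zero_denominator=True)
            )
        else:
            profiles.append(
                WindowProfile(contig_id, s, e, (g - c) / (g + c),
                              valid=n_frac <= MAX_N_FRAC)
            )
    return profiles


def cumulative_gc_skew(sequence: str) -> np.ndarray:
    """Cumulative GC skew along the sequence (+1 per G, −1 per C)."""
    codes = _encode(sequence)
    contrib = np.where(codes == 2, 1, np.where(codes == 1, -1, 0))
    return np.cumsum(contrib)


def _tetramer_counts(codes: np.ndarray) -> np.ndarray:
    """Counts of overlapping 4-mers, skipping any 4-mer containing N."""
    if len(codes) < 4:
        return np.zeros(256, dtype=np.int64)
    k = (
        codes[:-3] * 64 + codes[1:-2] * 16 + codes[2:-1] * 4 + codes[3:]
    )
    valid = (
        (codes[:-3] >= 0) & (codes[1:-2] >= 0) & (codes[2:-1] >= 0) & (codes[3:] >= 0)
    )
    return np.bincount(k[valid], minlength=256)


def tetramer_profile(sequence: str) -> np.ndarray:
    """Frequency vector over the 256 tetranucleotides (lexicographic
    A<C<G<T order), summing to 1. 4-mers spanning N are skipped."""
    counts = _tetramer_counts(_encode(sequence))
    total = counts.sum()
    if total < 1:
        raise ValueError("sequence too short/masked: no valid tetramer")
    return counts / total


def _canonicalize(vec: np.ndarray) -> np.ndarray:
    """Fold a tetramer vector onto canonical k-mers (k-mer + revcomp pooled)."""
    idx = np.arange(256)
    b = np.stack([(idx // 64) % 4, (idx // 16) % 4, (idx // 4) % 4, idx % 4])
    comp = 3 - b
    rc = comp[3] * 64 + comp[2] * 16 + comp[1] * 4 + comp[0]
    out = vec + vec[rc]
    return out / out.sum()


def tetramer_anomaly(
    sequence: str,
    contig_id: str = "",
    window: int = 5000,
    step: int = 1000,
    canonical: bool = False,
) -> list[WindowProfile]:
    """Per-window tetramer anomaly z-scores.

    Each window's Manhattan distance to the whole-contig tetramer vector
    is standardized across valid windows: z = (d − mean) / sd. With
    fewer than 5 valid windows the z-scores are unavailable (NaN,
    valid=False).
    """
    codes = _encode(sequence)
    global_counts = _tetramer_counts(codes)
    if global_counts.sum() < 1:
        raise ValueError("sequence too short/masked: no valid tetramer")
    global_vec = global_counts / global_counts.sum()
    if canonical:
        global_vec = _canonicalize(global_vec)

    spans = _windows(len(sequence), window, step)
    dists = np.full(len(spans), np.nan)
    valid = np.zeros(len(spans), dtype=bool)
    for i, (s, e) in enumerate(spans):
        win = codes[s:e]
        if np.mean(win < 0) > MAX_N_FRAC:
            continue
        counts = _tetramer_counts(win)
        if counts.sum() < 1:
            continue
        vec = counts / counts.sum()
        if canonical:
            vec = _canonicalize(vec)
        dists[i] = np.abs(vec - global_vec).sum()
        valid[i] = True

    profiles: list[WindowProfile] = []
    n_valid = int(valid.sum())
    if n_valid < 5:
        warnings.warn(
            f"only {n_valid} valid windows (<5); z-scores unavailable", stacklevel=2
        )
        for (s, e), v in zip(spans, valid):
            profiles.append(WindowProfile(contig_id, s, e, float("nan"), valid=False))
        return profiles

    mean = dists[valid].mean()
    sd = dists[valid].std(ddof=0)
    for i, (s, e) in enumerate(spans):
        if not valid[i]:
            profiles.append(WindowProfile(contig_id, s, e, float("nan"), valid=False))
        elif sd == 0:
            profiles.append(WindowProfile(contig_id, s, e, 0.0))
        else:
            profiles.append(WindowProfile(contig_id, s, e, float((dists[i] - mean) / sd)))
    return profiles


def anomalous_windows(
    profile: list[WindowProfile], signal_kind: str, k: float | None = None
) -> list[AnomalyInterval]:
    """Call anomaly intervals from a window profile.

    GC skew: windows with |value − median| > k·MAD (k default 3.0); if
    the MAD is exactly 0 but some residuals are nonzero, the standard
    deviation is used instead; if all residuals are 0 nothing is called.
    Tetramer: windows with z-score > k (k default 2.0). Threshold-passing
    windows that overlap or touch are merged; peak_score is the maximum
    window score within the merged interval.
    """
    if signal_kind not in ("gc_skew", "tetramer"):
        raise ValueError(f"unknown signal kind {signal_kind!r}")
    valid = [p for p in profile if p.valid and np.isfinite(p.value)]
    if not valid:
        warnings.warn("no valid windows; no anomalies called", stacklevel=2)
        return []
    contig_id = valid[0].contig_id

    if signal_kind == "gc_skew":
        if k is None:
            k = 3.0
        values = np.array([p.value for p in valid])
        med = np.median(values)
        resid = np.abs(values - med)
        mad = np.median(resid)
        if mad == 0:
            if np.all(resid == 0):
                return []
            mad = values.std(ddof=0)
            if mad == 0:
                return []
        scores = resid / mad
        flagged = scores > k
    else:
        if k is None:
            k = 2.0
        scores = np.array([p.value for p in valid])
        flagged = scores > k

    picked = [(p.start, p.end) for p, f in zip(valid, flagged) if f]
    merged = merge_intervals(picked)
    out: list[AnomalyInterval] = []
    for s, e in merged:
        peak = max(
            sc for p, sc in zip(valid, scores) if p.start < e and p.end > s
        )
        out.append(AnomalyInterval(contig_id, s, e, signal_kind, float(peak)))
    return out


def profile_to_bedgraph_rows(profile: list[WindowProfile]) -> list[tuple]:
    return [(p.contig_id, p.start, p.end, p.value) for p in profile if p.valid]
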