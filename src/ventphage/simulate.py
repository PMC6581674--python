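"""Seeded generators for every input the pipeline consumes, with truth.

The study's real inputs (SAG assemblies, metagenomic recruitment tables,
MDA kinetics, metatranscriptome hits) are emulated by pure functions of
their parameters and a seed:

* host genomes as order-3 Markov-chain sequences (so tetranucleotide
  composition is directly controllable), with genes tiled at ~1 gene/kb
  and tRNA features placed as integration sites;
* implanted prophage blocks resampled from a compositionally shifted
  chain, carrying viral gene products from the marker lexicon, an
  integrase at the attachment (tRNA) end and a structural gene at the
  distal end;
* fragment recruitment as 150 bp reads (2x150 sequencing) tiling the
  genome at high identity outside metagenomic islands and either absent
  or at 60-75% identity inside them;
* MDA Cp-recovery pairs on a negative linear trend with implanted
  below-line lytic outliers;
* transcript hit tables with multinomial fragment assignment and
  sub-cutoff decoy hits.

Every generated dataset ships with a :class:`SimTruth` sidecar (JSON);
downstream accuracy checks read truth only from it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import ContigRecord, GeneAnnotation, MdaRecord, OrfRecord, RecruitmentHit, TranscriptHit

READ_LEN = 150
GENE_SPACING = 1000
GENE_LEN = 900

HOST_PRODUCTS = (
    "DNA polymerase III subunit alpha",
    "ribosomal protein L2",
    "ABC transporter ATP-binding protein",
    "elongation factor Tu",
    "chaperonin GroEL",
    "NADH-quinone oxidoreductase subunit D",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "ATP synthase F1 subunit beta",
    "aminotransferase class I",
    "sulfur oxidation protein SoxB",
)

VIRAL_PRODUCTS = (
    "phage terminase large subunit",
    "major capsid protein",
    "phage portal protein",
    "baseplate assembly protein",
    "phage tail tape measure protein",
    "tail fiber protein",
    "virion structural protein",
    "phage head morphogenesis protein",
    "holin, phage lysis protein",
    "prophage antirepressor",
)

TRNA_NAMES = ("tRNA-Leu", "tRNA-Ser", "tRNA-Arg", "tRNA-Met", "tRNA-Gly")

# strongly GC-biased alternative composition the prophage blocks are
# shifted toward (mixing weight = the `shift` parameter)
PROPHAGE_ALT_ROW = np.array([0.08, 0.42, 0.42, 0.08])


def uniform_transition() -> np.ndarray:
    """Order-3 transition matrix (64 contexts x 4 bases), uniform."""
    return np.full((64, 4), 0.25)


def biased_transition(concentration: float, seed: int) -> np.ndarray:
    """Random transition with per-context Dirichlet(concentration) rows.

    Lower concentration → more skewed composition."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet([concentration] * 4, size=64)


def prophage_transition(base: np.ndarray, shift: float) -> np.ndarray:
    """Mix a background transition toward the GC-rich alternative."""
    alt = np.tile(PROPHAGE_ALT_ROW, (64, 1))
    return (1.0 - shift) * base + shift * alt


def _validate_transition(trans: np.ndarray) -> np.ndarray:
    trans = np.asarray(trans, dtype=float)
    if trans.shape != (64, 4):
        raise ValueError(f"transition must be 64x4, got {trans.shape}")
    if np.any(np.abs(trans.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition rows must sum to 1 within 1e-9")
    return trans


def _markov_sequence(length: int, trans: np.ndarray, rng: np.random.Generator,
                     context: tuple[int, int, int] | None = None) -> str:
    """Sample an order-3 Markov sequence of the given length."""
    cum = np.cumsum(trans, axis=1)
    us = rng.random(length)
    if context is None:
        c = tuple(rng.integers(0, 4, size=3))
    else:
        c = context
    code = c[0] * 16 + c[1] * 4 + c[2]
    out = np.empty(length, dtype=np.uint8)
    row_cache = cum
    for i in range(length):
        u = us[i]
        row = row_cache[code]
        b = 0
        while row[b] < u:
            b += 1
        out[i] = b
        code = (code * 4 + b) % 64
    return "".join("ACGT"[b] for b in out)


@dataclass
class SimTruth:
    """Ground truth recorded alongside each generated dataset."""

    seed: int = 0
    parameters: dict = field(default_factory=dict)
    prophage_intervals: dict = field(default_factory=dict)  # contig_id -> [[start, end], ...]
    island_intervals: dict = field(default_factory=dict)  # contig_id -> [[start, end, mode], ...]
    mda_outlier_sags: list = field(default_factory=list)
    orf_expression: dict = field(default_factory=dict)  # orf_id -> {count, fpkm}

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_host_genome(
    length_bp: int,
    tetramer_bias: np.ndarray | None = None,
    seed: int = 0,
    sag_id: str = "SAG-1",
    contig_id: str | None = None,
    n_trna: int = 2,
) -> tuple[ContigRecord, list[GeneAnnotation]]:
    """A phage-free host contig with tiled genes and tRNA features.

    Sequence is an order-3 Markov chain under ``tetramer_bias`` (uniform
    by default). Genes are tiled at ~1 gene/kb with host products (some
    hypothetical); ``n_trna`` (≥2) gene slots are replaced by tRNAs.
    """
    if length_bp < 20_000:
        raise ValueError(f"length_bp {length_bp} < 20000")
    if n_trna < 2:
        raise ValueError("at least 2 tRNA features required")
    trans = _validate_transition(tetramer_bias if tetramer_bias is not None else uniform_transition())
    rng = np.random.default_rng(seed)
    contig_id = contig_id or f"{sag_id}_c1"
    sequence = _markov_sequence(length_bp, trans, rng)

    n_slots = length_bp // GENE_SPACING
    # keep one tRNA in the first third so an integration site with
    # downstream room always exists
    first = int(rng.integers(1, max(2, n_slots // 3)))
    rest = rng.choice(
        [s for s in range(1, n_slots - 1) if s != first],
        size=n_trna - 1, replace=False,
    )
    trna_slots = sorted([first, *rest.tolist()])
    annotations: list[GeneAnnotation] = []
    for slot in range(n_slots):
        base = slot * GENE_SPACING
        if slot in trna_slots:
            annotations.append(
                GeneAnnotation(
                    contig_id, base + 100, base + 175,
                    strand="+", feature_kind="tRNA",
                    product=str(rng.choice(TRNA_NAMES)),
                    gene_id=f"{contig_id}_t{slot}",
                )
            )
            continue
        end = min(base + 50 + GENE_LEN, length_bp)
        if end - (base + 50) < 150:
            continue
        product = (
            "hypothetical protein"
            if rng.random() < 0.25
            else str(rng.choice(HOST_PRODUCTS))
        )
        annotations.append(
            GeneAnnotation(
                contig_id, base + 50, end,
                strand="+" if rng.random() < 0.5 else "-",
                feature_kind="gene", product=product,
                gene_id=f"{contig_id}_g{slot}",
            )
        )
    return ContigRecord(contig_id, sequence, sag_id=sag_id), annotations


def implant_prophage(
    contig: ContigRecord,
    annotations: list[GeneAnnotation],
    prophage_len: int,
    shift: float,
    seed: int = 0,
    host_bias: np.ndarray | None = None,
    occupied: tuple[tuple[int, int], ...] = (),
) -> tuple[ContigRecord, list[GeneAnnotation], tuple[int, int]]:
    """Overwrite a block downstream of a tRNA with prophage sequence.

    The block sequence is resampled from the host composition mixed
    toward a GC-rich alternative with weight ``shift`` ∈ (0, 1]. Genes
    fully inside the block are relabeled: an integrase first (at the
    attachment site), a structural gene last, and ≥6 viral products in
    between (with a 20% hypothetical fraction among interior genes).
    Returns the modified contig, annotations, and the truth interval.
    """
    if not (0.0 < shift <= 1.0):
        raise ValueError("shift must be in (0, 1]")
    if prophage_len > len(contig) // 2:
        raise ValueError("prophage_len exceeds half the genome")
    rng = np.random.default_rng(seed)
    trnas = [a for a in annotations if a.feature_kind == "tRNA"]

    def _free(lo: int, hi: int) -> bool:
        if hi > len(contig):
            return False
        for s, e in occupied:
            if lo < e and s < hi:
                return False
        for t in trnas:
            if lo < t.end and t.start < hi:
                return False
        return True

    site = None
    for t in sorted(trnas, key=lambda t: t.start):
        if _free(t.end, t.end + prophage_len):
            site = t
            break
    if site is None:
        raise ValueError("no integration site: no tRNA with room for the implant")
    start, end = site.end, site.end + prophage_len

    base = _validate_transition(host_bias if host_bias is not None else uniform_transition())
    trans = _validate_transition(prophage_transition(base, shift))
    block = _markov_sequence(end - start, trans, rng)
    sequence = contig.sequence[:start] + block + contig.sequence[end:]

    inside = [
        a for a in annotations
        if a.feature_kind == "gene" and a.start >= start and a.end <= end
    ]
    inside.sort(key=lambda a: a.start)
    if len(inside) < 7:
        raise ValueError(
            f"prophage block holds {len(inside)} genes; ≥7 required "
            "(integrase plus ≥6 viral)"
        )
    relabel: dict[str, str] = {}
    relabel[inside[0].gene_id] = "site-specific integrase"
    relabel[inside[-1].gene_id] = "virion structural protein"
    interior = inside[1:-1]
    n_viral = max(5, math.ceil(0.8 * len(interior)))
    viral_idx = set(rng.choice(len(interior), size=min(n_viral, len(interior)), replace=False))
    for i, a in enumerate(interior):
        relabel[a.gene_id] = (
            str(rng.choice(VIRAL_PRODUCTS)) if i in viral_idx else "hypothetical protein"
        )

    new_annotations = []
    from dataclasses import replace as _replace

    for a in annotations:
        if a.gene_id in relabel:
            a = _replace(a, product=relabel[a.gene_id])
        new_annotations.append(a)
    return ContigRecord(contig.contig_id, sequence, sag_id=contig.sag_id), new_annotations, (start, end)


def simulate_sag(
    length_bp: int = 60_000,
    with_prophage: bool = True,
    prophage_len: int = 20_000,
    shift: float = 0.6,
    seed: int = 0,
    sag_id: str = "SAG-1",
) -> tuple[ContigRecord, list[GeneAnnotation], SimTruth]:
    """One synthetic SAG contig, optionally with an implanted prophage."""
    contig, annotations = simulate_host_genome(length_bp, seed=seed, sag_id=sag_id)
    truth = SimTruth(seed=seed, parameters={
        "length_bp": length_bp, "with_prophage": with_prophage,
        "prophage_len": prophage_len, "shift": shift,
    })
    if with_prophage:
        contig, annotations, interval = implant_prophage(
            contig, annotations, prophage_len, shift, seed=seed + 1
        )
        truth.prophage_intervals[contig.contig_id] = [list(interval)]
    return contig, annotations, truth


def simulate_recruitment(
    contig: ContigRecord,
    island_intervals: list[tuple[int, int]],
    depth: int = 20,
    seed: int = 0,
) -> tuple[list[RecruitmentHit], SimTruth]:
    """Recruitment hits tiling the contig outside metagenomic islands.

    Reads are 150 bp, evenly spaced with small jitter so that any depth
    ≥ 20 covers every base outside islands. Identity is Normal(98, 1)
    truncated to [90, 100] outside islands. Each island independently is
    either a no-hit island (probability 0.5) or recruits at identity
    Uniform(60, 75). A read belongs to an island when its midpoint does.
    """
    if depth < 5:
        raise ValueError("depth must be >= 5")
    length = len(contig)
    for s, e in island_intervals:
        if not (0 <= s < e <= length):
            raise ValueError(f"island [{s}, {e}) outside contig of length {length}")
    rng = np.random.default_rng(seed)
    modes = {
        (s, e): ("nohit" if rng.random() < 0.5 else "lowid")
        for s, e in island_intervals
    }
    n_reads = max(2, math.ceil(depth * length / READ_LEN))
    base_starts = np.linspace(0, length - READ_LEN, n_reads)
    jitter = rng.uniform(-3, 3, size=n_reads)
    starts = np.clip(np.round(base_starts + jitter).astype(int), 0, length - READ_LEN)
    starts[0], starts[-1] = 0, length - READ_LEN  # pin the ends: full coverage

    hits: list[RecruitmentHit] = []
    for i, s in enumerate(starts):
        mid = s + READ_LEN // 2
        island = next(((a, b) for a, b in island_intervals if a <= mid < b), None)
        if island is not None:
            if modes[island] == "nohit":
                continue
            ident = rng.uniform(60.0, 75.0)
        else:
            ident = float(np.clip(rng.normal(98.0, 1.0), 90.0, 100.0))
        hits.append(
            RecruitmentHit(
                read_id=f"r{i:07d}",
                contig_id=contig.contig_id,
                identity_pct=round(ident, 2),
                start=int(s),
                end=int(s) + READ_LEN,
                aln_len=READ_LEN,
                reverse=bool(rng.random() < 0.5),
            )
        )
    truth = SimTruth(
        seed=seed,
        parameters={"depth": depth, "read_len": READ_LEN},
        island_intervals={
            contig.contig_id: [[s, e, modes[(s, e)]] for s, e in island_intervals]
        },
    )
    return hits, truth


def simulate_mda(
    n_sags: int = 50,
    slope: float = -0.04,
    noise_sd: float = 0.03,
    n_outliers: int = 1,
    offset: float = 0.4,
    seed: int = 0,
    intercept: float = 0.9,
) -> tuple[list[MdaRecord], SimTruth]:
    """MDA Cp-recovery pairs on a linear trend plus below-line outliers.

    cp ~ Uniform(2, 12); recovery = clip(intercept + slope*cp + noise, 0, 1);
    ``n_outliers`` records are shifted down by ``offset`` (the lytic
    pattern: low Cp but degraded host genome).
    """
    if n_sags < 10:
        raise ValueError("n_sags must be >= 10")
    if n_outliers > 0 and offset <= 0:
        raise ValueError("offset must be positive when implanting outliers")
    if slope >= 0:
        warnings.warn("non-negative slope requested; the expected trend is negative",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    cp = rng.uniform(2.0, 12.0, size=n_sags)
    recovery = intercept + slope * cp + rng.normal(0.0, noise_sd, size=n_sags)
    outlier_idx = rng.choice(n_sags, size=n_outliers, replace=False) if n_outliers else []
    for i in outlier_idx:
        recovery[i] -= offset
    recovery = np.clip(recovery, 0.0, 1.0)
    records = [
        MdaRecord(f"SAG-{i+1:03d}", float(cp[i]), float(recovery[i]))
        for i in range(n_sags)
    ]
    truth = SimTruth(
        seed=seed,
        parameters={
            "n_sags": n_sags, "slope": slope, "noise_sd": noise_sd,
            "n_outliers": n_outliers, "offset": offset, "intercept": intercept,
        },
        mda_outlier_sags=[f"SAG-{i+1:03d}" for i in sorted(outlier_idx)],
    )
    return records, truth


def simulate_transcripts(
    orf_records: list[OrfRecord],
    expression_levels: list[float],
    total_fragments: int,
    seed: int = 0,
    decoy_frac: float = 0.0,
) -> tuple[list[TranscriptHit], SimTruth]:
    """Transcript hits with multinomial assignment and decoys.

    Fragments are assigned to ORFs with probability proportional to
    level x length; expressed hits draw amino-acid identity from
    Normal(98, 1) capped at 100, decoys (a ``decoy_frac`` share of the
    total) from Uniform(70, 94.9) — below the 95% cutoff. Truth FPKM is
    computed analytically from the assigned (non-decoy) counts.
    """
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    levels = np.asarray(expression_levels, dtype=float)
    if len(levels) != len(orf_records):
        raise ValueError("one expression level per ORF required")
    if np.any(levels < 0) or levels.sum() == 0:
        raise ValueError("expression levels must be >= 0 and not all zero")
    if not (0.0 <= decoy_frac < 1.0):
        raise ValueError("decoy_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    weights = levels * np.array([o.length_bp for o in orf_records], dtype=float)
    p = weights / weights.sum()
    n_decoy = int(round(decoy_frac * total_fragments))
    n_real = total_fragments - n_decoy
    counts = rng.multinomial(n_real, p)

    hits: list[TranscriptHit] = []
    frag = 0
    for orf, count in zip(orf_records, counts):
        for _ in range(count):
            ident = min(100.0, rng.normal(98.0, 1.0))
            hits.append(TranscriptHit(f"f{frag:07d}", orf.orf_id, round(ident, 2)))
            frag += 1
    for _ in range(n_decoy):
        orf = orf_records[rng.integers(0, len(orf_records))]
        hits.append(
            TranscriptHit(f"f{frag:07d}", orf.orf_id, round(rng.uniform(70.0, 94.9), 2))
        )
        frag += 1

    total = int(counts.sum())
    truth_expr = {}
    for orf, count in zip(orf_records, counts):
        fpkm = (
            count / ((orf.length_bp / 1000.0) * (total / 1e6)) if total else 0.0
        )
        truth_expr[orf.orf_id] = {"count": int(count), "fpkm": fpkm}
    truth = SimTruth(
        seed=seed,
        parameters={
            "total_fragments": total_fragments, "decoy_frac": decoy_frac,
            "n_orfs": len(orf_records),
        },
        orf_expression=truth_expr,
    )
    return hits, truth
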