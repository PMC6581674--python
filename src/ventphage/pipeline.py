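"""End-to-end detect → diagnose → report orchestration over the modules."""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from pathlib import Path

from . import __version__
from .caller import (
    call_candidate_regions,
    candidates_to_bed_rows,
    classify_lifestyle,
    collect_evidence,
    write_evidence_table,
)
from .composition import anomalous_windows, gc_skew_profile, tetramer_anomaly
from .config import PipelineConfig
from .io import write_bed
from .markers import DEFAULT_EXCLUSIONS, DEFAULT_KEYWORDS, MarkerLexicon, scan_annotations
from .mda import fit_cp_recovery, flag_outliers, lytic_suspect_sags
from .model import ContigRecord, GeneAnnotation, MdaRecord


class ValidationError(ValueError):
    """Input-validation failure (maps to exit code 2 at the CLI)."""


def validate_inputs(
    contigs: list[ContigRecord], annotations: list[GeneAnnotation]
) -> None:
    known = {c.contig_id for c in contigs}
    orphans = sorted({a.contig_id for a in annotations} - known)
    if orphans:
        raise ValidationError(
            f"annotations reference unknown contigs: {orphans}"
        )
    lengths = {c.contig_id: len(c) for c in contigs}
    for a in annotations:
        if a.end > lengths[a.contig_id]:
            raise ValidationError(
                f"feature {a.gene_id!r} exceeds contig {a.contig_id} "
                f"({a.end} > {lengths[a.contig_id]})"
            )


def detect_prophages(
    contigs: list[ContigRecord],
    annotations: list[GeneAnnotation],
    config: PipelineConfig | None = None,
    mda_records: list[MdaRecord] | None = None,
):
    """Run marker scan, composition anomaly, candidate calling, evidence
    collection and lifestyle classification over a set of contigs.

    Returns (candidates, sag_summary) where sag_summary maps SAG id to
    "prophage-bearing", "lytic-suspect" or "none".
    """
    cfg = config or PipelineConfig()
    validate_inputs(contigs, annotations)
    lexicon = MarkerLexicon(
        keywords=DEFAULT_KEYWORDS + tuple(cfg.extra_keywords),
        exclusions=DEFAULT_EXCLUSIONS + tuple(cfg.extra_exclusions),
    )
    outlier_flags: dict[str, bool] = {}
    if mda_records and len(mda_records) >= 5:
        fit = fit_cp_recovery(mda_records)
        suspects = lytic_suspect_sags(
            flag_outliers(fit, mda_records, cfg.mda_outlier_threshold)
        )
        outlier_flags = {r.sag_id: r.sag_id in suspects for r in mda_records}

    by_contig: dict[str, list[GeneAnnotation]] = defaultdict(list)
    for a in annotations:
        by_contig[a.contig_id].append(a)

    all_candidates = []
    for contig in contigs:
        anns = by_contig.get(contig.contig_id, [])
        hits = scan_annotations(anns, lexicon)
        if not hits:
            continue
        anomalies = []
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            try:
                tet = tetramer_anomaly(
                    contig.sequence, contig.contig_id,
                    cfg.tetramer_window, cfg.tetramer_step,
                )
                anomalies += anomalous_windows(tet, "tetramer", cfg.tetramer_k)
            except ValueError:
                pass
            skew = gc_skew_profile(
                contig.sequence, contig.contig_id, cfg.skew_window, cfg.skew_step
            )
            anomalies += anomalous_windows(skew, "gc_skew", cfg.skew_k)
        candidates = call_candidate_regions(contig, anns, hits, cfg.caller_params())
        candidates = [collect_evidence(c, anns, anomalies, cfg.caller_params()) for c in candidates]
        all_candidates.extend(candidates)

    all_candidates = classify_lifestyle(all_candidates, outlier_flags)

    sag_summary: dict[str, str] = {}
    for contig in contigs:
        sag = contig.sag_id or contig.contig_id
        sag_summary.setdefault(sag, "none")
    for c in all_candidates:
        if c.lifestyle_call == "prophage":
            sag_summary[c.sag_id or c.contig_id] = "prophage-bearing"
    for sag, is_outlier in outlier_flags.items():
        if is_outlier and sag_summary.get(sag) != "prophage-bearing":
            sag_summary[sag] = "lytic-suspect"
    return all_candidates, sag_summary


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_detect_outputs(
    candidates, sag_summary, config: PipelineConfig, outdir: str | Path
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed(candidates_to_bed_rows(candidates), out / "prophages.bed")
    write_evidence_table(candidates, out / "prophage_evidence.tsv")
    with open(out / "sag_summary.tsv", "w") as fh:
        fh.write("sag_id\tstatus\n")
        for sag in sorted(sag_summary):
            fh.write(f"{sag}\t{sag_summary[sag]}\n")
    # Table-1-shaped summary: SAG, contig, viral region length
    with open(out / "viral_regions.tsv", "w") as fh:
        fh.write("sag_id\tcontig_id\tviral_region_length\n")
        for c in candidates:
            fh.write(f"{c.sag_id}\t{c.contig_id}\t{c.end - c.start}\n")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "input_checksums": {
            name: _checksum(p)
            for name, p in (("fasta", config.fasta), ("gff", config.gff),
                            ("mda", config.mda))
            if p and Path(p).exists()
        },
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
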