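#!/usr/bin/env python
"""Per-ORF FPKM from the simulated transcript hits, with prophage status.

Filters hits at 95% amino-acid identity, computes FPKM, verifies the
count-conservation identity, and classifies each called prophage as
fully transcribed / expressed / silent from the per-gene FPKM values.
"""

import json
from pathlib import Path

import pandas as pd

from ventphage.fpkm import (
    filter_hits, fpkm_table, prophage_expression, write_expression_summary,
    write_fpkm_table,
)
from ventphage.io import read_transcript_hits
from ventphage.model import OrfRecord

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    study = ROOT / "study"
    hits = read_transcript_hits(study / "transcripts.tsv")
    orf_df = pd.read_csv(study / "orfs.tsv", sep="\t")
    orfs = [OrfRecord(str(r.orf_id), int(r.length_bp))
            for r in orf_df.itertuples(index=False)]
    kept = filter_hits(hits)
    table = fpkm_table(kept, orfs)

    out = ROOT / "fpkm"
    out.mkdir(parents=True, exist_ok=True)
    write_fpkm_table(table, out / "fpkm.tsv")

    total = len(kept)
    conserved = sum(e.fpkm * (o.length_bp / 1000.0) * (total / 1e6)
                    for e, o in zip(table, orfs))
    print(f"{total} of {len(hits)} fragments pass the 95% aa-identity filter")
    print(f"conservation check: sum(fpkm*kb*millions) = {conserved:.6f} "
          f"vs total {total}")

    # prophage expression status from the detect stage, if it has run
    evidence = ROOT / "detect" / "prophage_evidence.tsv"
    if evidence.exists():
        from ventphage.io import read_annotations

        coords = {
            a.gene_id: (a.contig_id, a.start, a.end)
            for a in read_annotations(study / "annotations.gff3")
            if a.feature_kind == "gene"
        }
        ev = pd.read_csv(evidence, sep="\t")
        rows = []
        for i, r in enumerate(ev.itertuples(index=False)):
            member = {
                o.orf_id for o in orfs
                if o.orf_id in coords
                and coords[o.orf_id][0] == r.contig_id
                and coords[o.orf_id][1] >= r.start
                and coords[o.orf_id][2] <= r.end
            }
            rows.append(prophage_expression(f"{r.sag_id}:candidate{i+1}",
                                            member, table))
        write_expression_summary(rows, out / "prophage_expression.tsv")
        for row in rows:
            note = "" if row.n_genes else " (no transcript data for this region)"
            print(f"  {row.candidate_name}: {row.n_expressed}/{row.n_genes} "
                  f"genes expressed -> {row.status}{note}")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
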