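#!/usr/bin/env python
"""Generate the seeded synthetic study all downstream analyses consume.

Writes a 10-SAG study (five with an implanted 20 kb prophage), one
recruitment experiment with two metagenomic islands, an MDA kinetics
table with one implanted lytic outlier, and a transcript hit table —
each with its ground-truth sidecar — under results/study/.
"""

import json
from pathlib import Path

from ventphage.io import (
    write_annotations, write_contigs, write_mda, write_recruitment,
    write_transcript_hits,
)
from ventphage.model import OrfRecord
from ventphage.simulate import (
    simulate_mda, simulate_recruitment, simulate_sag, simulate_transcripts,
)

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    contigs, annotations, truths = [], [], {}
    for i in range(10):
        sag_id = f"SAG-{i+1:03d}"
        contig, anns, truth = simulate_sag(
            length_bp=60_000, with_prophage=(i % 2 == 0), prophage_len=20_000,
            shift=0.6, seed=SEED + 97 * i, sag_id=sag_id,
        )
        contigs.append(contig)
        annotations += anns
        truths[sag_id] = {"prophage_intervals": truth.prophage_intervals}
    write_contigs(contigs, OUT / "assembly.fasta")
    write_annotations(annotations, OUT / "annotations.gff3")
    with open(OUT / "prophage_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)

    c0 = contigs[1]  # a phage-free host for the island experiment
    islands = [(12_000, 18_000), (35_000, 43_000)]
    hits, rec_truth = simulate_recruitment(c0, islands, depth=20, seed=SEED + 7)
    write_recruitment(hits, OUT / "recruitment.tsv")
    rec_truth.save(OUT / "recruitment_truth.json")

    mda_records, mda_truth = simulate_mda(
        n_sags=50, slope=-0.04, noise_sd=0.03, n_outliers=1, offset=0.2,
        seed=SEED + 11,
    )
    write_mda(mda_records, OUT / "mda.tsv")
    mda_truth.save(OUT / "mda_truth.json")

    genes = [a for a in annotations if a.feature_kind == "gene"][:40]
    orfs = [OrfRecord(a.gene_id, len(a), a.contig_id, a.start, a.end) for a in genes]
    levels = [1.0 + (i % 5) for i in range(len(orfs))]
    t_hits, t_truth = simulate_transcripts(orfs, levels, 20_000, seed=SEED + 13,
                                           decoy_frac=0.1)
    write_transcript_hits(t_hits, OUT / "transcripts.tsv")
    t_truth.save(OUT / "transcripts_truth.json")
    with open(OUT / "orfs.tsv", "w") as fh:
        fh.write("orf_id\tlength_bp\n")
        for o in orfs:
            fh.write(f"{o.orf_id}\t{o.length_bp}\n")

    n_implanted = sum(1 for t in truths.values() if t["prophage_intervals"])
    print(f"wrote 10 SAGs ({n_implanted} with implanted prophages), "
          f"{len(hits)} recruitment hits, {len(mda_records)} MDA records, "
          f"{len(t_hits)} transcript hits -> {OUT}")


if __name__ == "__main__":
    main()
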