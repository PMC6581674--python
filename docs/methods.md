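# Methods

This note records the models, thresholds and design choices behind each
stage, what the synthetic-data generators do and do not emulate, and the
package's known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All in-memory intervals are 0-based half-open; the conversion from the
1-based inclusive conventions of GFF3 and BLAST tabular happens exactly
once, at the reader boundary, and is reversed at write time. Sequences
are uppercased and non-ACGTN characters collapse to N; N-containing
k-mers are excluded from composition statistics. Minus-strand
recruitment hits (sstart > send) are normalized to start < end with an
orientation flag.

## Viral marker lexicon

Gene products are tokenized on non-alphanumeric characters and matched
case-insensitively. The default lexicon is: phage, virus, virion,
prophage, terminase, capsid, head, tail, fiber, baseplate, portal,
lysis, structural, t4, lambda, mu, lambdoid, podo\*, myovir\*,
siphovir\*. `phage` and `virus` match as token *suffixes* (so
"bacteriophage" and "myovirus" fire); terms with a trailing `*` match
token prefixes; everything else must equal a whole token, which keeps
short terms ("head", "mu", "t4") from firing inside longer words.
Integrase and transposase are excluded because both are common in
bacterial genomes unrelated to phages; an exclusion cancels only its
own match, so "phage integrase" is still phage-flagged. Token-level
matching (rather than substring matching) is a deliberate choice; the
lexicon and exclusions are overridable through the pipeline config.

## Composition anomalies

GC skew is `(G−C)/(G+C)` per window (default 1 kb window, 500 bp step);
windows without G or C get value 0 and a flag. Tetramer anomaly uses
the Manhattan (L1) distance between each window's 256-dimensional
tetranucleotide frequency vector (default 5 kb window, 1 kb step) and
the whole-contig vector, standardized to z-scores across valid windows
(≥5 valid windows required; windows with >10% N are invalid). Tetramers
are counted single-stranded by default; canonical collapsing with
reverse complements is a flag. Windowed (not cumulative) skew is the
default; cumulative skew is available as a helper.

Anomaly calling: GC-skew windows with `|value − median| > 3·MAD` and
tetramer windows with `z > 2` are flagged and merged when overlapping
or adjacent. When the MAD is exactly 0 with some nonzero residuals the
standard deviation is used instead; when all residuals are 0 nothing is
called. No calling thresholds are inherent to the statistics — all are
config-exposed.

A structural note on the z-score: with an anomalous fraction *f* of
windows, the achievable z of the anomalous group is bounded near
`sqrt((1−f)/f)` regardless of effect size, because the anomalous
windows themselves inflate the standard deviation. A 20 kb prophage in
a 60 kb contig (f ≈ ⅓) therefore cannot exceed z ≈ 1.4, and composition
evidence is expected to contribute mainly for implants occupying ≲15%
of the contig. The prophage caller does not depend on composition
evidence alone for exactly this reason.

## Prophage calling

Candidates are maximal marker-gene runs in which at least `min_markers`
(default 3) marker genes fall within any `marker_window_bp` (default
10 kb) span. The region spans first-to-last marker gene and each
boundary is extended to abut the nearest tRNA within `trna_link_bp`
(default 5 kb) — tRNAs are common integration sites, and the abutment
convention (upstream tRNA: new start = tRNA end) keeps the att-side
boundary at the integration site. Regions shorter than `min_region_len`
(default 5 kb) are dropped.

Evidence classes beyond `markers`: `trna_flank` (extension happened),
`mobility_gene` (integrase/recombinase/transposase product inside the
region), `composition_anomaly` (overlap with a called anomaly interval
by ≥50% of the smaller interval), `host_flanking` (≥2 recognizable
non-marker, non-hypothetical genes within 10 kb on *each* side).
"Hypothetical protein" genes are neutral throughout. A region is called
`prophage` with ≥2 evidence classes including markers, provided its SAG
is not an MDA lytic suspect; otherwise it stays `unresolved`. Lytic
suspicion is never a region call — it is a SAG-level diagnostic. The
thresholds codify what is, in practice, a manual multi-evidence
curation; reproducibility requires an operational rule, so every
threshold is explicit and configurable.

## Metagenomic islands

Per-base tracks record the maximum hit identity and whether any hit
with identity strictly above 75% covers the base ("not go above 75%"
is a strict inequality, so hits at exactly 75% do not count). Windows
(default 1 kb / 500 bp step) with high-identity coverage below 50% are
island windows; merged islands shorter than 2 kb are dropped and the
coverage fraction is recomputed over the merged interval. The compound
rule — coverage computed from >75%-identity hits only, island where
that coverage is <50% — captures both clauses with one condition;
evaluating the clauses independently is a config option. Window, step
and minimum length are suppression parameters for single-read gaps, not
part of the island definition.

## MDA diagnostics

Ordinary least squares of recovery on Cp (statsmodels), requiring ≥5
points and nonzero Cp variance. Outliers are flagged at |externally
studentized residual| > 2.5; only below-line flags are lytic suspects
(the mechanism is host-genome degradation with high phage DNA content,
i.e. low Cp with low recovery). Both directions are reported. The
flags are screening diagnostics, not hypothesis tests, so no
multiple-testing correction is applied across SAGs. An effectively
exact fit (residual sd < 1e-10 of the recovery scale) yields zero
studentized residuals rather than numerical blow-ups. Cp is treated as
hours throughout.

## ANI and the clock

`global_ani` performs one global alignment with free terminal gaps
(Bio.Align.PairwiseAligner; match +5, mismatch −4, gap open −12, gap
extend −3, all config-exposed — an explicit affine scheme replaces
GUI-aligner presets for reproducibility). Identity is counted over
non-terminal alignment columns, with internal gap columns counted as
non-identical; terminal-gap columns are excluded from the denominator.
`fragment_ani` reimplements the ANIb scheme: consecutive 1020 bp query
fragments locally aligned to the subject, accepted at ≥30% identity
over ≥70% of fragment length; ANI is the mean identity of accepted
fragments and the method is directional by construction. The clock is
`divergence_Myr = (100 − identity%) × rate` with rate 50 My per 1% 16S
divergence. The co-evolution comparison reports the host-minus-prophage
ANI gap per host pair and flags prophage-faster divergence when it is
positive.

## Expression

Transcript hits are kept at ≥95% amino-acid identity (inclusive
boundary); a multi-mapping fragment keeps only its best-identity hit,
ties broken to the lexicographically first ORF id (no fractional
weighting). Total mapped fragments is defined as the hits surviving the
filter across the analyzed ORF set, making the normalization
self-contained; per-sample totals are a config option. FPKM =
count / (length_kb × total_millions), so
Σ fpkm·length_kb·total_millions = total exactly. A prophage is
"expressed" when ≥1 of its genes has fpkm > 0 and "fully transcribed"
when all do.

## Synthetic data

Host genomes are order-3 Markov chains (64×4 transition matrix), which
makes tetranucleotide composition directly controllable. Genes are
tiled at ~1 gene/kb (900 bp genes, 25% hypothetical) with ≥2 tRNAs, one
of them placed in the first third of the contig so an integration site
with downstream room always exists. Prophage implants overwrite a block
downstream of a tRNA with sequence drawn from the host composition
mixed toward a strongly GC-rich alternative (mixing weight = `shift`;
at shift 0.5 the realized Manhattan separation is ≈0.5–0.6). Genes in
the block are relabeled with an integrase first (at the attachment
site), a structural gene last, and ≥6 viral products with a ~20%
hypothetical fraction in between — the standard architecture of an
annotated prophage.

Recruitment reads are 150 bp (matching 2×150 sequencing), evenly spaced
with ±3 bp jitter and pinned ends so depth ≥20 guarantees full coverage
outside islands; identity is Normal(98, 1) truncated to [90, 100]
outside islands, and inside an island either no reads map (probability
0.5 per island) or identity is Uniform(60, 75) — both regimes sit
cleanly on the low side of the 75% threshold. MDA tables draw Cp from
Uniform(2, 12) h with recovery = clip(0.9 − 0.04·Cp + N(0, 0.03²)) and
implant below-line outliers by subtracting a fixed offset. Transcript
hits are multinomial with probability ∝ level × length, identity
N(98, 1) capped at 100, plus a configurable fraction of sub-95% decoys.
Every generator is a pure function of parameters and seed, and each
dataset ships a JSON truth sidecar; accuracy checks read truth only
from it.

What the generators do **not** emulate: assembly fragmentation and
chimerism, MDA coverage bias along the genome, sequencing error
profiles and quality scores, repeat-induced misassembly at integration
sites, strain heterogeneity in recruitment, and compositional
amelioration of anciently integrated prophages. Passing tests
demonstrate that the operational rules recover truth under the stated
statistical structure, not that they match manual curation on real
SAGs.

## Problem sizes and numerical choices

The accuracy studies use 60 kb SAGs with 20 kb implants (50 positive +
50 negative) for detection, 40 kb contigs with 6–8 kb islands over 20
simulations, 50-point MDA tables over 100 simulations, 100 kb contigs
with 12 kb implants over 100 seeds for composition sensitivity (the
implant fraction is kept near 0.13 for the z-score reason above), and
alignment fixtures ≤200 bp for exact oracle comparison. These sizes
make every property measurable with comfortable margins while the whole
suite stays fast. Ties in island-window merging are resolved by
interval union; anomaly peak scores are the maximum window score over
the merged interval; degenerate inputs (empty hit tables, all-N
windows, zero totals) return empty/zero results with warnings rather
than errors wherever the contract allows.

## Known limitations

Whole-contig viral classification by homology to external viral
databases is out of scope (hit tables are consumed, not produced), as
are gene calling, read QC/assembly, phage taxonomy, CRISPR/Cas
detection and tree inference. `fragment_ani` searches the forward
strand of the subject only. The prophage caller's boundaries are
marker-span-based with tRNA abutment, not att-site detection, so exact
attL/attR resolution is beyond its stated 2 kb tolerance by design.
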