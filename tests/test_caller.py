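"""Prophage candidate calling, evidence collection and lifestyle calls."""

import numpy as np

from ventphage.caller import (
    CallerParams,
    ProphageCandidate,
    call_candidate_regions,
    call_candidate_regions as _call,
    classify_lifestyle,
    collect_evidence,
)
from ventphage.composition import AnomalyInterval
from ventphage.markers import scan_annotations
from ventphage.model import ContigRecord, overlap_len
from ventphage.pipeline import detect_prophages
from tests.conftest import make_gene


def _contig(length=50_000, contig_id="c1", sag_id="S1"):
    rng = np.random.default_rng(0)
    return ContigRecord(contig_id, "".join(rng.choice(list("ACGT"), length)), sag_id)


def _marker_genes(starts, contig="c1"):
    return [
        make_gene(contig, s, s + 900, product="major capsid protein", gene_id=f"m{s}")
        for s in starts
    ]


class TestCandidateCalling:
    def test_cluster_of_five_markers_without_trna(self):
        contig = _contig()
        anns = _marker_genes([10_000, 12_000, 14_000, 16_000, 17_500])
        cands = _call(contig, anns, scan_annotations(anns))
        assert len(cands) == 1
        c = cands[0]
        assert (c.start, c.end) == (10_000, 18_400)
        assert c.marker_gene_count == 5
        assert c.evidence == frozenset({"markers"})

    def test_two_distant_markers_below_threshold(self):
        contig = _contig()
        anns = _marker_genes([5_000, 35_000])
        assert _call(contig, anns, scan_annotations(anns)) == []

    def test_trna_extension_upstream(self):
        contig = _contig()
        trna = make_gene("c1", 7_900, 7_975, product="tRNA-Leu", kind="tRNA",
                         gene_id="t1")
        anns = [trna] + _marker_genes([10_000, 12_000, 14_000, 16_000])
        cands = _call(contig, anns, scan_annotations(anns))
        assert len(cands) == 1
        c = cands[0]
        assert c.start == 7_975  # extended to abut the tRNA
        assert "trna_flank" in c.evidence

    def test_short_region_dropped(self):
        contig = _contig()
        anns = _marker_genes([10_000, 10_950, 11_900])  # span < 5 kb
        assert _call(contig, anns, scan_annotations(anns)) == []

    def test_lowering_min_markers_is_monotone(self, prophage_sag):
        contig, anns, _ = prophage_sag
        hits = scan_annotations(anns)
        strict = _call(contig, anns, hits, CallerParams(min_markers=4))
        loose = _call(contig, anns, hits, CallerParams(min_markers=3))
        for c in strict:
            assert any(
                overlap_len(c.start, c.end, l.start, l.end) > 0 for l in loose
            )


class TestEvidence:
    def _candidate(self, start=10_000, end=20_000):
        return ProphageCandidate("c1", start, end, 4, frozenset({"markers"}),
                                 sag_id="S1")

    def test_integrase_adds_mobility_gene(self):
        anns = _marker_genes([10_000, 12_000]) + [
            make_gene("c1", 14_000, 14_900, product="site-specific integrase")
        ]
        c = collect_evidence(self._candidate(), anns, [])
        assert "mobility_gene" in c.evidence

    def test_region_inside_anomaly_interval(self):
        iv = AnomalyInterval("c1", 8_000, 22_000, "tetramer", 3.2)
        c = collect_evidence(self._candidate(), [], [iv])
        assert "composition_anomaly" in c.evidence

    def test_half_overlap_rule(self):
        # overlap 4 kb < 50% of the 10 kb candidate and of the 9 kb interval
        iv = AnomalyInterval("c1", 16_000, 25_000, "tetramer", 3.0)
        c = collect_evidence(self._candidate(), [], [iv])
        assert "composition_anomaly" not in c.evidence

    def test_host_flanking_requires_both_sides(self):
        host_left = [
            make_gene("c1", 1_000, 1_900, product="elongation factor Tu"),
            make_gene("c1", 3_000, 3_900, product="ribosomal protein L2"),
        ]
        host_right = [
            make_gene("c1", 21_000, 21_900, product="chaperonin GroEL"),
            make_gene("c1", 23_000, 23_900, product="ATP synthase F1 subunit beta"),
        ]
        c = collect_evidence(self._candidate(), host_left + host_right, [])
        assert "host_flanking" in c.evidence
        c_edge = collect_evidence(self._candidate(), host_left, [])
        assert "host_flanking" not in c_edge.evidence

    def test_hypothetical_genes_are_neutral(self):
        fillers = [
            make_gene("c1", s, s + 900) for s in (1_000, 3_000, 21_000, 23_000)
        ]
        c = collect_evidence(self._candidate(), fillers, [])
        assert "host_flanking" not in c.evidence


class TestLifestyle:
    def _cand(self, evidence, sag="S1"):
        return ProphageCandidate("c1", 0, 10_000, 3, frozenset(evidence), sag_id=sag)

    def test_two_evidence_classes_and_no_outlier_is_prophage(self):
        (c,) = classify_lifestyle([self._cand({"markers", "trna_flank"})], {})
        assert c.lifestyle_call == "prophage"

    def test_single_class_unresolved(self):
        (c,) = classify_lifestyle([self._cand({"markers"})], {})
        assert c.lifestyle_call == "unresolved"

    def test_mda_outlier_vetoes(self):
        (c,) = classify_lifestyle(
            [self._cand({"markers", "mobility_gene"})], {"S1": True}
        )
        assert c.lifestyle_call == "unresolved"


def test_detect_is_deterministic(prophage_sag, tmp_path):
    """Identical inputs give byte-identical evidence tables."""
    from ventphage.caller import write_evidence_table

    contig, anns, _ = prophage_sag
    outputs = []
    for run in range(2):
        cands, _summary = detect_prophages([contig], anns)
        path = tmp_path / f"run{run}.tsv"
        write_evidence_table(cands, path)
        outputs.append(path.read_bytes())
    assert outputs[0] == outputs[1]


def test_implanted_prophage_recovered(prophage_sag):
    contig, anns, truth = prophage_sag
    (iv,) = truth.prophage_intervals[contig.contig_id]
    cands, summary = detect_prophages([contig], anns)
    called = [c for c in cands if c.lifestyle_call == "prophage"]
    assert len(called) == 1
    c = called[0]
    assert abs(c.start - iv[0]) <= 2000 and abs(c.end - iv[1]) <= 2000
    assert summary[contig.sag_id] == "prophage-bearing"


def test_no_calls_on_phage_free_sag(clean_sag):
    contig, anns, _ = clean_sag
    cands, summary = detect_prophages([contig], anns)
    assert cands == []
    assert summary[contig.sag_id] == "none"
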