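"""GC skew, tetramer profiles and anomaly calling."""

import numpy as np
import pytest

from ventphage.composition import (
    WindowProfile,
    anomalous_windows,
    gc_skew_profile,
    tetramer_anomaly,
    tetramer_profile,
)
from ventphage.model import overlap_len
from ventphage.simulate import implant_prophage, simulate_host_genome
from tests.oracles import naive_tetramer_freqs

BASES = "ACGT"
COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def _kmer_index(kmer: str) -> int:
    idx = 0
    for c in kmer:
        idx = idx * 4 + BASES.index(c)
    return idx


class TestGcSkew:
    def test_pure_g_then_pure_c_windows(self):
        prof = gc_skew_profile("GGGGGCCCCC", window=5, step=5)
        assert [p.value for p in prof] == [1.0, -1.0]

    def test_no_gc_flagged_zero_denominator(self):
        prof = gc_skew_profile("ATATATATAT", window=5, step=5)
        assert [p.value for p in prof] == [0.0, 0.0]
        assert all(p.zero_denominator for p in prof)

    def test_reverse_complement_negates_and_reverses(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(BASES), 4000))
        fwd = gc_skew_profile(seq, window=500, step=500)
        rev = gc_skew_profile(_revcomp(seq), window=500, step=500)
        assert np.allclose([p.value for p in rev],
                           [-p.value for p in reversed(fwd)])

    def test_short_sequence_single_window_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than window"):
            prof = gc_skew_profile("ACGTACGT", window=100, step=50)
        assert len(prof) == 1 and (prof[0].start, prof[0].end) == (0, 8)

    def test_high_n_windows_invalid(self):
        prof = gc_skew_profile("N" * 500 + "ACGT" * 125, window=500, step=500)
        assert not prof[0].valid and prof[1].valid


class TestTetramerProfile:
    def test_homopolymer(self):
        v = tetramer_profile("AAAAA")
        assert v[_kmer_index("AAAA")] == 1.0 and v.sum() == 1.0

    def test_hand_enumeration(self):
        v = tetramer_profile("ACGTACGT")
        assert v[_kmer_index("ACGT")] == pytest.approx(0.4)
        for k in ("CGTA", "GTAC", "TACG"):
            assert v[_kmer_index(k)] == pytest.approx(0.2)

    def test_sums_to_one_and_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            seq = "".join(rng.choice(list("ACGTN"), 800, p=[0.24] * 4 + [0.04]))
            vec = tetramer_profile(seq)
            assert abs(vec.sum() - 1.0) < 1e-12
            assert np.allclose(vec, naive_tetramer_freqs(seq))

    def test_all_masked_errors(self):
        with pytest.raises(ValueError, match="too short/masked"):
            tetramer_profile("NNNNNNNN")

    def test_manhattan_distance_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(2)
        genome = "".join(rng.choice(list(BASES), 3000))
        window = genome[500:1500]
        d_fwd = np.abs(tetramer_profile(window) - tetramer_profile(genome)).sum()
        d_rev = np.abs(
            tetramer_profile(_revcomp(window)) - tetramer_profile(_revcomp(genome))
        ).sum()
        assert d_fwd == pytest.approx(d_rev, abs=1e-12)


class TestTetramerAnomaly:
    def test_tandem_repeat_gives_zero_z(self):
        rng = np.random.default_rng(3)
        unit = "".join(rng.choice(list(BASES), 5000))
        prof = tetramer_anomaly(unit * 8, window=5000, step=5000)
        assert all(p.value == 0.0 for p in prof if p.valid)

    def test_implanted_block_has_max_z(self):
        contig, anns = simulate_host_genome(50_000, seed=4)
        contig, anns, (s, e) = implant_prophage(contig, anns, 10_000, shift=0.8, seed=5)
        prof = tetramer_anomaly(contig.sequence)
        best = max((p for p in prof if p.valid), key=lambda p: p.value)
        assert overlap_len(best.start, best.end, s, e) > 0

    def test_too_few_windows_marked_unavailable(self):
        with pytest.warns(UserWarning, match="z-scores unavailable"):
            prof = tetramer_anomaly("ACGT" * 2000, window=5000, step=5000)
        assert all(not p.valid for p in prof)


class TestAnomalousWindows:
    @staticmethod
    def _zprof(values, window=1000):
        return [
            WindowProfile("c1", i * window, (i + 1) * window, v)
            for i, v in enumerate(values)
        ]

    def test_flat_profile_no_calls(self):
        assert anomalous_windows(self._zprof([0.3] * 10), "gc_skew") == []

    def test_single_hot_window(self):
        calls = anomalous_windows(self._zprof([0, 0.1, 5.0, -0.1, 0, 0]), "tetramer", 2.0)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (2000, 3000)
        assert calls[0].peak_score == pytest.approx(5.0)

    def test_adjacent_windows_merge(self):
        calls = anomalous_windows(
            self._zprof([0, 4.0, 5.0, 0, 0, 0]), "tetramer", 2.0
        )
        assert len(calls) == 1 and (calls[0].start, calls[0].end) == (1000, 3000)
        assert calls[0].peak_score == pytest.approx(5.0)

    def test_gc_skew_mad_calls_outlier_window(self):
        values = [0.01, -0.02, 0.0, 0.01, -0.01, 0.9, 0.0, 0.02]
        calls = anomalous_windows(self._zprof(values), "gc_skew", 3.0)
        assert len(calls) == 1 and calls[0].start == 5000

    def test_all_invalid_profile_warns_empty(self):
        prof = [WindowProfile("c1", 0, 1000, float("nan"), valid=False)]
        with pytest.warns(UserWarning):
            assert anomalous_windows(prof, "tetramer") == []


def test_block_sensitivity_on_seeded_implants():
    """Compositionally shifted blocks ≥2 windows long are recovered."""
    found = 0
    for seed in range(10):
        contig, anns = simulate_host_genome(100_000, seed=seed)
        contig, anns, (s, e) = implant_prophage(contig, anns, 12_000, shift=0.5,
                                                seed=seed + 100)
        calls = anomalous_windows(tetramer_anomaly(contig.sequence), "tetramer")
        found += any(overlap_len(c.start, c.end, s, e) > 0 for c in calls)
    assert found >= 9
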