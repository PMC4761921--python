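"""Promoter windows, TSS correction, regulator assignment, motifs, BED I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import circamir as cm
from circamir.network import (
    BindingCall,
    GenomicInterval,
    TranscriptModel,
    read_peaks_bed,
    read_transcripts_bed12,
    write_peaks_bed,
    write_transcripts_bed12,
)


def _tx(tid, start, end, strand="+", chrom="chr1"):
    return TranscriptModel(id=tid, interval=GenomicInterval(chrom, start, end, strand))


class TestPromoterWindow:
    def test_plus_strand(self):
        w = cm.promoter_window(_tx("t", 10000, 20000, "+"))
        assert (w.start, w.end) == (5000, 20000)

    def test_minus_strand(self):
        w = cm.promoter_window(_tx("t", 10000, 20000, "-"))
        assert (w.start, w.end) == (10000, 25000)

    def test_clipped_at_zero(self):
        w = cm.promoter_window(_tx("t", 3000, 9000, "+"))
        assert (w.start, w.end) == (0, 9000)

    @given(
        start=st.integers(0, 10**6),
        length=st.integers(1, 10**5),
        upstream=st.integers(0, 10**4),
        strand=st.sampled_from(["+", "-"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_window_length_property(self, start, length, upstream, strand):
        t = _tx("t", start, start + length, strand)
        w = cm.promoter_window(t, upstream)
        available = start if strand == "+" else upstream
        assert len(w) == length + min(upstream, available if strand == "+" else upstream)


class TestCorrectTss:
    H3 = [GenomicInterval("chr1", 9000, 11000)]
    POL = [GenomicInterval("chr1", 9500, 10500)]

    def test_both_marks_unchanged(self):
        t = _tx("t", 10000, 20000, "+")
        out = cm.correct_tss(t, self.H3, self.POL)
        assert out.tss_status == "h3k4me3_and_polii"
        assert out.interval == t.interval

    def test_h3k4me3_only(self):
        t = _tx("t", 10000, 20000, "+")
        out = cm.correct_tss(t, self.H3, [])
        assert out.tss_status == "h3k4me3_only"
        assert out.interval == t.interval

    def test_corrects_to_peak_center(self):
        t = _tx("t", 10000, 20000, "+")
        h3_far = [GenomicInterval("chr1", 7000, 7500)]  # outside the 5'-end window
        out = cm.correct_tss(t, h3_far, [], max_distance=20000)
        assert out.tss_status == "corrected"
        assert out.interval.start == 7250
        assert out.interval.end == 20000

    def test_minus_strand_correction(self):
        t = _tx("t", 10000, 20000, "-")
        h3 = [GenomicInterval("chr1", 30000, 30500)]
        out = cm.correct_tss(t, h3, [], max_distance=20000)
        assert out.tss_status == "corrected"
        assert out.five_prime == 30250
        assert out.interval.start == 10000

    def test_fallback_to_polii_and_uncorrectable(self):
        t = _tx("t", 50000, 60000, "+")
        pol = [GenomicInterval("chr1", 40000, 40500)]
        out = cm.correct_tss(t, [], pol, max_distance=20000)
        assert out.tss_status == "corrected"
        assert out.interval.start == 40250
        far = [GenomicInterval("chr1", 1000, 1200)]
        out2 = cm.correct_tss(t, far, [], max_distance=5000)
        assert out2.tss_status == "uncorrectable"
        assert out2.interval == t.interval

    def test_equidistant_ties_break_upstream_and_idempotent(self):
        t = _tx("t", 10000, 20000, "+", chrom="chrX")
        up = GenomicInterval("chrX", 6900, 7100)  # center 7000, 3 kb upstream
        down = GenomicInterval("chrX", 12900, 13100)  # center 13000, 3 kb downstream
        out = cm.correct_tss(t, [up, down], [], max_distance=20000)
        assert out.interval.start == 7000  # upstream wins the tie
        again = cm.correct_tss(out, [up, down], [], max_distance=20000)
        assert again.interval == out.interval  # coordinates are a fixed point
        assert again.tss_status == "h3k4me3_only"

    def test_exhaustive_small_cases_vs_naive_scan(self, rng):
        """Random small instances: chosen anchor equals a naive nearest-peak
        scan with explicit upstream tie-break."""
        for _ in range(50):
            start = int(rng.integers(20000, 30000))
            t = _tx("t", start, start + int(rng.integers(1000, 5000)), "+")
            peaks = [
                GenomicInterval(
                    "chr1", s := int(rng.integers(0, 60000)), s + int(rng.integers(100, 500))
                )
                for _ in range(int(rng.integers(1, 6)))
            ]
            out = cm.correct_tss(t, peaks, [], tss_window=1000, max_distance=15000)
            five = t.five_prime
            overlapping = [
                p for p in peaks if p.start < five + 1000 and five - 1000 < p.end
            ]
            if overlapping:
                assert out.tss_status == "h3k4me3_only"
                assert out.interval == t.interval
                continue
            candidates = [
                ((p.start + p.end) // 2) for p in peaks
                if abs((p.start + p.end) // 2 - five) <= 15000
                and (p.start + p.end) // 2 < t.interval.end
            ]
            if not candidates:
                assert out.tss_status == "uncorrectable"
                continue
            dmin = min(abs(c - five) for c in candidates)
            best = min(c for c in candidates if abs(c - five) == dmin)  # upstream on +
            assert out.interval.start == best


def _brute_force_edges(transcripts, calls, support_rule, default_support, upstream):
    edges = set()
    for c in calls:
        need = support_rule.get(c.regulator, default_support)
        if c.n_supporting_datasets < need:
            continue
        for t in transcripts:
            w = cm.promoter_window(t, upstream)
            if w.overlaps(c.interval):
                edges.add((c.regulator, t.id))
    return pd.DataFrame(sorted(edges), columns=["regulator", "transcript"])


class TestAssignRegulators:
    def test_bmal1_two_dataset_rule(self):
        t = _tx("t1", 10000, 20000, "+")
        peak = GenomicInterval("chr1", 8000, 8200)
        weak = BindingCall("BMAL1", peak, n_supporting_datasets=1)
        strong = BindingCall("BMAL1", peak, n_supporting_datasets=2)
        assert cm.assign_regulators([t], [weak]).empty
        edges = cm.assign_regulators([t], [strong])
        assert list(edges.itertuples(index=False, name=None)) == [("BMAL1", "t1")]

    def test_other_regulators_need_one_dataset(self):
        t = _tx("t1", 10000, 20000, "+")
        call = BindingCall("PER1", GenomicInterval("chr1", 8000, 8200), 1)
        assert len(cm.assign_regulators([t], [call])) == 1

    def test_abutting_peak_is_not_overlap(self):
        t = _tx("t1", 10000, 20000, "+")
        # promoter window is [5000, 20000); peak ending exactly at 5000 abuts
        call = BindingCall("CLOCK", GenomicInterval("chr1", 4800, 5000), 1)
        assert cm.assign_regulators([t], [call]).empty
        inside = BindingCall("CLOCK", GenomicInterval("chr1", 4800, 5001), 1)
        assert len(cm.assign_regulators([t], [inside])) == 1

    def test_unknown_regulator_without_default_errors(self):
        t = _tx("t1", 10000, 20000, "+")
        call = BindingCall("MYSTERY", GenomicInterval("chr1", 8000, 8200), 1)
        with pytest.raises(KeyError, match="MYSTERY"):
            cm.assign_regulators([t], [call], default_support=None)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        transcripts = [
            _tx(
                f"t{i}",
                s := int(rng.integers(0, 200000)),
                s + int(rng.integers(500, 20000)),
                "+" if rng.random() < 0.5 else "-",
                chrom=f"chr{rng.integers(1, 3)}",
            )
            for i in range(15)
        ]
        calls = [
            BindingCall(
                str(rng.choice(["BMAL1", "CLOCK", "PER1"])),
                GenomicInterval(
                    f"chr{rng.integers(1, 3)}",
                    s := int(rng.integers(0, 220000)),
                    s + int(rng.integers(100, 2000)),
                ),
                int(rng.integers(1, 7)),
            )
            for _ in range(40)
        ]
        got = cm.assign_regulators(transcripts, calls)
        want = _brute_force_edges(transcripts, calls, {"BMAL1": 2}, 1, 5000)
        pd.testing.assert_frame_equal(got.reset_index(drop=True), want)

    def test_zero_edges_when_no_overlap(self):
        txs = [_tx("t1", 100000, 110000, "+")]
        calls = [BindingCall("CLOCK", GenomicInterval("chr1", 0, 50), 1)]
        assert cm.assign_regulators(txs, calls).empty


class TestBindingEnrichment:
    def test_identical_fractions_p_one(self):
        txs = [_tx(f"t{i}", 10000 + 50000 * i, 20000 + 50000 * i) for i in range(10)]
        edges = pd.DataFrame(
            {"regulator": ["CLOCK"] * 4, "transcript": [t.id for t in txs[:4]]}
        )
        circ = [t.id for t in txs[:5]]
        res = cm.binding_enrichment(circ, [t.id for t in txs], edges, "PER1")
        assert res.p_value == pytest.approx(1.0)  # zero bound in both sets

    def test_circadian_equals_universe_p_one(self):
        ids = [f"t{i}" for i in range(8)]
        edges = pd.DataFrame({"regulator": ["CLOCK"] * 3, "transcript": ids[:3]})
        res = cm.binding_enrichment(ids, ids, edges, "CLOCK")
        assert res.p_value == pytest.approx(1.0)

    def test_subset_violation_errors(self):
        with pytest.raises(ValueError, match="subset"):
            cm.binding_enrichment(["a", "zzz"], ["a", "b"], pd.DataFrame({"regulator": [], "transcript": []}), "CLOCK")


class TestBuildMotifs:
    GROUPS = pd.Series({"Gadd45a": "I", "Por": "I", "Cdkn1a": "III", "Bcl2": "III", "X": "none"})
    MIRNA = pd.DataFrame(
        {"mirna": ["miR-378"] * 5, "target": ["Gadd45a", "Por", "Cdkn1a", "Bcl2", "X"]}
    )

    def test_type1_bmal1_clock_on_group_i(self):
        tf = pd.DataFrame({"tf": ["BMAL1", "CLOCK"], "target": ["Gadd45a", "Por"], "functional": [True, True]})
        motifs = cm.build_motifs(tf, self.MIRNA, self.GROUPS)
        assert [(m.motif_type, m.target) for m in motifs] == [(1, "Gadd45a"), (1, "Por")]
        assert all(m.tf_set == "BMAL1/CLOCK" for m in motifs)

    def test_type2_reverb_on_group_iii(self):
        tf = pd.DataFrame({"tf": ["REV-ERBA", "REV-ERBB"], "target": ["Cdkn1a", "Bcl2"], "functional": [True, True]})
        motifs = cm.build_motifs(tf, self.MIRNA, self.GROUPS)
        assert [(m.motif_type, m.target) for m in motifs] == [(2, "Bcl2"), (2, "Cdkn1a")]
        assert all(m.tf_set == "REV-ERBa/b" for m in motifs)

    def test_functional_flag_required(self):
        tf = pd.DataFrame({"tf": ["BMAL1"], "target": ["Por"], "functional": [False]})
        assert cm.build_motifs(tf, self.MIRNA, self.GROUPS) == []

    def test_wrong_group_tf_pairing_excluded(self):
        # BMAL1 on a Group III gene forms no motif; neither does REV-ERB on Group I
        tf = pd.DataFrame({"tf": ["BMAL1", "REV-ERBA"], "target": ["Cdkn1a", "Por"], "functional": [True, True]})
        assert cm.build_motifs(tf, self.MIRNA, self.GROUPS) == []

    def test_empty_mirna_edges(self):
        tf = pd.DataFrame({"tf": ["BMAL1"], "target": ["Por"], "functional": [True]})
        assert cm.build_motifs(tf, pd.DataFrame(columns=["mirna", "target"]), self.GROUPS) == []


class TestBedIo:
    def test_peaks_roundtrip(self, tmp_path):
        calls = [
            BindingCall("BMAL1", GenomicInterval("chr1", 100, 400), 3),
            BindingCall("CLOCK", GenomicInterval("chr2", 0, 50), 1),
        ]
        p = tmp_path / "peaks.bed"
        write_peaks_bed(calls, p)
        back = read_peaks_bed(p)
        assert back == calls

    def test_transcripts_roundtrip(self, tmp_path):
        txs = [_tx("tx1", 1000, 9000, "+"), _tx("tx2", 500, 600, "-")]
        p = tmp_path / "tx.bed"
        write_transcripts_bed12(txs, p)
        back = read_transcripts_bed12(p)
        assert [(t.id, t.interval) for t in back] == [(t.id, t.interval) for t in txs]
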