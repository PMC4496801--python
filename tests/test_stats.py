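"""Per-SF accounting, completeness filter, WGS correction, region stats."""

import numpy as np
import pytest

from alphaclass.annotator import AnnotationRecord
from alphaclass.stats import (
    corrected_profile,
    end_trim,
    filter_complete,
    read_set_summary,
    region_stats,
    summarize,
)
from alphaclass.synth import BlockSpec, LayoutSpec, build_genome, simulate_reads


def rec(start, end, label, seq_id="c", box="A", strand="+", post=1.0):
    return AnnotationRecord(seq_id, start, end, label, box, strand, post)


class TestSummarize:
    def test_sf1_byte_count(self):
        records = [rec(i * 171, (i + 1) * 171, "J1") for i in range(10)]
        records += [rec(2000 + i * 171, 2000 + (i + 1) * 171, "J2") for i in range(10)]
        s = summarize(records, total_bp=10000)
        assert s.per_sf_bp["SF1"] == 3420
        assert all(s.per_sf_bp[sf] == 0 for sf in ("SF2", "SF3", "SF5", "SF4+"))
        assert s.unclassed_fraction == 0.0
        assert s.mean_monomer_length == 171.0

    def test_empty(self):
        s = summarize([], total_bp=100)
        assert s.n_monomers == 0 and s.total_as_bp == 0
        assert s.as_fraction == 0.0

    def test_per_sf_sums_to_total(self):
        records = [rec(0, 171, "J1"), rec(200, 340, "R1"), rec(400, 460, "Um")]
        s = summarize(records, 1000)
        assert sum(s.per_sf_bp.values()) == s.total_as_bp
        assert s.unclassed_fraction == pytest.approx(1 / 3)


class TestFilterComplete:
    def test_boundary(self):
        records = [rec(0, 139, "J1"), rec(200, 340, "J1"), rec(400, 571, "J1")]
        kept = filter_complete(records)
        assert [r.length for r in kept] == [140, 171]

    def test_filter_never_increases_totals(self):
        rng = np.random.default_rng(60)
        records = [
            rec(i * 200, i * 200 + int(rng.integers(50, 180)), "R1")
            for i in range(50)
        ]
        raw = summarize(records, 100000)
        filt = summarize(filter_complete(records), 100000)
        for sf in raw.per_sf_bp:
            assert filt.per_sf_bp[sf] <= raw.per_sf_bp[sf]


class TestCorrectedProfile:
    def test_proportions_applied(self):
        raw = summarize(
            [rec(0, 100, "J1"), rec(200, 300, "D1"), rec(400, 500, "R1"),
             rec(600, 700, "Um")],
            10000,
        )
        filtered = summarize(
            [rec(0, 171, "J1"), rec(200, 371, "J1"), rec(400, 571, "D1")], 10000
        )
        # filtered proportions: SF1 2/3, SF2 1/3 of 513 bp
        out = corrected_profile(raw, filtered)
        assert out.total_as_bp == raw.total_as_bp
        assert out.per_sf_bp["SF1"] == pytest.approx(400 * 2 / 3, abs=1)
        assert out.per_sf_bp["SF2"] == pytest.approx(400 / 3, abs=1)

    def test_identity_when_filtered_equals_raw(self):
        records = [rec(0, 171, "J1"), rec(200, 371, "R2")]
        raw = summarize(records, 1000)
        out = corrected_profile(raw, raw)
        assert out.per_sf_bp["SF1"] == raw.per_sf_bp["SF1"]
        assert out.per_sf_bp["SF5"] == raw.per_sf_bp["SF5"]

    def test_total_conserved_exactly(self):
        rng = np.random.default_rng(61)
        labels = ["J1", "D2", "W3", "R1", "M1", "Um"]
        records = [
            rec(i * 300, i * 300 + int(rng.integers(60, 180)),
                labels[int(rng.integers(len(labels)))])
            for i in range(200)
        ]
        raw = summarize(records, 10 ** 6)
        filtered = summarize(filter_complete(records), 10 ** 6)
        out = corrected_profile(raw, filtered)
        assert sum(out.per_sf_bp.values()) == raw.total_as_bp

    def test_zero_filtered_rejected(self):
        raw = summarize([rec(0, 171, "J1")], 1000)
        empty = summarize([], 1000)
        with pytest.raises(ValueError):
            corrected_profile(raw, empty)


class TestEndTrim:
    def test_basic(self):
        assert len(end_trim("A" * 500, n_bases=50)) == 400

    def test_zero_is_identity(self):
        assert end_trim("ACGTACGT", n_bases=0) == "ACGTACGT"

    def test_overtrim_empties(self):
        assert end_trim("ACGT", n_bases=3) == ""

    def test_quality_aware_extension(self):
        read = "ACGTACGTACGT"
        quals = [5, 5, 30, 30, 30, 30, 30, 30, 30, 30, 5, 5]
        assert end_trim(read, qualities=quals, n_bases=1) == read[2:10]


class TestReadSetSummary:
    def test_genome_normalization(self):
        records = [rec(0, 146, "J1")] * 100
        s = read_set_summary(records, n_reads=10, total_read_bp=7000 * 10,
                             genome_size=3e9)
        # 100 monomers * 146 bp * (3e9 / 7e4) / 1e6 Mb
        assert s.mb_per_genome == pytest.approx(100 * 146 * (3e9 / 7e4) / 1e6)


class TestRegionStats:
    def test_mask_corrects_size_and_fractions_count_monomers(self):
        records = [
            rec(100, 271, "R2"), rec(280, 451, "R2"), rec(460, 631, "R1", box="B"),
            rec(5100, 5271, "J1"),
        ]
        regions = [("c", 0, 1000)]
        mask = [("c", 700, 900)]
        df = region_stats(records, regions, mask)
        row = df.iloc[0]
        assert row["corrected_size_bp"] == 800
        assert row["n_monomers"] == 3
        assert row["r2_pct"] == pytest.approx(200 / 3)
        assert row["bbox_pct"] == pytest.approx(100 / 3)
        assert row["sf5_pct"] == pytest.approx(100.0)


class TestPlantedMixRecovery:
    def test_sf_proportions_recovered_within_2pct(self, annotator):
        """60/25/15 SF1/SF2/SF5 planted bp mix is recovered from the track."""
        spec = LayoutSpec(
            blocks=[
                BlockSpec("dimeric_sf1", 120, divergence_pct=5.0),
                BlockSpec("dimeric_sf2", 50, divergence_pct=5.0),
                BlockSpec("irregular_sf5", 30, divergence_pct=5.0),
            ],
            flank_len=3000,
            spacer_len=2000,
            seed=62,
        )
        genome, truth = build_genome(spec)
        records = annotator.annotate({"c": genome})
        s = summarize(records, len(genome))
        props = s.sf_proportions()
        truth_bp = {"SF1": 0, "SF2": 0, "SF5": 0}
        sf_of_label = {"J1": "SF1", "J2": "SF1", "D1": "SF2", "D2": "SF2",
                       "R1": "SF5", "R2": "SF5"}
        for t in truth.monomers:
            truth_bp[sf_of_label[t.label]] += t.end - t.start
        total = sum(truth_bp.values())
        for sf in truth_bp:
            assert props[sf] == pytest.approx(truth_bp[sf] / total, abs=0.02)


class TestFragmentedReads:
    def test_140bp_filter_reduces_unclassed_fraction(self, annotator):
        """Read-end truncation and bad-end noise inflate Um/Xm; filtering
        for complete monomers strictly reduces the unclassed fraction."""
        spec = LayoutSpec(
            blocks=[
                BlockSpec("dimeric_sf1", 120, divergence_pct=8.0),
                BlockSpec("irregular_sf5", 120, divergence_pct=8.0),
            ],
            flank_len=500,
            spacer_len=500,
            seed=63,
        )
        genome, _ = build_genome(spec)
        reads = simulate_reads(genome, n_reads=60, read_len=700, rng=64)
        records = []
        for i, read in enumerate(reads):
            records.extend(annotator.annotate({f"read{i}": read}))
        raw = summarize(records, sum(map(len, reads)))
        filt = summarize(filter_complete(records), sum(map(len, reads)))
        assert raw.unclassed_fraction > 0
        assert filt.unclassed_fraction < raw.unclassed_fraction

    def test_trim_plus_filter_raises_mean_monomer_length(self, annotator):
        """Bad-end trimming combined with the 140 bp filter (the corrected
        WGS protocol) raises the mean monomer length over the raw calls."""
        spec = LayoutSpec(
            blocks=[BlockSpec("dimeric_sf2", 150, divergence_pct=5.0)],
            flank_len=200,
            spacer_len=0,
            seed=65,
        )
        genome, _ = build_genome(spec)
        reads = simulate_reads(genome, n_reads=40, read_len=700, rng=66)

        def annotate_all(read_list):
            recs = []
            for i, read in enumerate(read_list):
                recs.extend(annotator.annotate({f"r{i}": read}))
            return recs

        raw = summarize(annotate_all(reads), 1)
        corrected_records = filter_complete(
            annotate_all([end_trim(r, n_bases=60) for r in reads])
        )
        corrected = summarize(corrected_records, 1)
        assert corrected.mean_monomer_length > raw.mean_monomer_length
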