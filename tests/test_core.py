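"""Interval algebra and file I/O round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopevo.core import (BedpeRecord, GenomeInterval, Peak, SignalTrack,
                          merge_peaks, read_bedpe, read_chain, read_peaks,
                          write_bedpe, write_chain, write_peaks)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestReadPeaks:
    def test_narrowpeak_summit_is_start_plus_offset(self, tmp_path):
        path = _write(tmp_path, "a.narrowPeak",
                      "chr1\t100\t200\tp1\t0\t.\t5.0\t-1\t-1\t40\n")
        (peak,) = read_peaks(path, "narrowPeak")
        assert peak.summit == 140
        assert peak.signal == 5.0

    def test_broadpeak_summit_is_midpoint(self, tmp_path):
        path = _write(tmp_path, "a.broadPeak",
                      "chr1\t100\t201\tp1\t0\t.\t5.0\t-1\t-1\n")
        (peak,) = read_peaks(path, "broadPeak")
        assert peak.summit == 150

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert read_peaks(_write(tmp_path, "e.narrowPeak", "")) == []

    def test_malformed_row_names_line_number(self, tmp_path):
        path = _write(tmp_path, "bad.narrowPeak",
                      "chr1\t0\t10\tp\t0\t.\t1\t-1\t-1\t5\nchr1\t0\tbad\n")
        with pytest.raises(ValueError, match=":2"):
            read_peaks(path)

    def test_negative_summit_offset_rejected(self, tmp_path):
        path = _write(tmp_path, "neg.narrowPeak",
                      "chr1\t0\t10\tp\t0\t.\t1\t-1\t-1\t-1\n")
        with pytest.raises(ValueError, match="summit"):
            read_peaks(path)


def _pk(start, end, summit, signal=1.0, chrom="chr1"):
    return Peak(GenomeInterval(chrom, start, end), signal, summit)


class TestMergePeaks:
    def test_overlapping_pair_merges_with_centroid_summit(self):
        (m,) = merge_peaks([_pk(0, 100, 50, 2.0), _pk(80, 200, 150, 7.0)])
        assert (m.interval.start, m.interval.end) == (0, 200)
        assert m.summit == 100          # centroid of 50 and 150
        assert m.signal == 7.0          # max of constituents

    def test_single_peak_unchanged(self):
        p = _pk(10, 20, 15)
        (m,) = merge_peaks([p])
        assert m.interval == p.interval and m.summit == p.summit

    def test_disjoint_peaks_sorted(self):
        out = merge_peaks([_pk(500, 600, 550), _pk(0, 100, 50, chrom="chr2"),
                           _pk(100, 200, 150)])
        keys = [(m.interval.chrom, m.interval.start) for m in out]
        assert keys == sorted(keys) and len(out) == 3

    def test_bookended_peaks_merge(self):
        (m,) = merge_peaks([_pk(0, 100, 50), _pk(100, 200, 150)])
        assert (m.interval.start, m.interval.end) == (0, 200)

    @given(st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 80)), max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_coverage_preserving(self, raw):
        peaks = [_pk(s, s + l, s + l // 2) for s, l in raw]
        once = merge_peaks(peaks)
        assert merge_peaks(once) == once
        covered = set()
        for p in peaks:
            covered |= set(range(p.interval.start, p.interval.end))
        merged_cov = set()
        for m in once:
            merged_cov |= set(range(m.interval.start, m.interval.end))
        assert merged_cov >= covered

    def test_output_non_overlapping_non_abutting(self):
        rng = np.random.default_rng(0)
        peaks = [_pk(int(s), int(s) + int(l), int(s) + int(l) // 2)
                 for s, l in zip(rng.integers(0, 1000, 50),
                                 rng.integers(1, 100, 50))]
        out = merge_peaks(peaks)
        for a, b in zip(out, out[1:]):
            assert a.interval.end < b.interval.start


class TestOverlapPredicate:
    def test_matches_per_base_set_intersection(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            s1, s2 = rng.integers(0, 50, 2)
            l1, l2 = rng.integers(1, 20, 2)
            a = GenomeInterval("c", int(s1), int(s1 + l1))
            b = GenomeInterval("c", int(s2), int(s2 + l2))
            expected = bool(set(range(a.start, a.end))
                            & set(range(b.start, b.end)))
            assert a.overlaps(b) == expected


class TestBedpe:
    def test_reversed_anchors_normalized(self, tmp_path):
        path = _write(tmp_path, "r.bedpe",
                      "chr1\t500\t600\tchr1\t100\t200\tL1\t5\n")
        (rec,) = read_bedpe(path)
        assert rec.left.start == 100 and rec.right.start == 500

    def test_roundtrip_identity(self, tmp_path):
        recs = [BedpeRecord(GenomeInterval("chr1", 0, 10),
                            GenomeInterval("chr1", 50, 60), "a", "3",
                            ("x", "y"))]
        out = tmp_path / "o.bedpe"
        write_bedpe(recs, str(out))
        assert read_bedpe(str(out)) == recs
        text1 = out.read_text()
        write_bedpe(read_bedpe(str(out)), str(out))
        assert out.read_text() == text1

    def test_too_few_columns_names_missing(self, tmp_path):
        path = _write(tmp_path, "s.bedpe", "chr1\t0\t10\n")
        with pytest.raises(ValueError, match="chrom2"):
            read_bedpe(path)

    def test_interchromosomal_skipped(self, tmp_path):
        path = _write(tmp_path, "i.bedpe",
                      "chr1\t0\t10\tchr2\t0\t10\n"
                      "chr1\t0\t10\tchr1\t50\t60\n")
        assert len(read_bedpe(path)) == 1


CHAIN_PLUS = """chain 100 chrA 10000 + 1000 1100 chrB 20000 + 5000 5100 7
100
"""

CHAIN_MINUS = """chain 50 chrA 10000 + 0 150 chrB 1000 - 100 200 9
50\t50\t0
50
"""

CHAIN_BAD = """chain 10 chrA 10000 + 0 100 chrB 1000 + 0 150 11
100
"""


class TestChain:
    def test_single_block_absolute_coordinates(self, tmp_path):
        (ch,) = read_chain(_write(tmp_path, "a.chain", CHAIN_PLUS))
        assert ch.blocks == ((1000, 1100, 5000, 5100),)
        assert ch.chain_id == 7

    def test_minus_strand_reflection_is_involution(self, tmp_path):
        (ch,) = read_chain(_write(tmp_path, "m.chain", CHAIN_MINUS))
        # strand coords [100,150) and [150,200) reflect through qSize=1000
        assert ch.blocks == ((0, 50, 850, 900), (100, 150, 800, 850))
        for ts, te, qs, qe in ch.blocks:
            s2, e2 = ch.q_size - qe, ch.q_size - qs
            assert (ch.q_size - e2, ch.q_size - s2) == (qs, qe)

    def test_inconsistent_block_sizes_name_chain(self, tmp_path):
        with pytest.raises(ValueError, match="chain 11"):
            read_chain(_write(tmp_path, "b.chain", CHAIN_BAD))

    def test_disjoint_chains_both_kept(self, tmp_path):
        text = CHAIN_PLUS + "\n" + CHAIN_PLUS.replace(" 7", " 8").replace(
            "+ 1000 1100", "+ 3000 3100").replace("+ 5000 5100",
                                                  "+ 9000 9100")
        chains = read_chain(_write(tmp_path, "two.chain", text))
        assert sorted(c.chain_id for c in chains) == [7, 8]

    def test_write_read_write_byte_stable(self, tmp_path):
        chains = read_chain(_write(tmp_path, "m.chain", CHAIN_MINUS))
        p1 = tmp_path / "w1.chain"
        write_chain(chains, str(p1))
        p2 = tmp_path / "w2.chain"
        write_chain(read_chain(str(p1)), str(p2))
        assert p1.read_text() == p2.read_text()


class TestSignalTrack:
    def test_out_of_range_yields_sentinel(self):
        track = SignalTrack({"chr1": 100})
        track.set_values("chr1", 0, np.ones(100))
        vals = track.values("chr1", -5, 105)
        assert np.isnan(vals[:5]).all() and np.isnan(vals[-5:]).all()
        assert (vals[5:105] == 1).all()
        assert np.isnan(track.values("chrX", 0, 10)).all()


class TestPeakWriter:
    def test_write_read_write_byte_stable(self, tmp_path):
        peaks = [_pk(0, 100, 50), _pk(200, 300, 260, 4.5)]
        p1 = tmp_path / "a.narrowPeak"
        write_peaks(peaks, str(p1))
        p2 = tmp_path / "b.narrowPeak"
        write_peaks(read_peaks(str(p1)), str(p2))
        assert p1.read_text() == p2.read_text()
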