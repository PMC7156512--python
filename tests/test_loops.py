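"""Loop trimming, TE attribution, conservation classes, TADs, rank tests."""

import numpy as np
import pytest

from loopevo.core import ChainAlignment, GenomeInterval, Peak, TEAnnotation
from loopevo.crossmap import ChainIndex, identity_chains
from loopevo.loops import (CLASS_RANK, Classification, Loop, TAD,
                           attribute_te, classify_all, classify_loop,
                           filter_and_trim, groupwise_compare, match_tads,
                           te_in_variable_anchor)

from conftest import bruteforce_classify, random_instance


def _peak(start, end, signal, chrom="chr1"):
    return Peak(GenomeInterval(chrom, start, end), signal, (start + end) // 2)


def _loop(ls, le_, rs, re_, cell="q", loop_id="L", chrom="chr1"):
    return Loop(cell=cell, left=GenomeInterval(chrom, ls, le_),
                right=GenomeInterval(chrom, rs, re_), strength=1.0,
                loop_id=loop_id)


FULL_CHAIN = [ChainAlignment(1, 1.0, "chr1", 1_000_000, "chr1", 1_000_000,
                             "+", ((0, 1_000_000, 0, 1_000_000),))]


class TestFilterAndTrim:
    def test_strongest_peak_wins_and_anchor_trimmed(self):
        peaks = [_peak(90, 190, 5.0), _peak(150, 260, 9.0),
                 _peak(5000, 5100, 3.0)]
        (out,) = filter_and_trim([_loop(100, 250, 4990, 5110)], peaks)
        assert out.left == GenomeInterval("chr1", 150, 260)
        assert out.left_peak.signal == 9.0
        assert out.right == GenomeInterval("chr1", 5000, 5100)

    def test_loop_without_peak_dropped(self):
        peaks = [_peak(100, 200, 5.0)]
        assert filter_and_trim([_loop(100, 200, 5000, 5100)], peaks) == []

    def test_signal_tie_prefers_leftmost(self):
        peaks = [_peak(90, 190, 5.0), _peak(150, 260, 5.0),
                 _peak(5000, 5100, 1.0)]
        (out,) = filter_and_trim([_loop(100, 250, 4990, 5110)], peaks)
        assert out.left.start == 90


class TestAttributeTE:
    REPEATS = [TEAnnotation(GenomeInterval("chr1", 100, 200), "Alu", "SINE",
                            10.0)]

    def _trimmed(self, l_pk, r_pk):
        return Loop(cell="q", left=l_pk.interval, right=r_pk.interval,
                    strength=1.0, left_peak=l_pk, right_peak=r_pk,
                    loop_id="L")

    def test_te_at_left_anchor_only(self):
        loop = self._trimmed(_peak(100, 200, 1), _peak(5000, 5100, 1))
        (out,) = attribute_te([loop], self.REPEATS)
        assert out.te_left is not None and out.te_right is None
        assert out.te_derived

    def test_te_at_both_anchors(self):
        reps = self.REPEATS + [TEAnnotation(
            GenomeInterval("chr1", 5000, 5100), "L1", "LINE", 20.0)]
        loop = self._trimmed(_peak(100, 200, 1), _peak(5000, 5100, 1))
        (out,) = attribute_te([loop], reps)
        assert out.te_left is not None and out.te_right is not None

    def test_native_loop(self):
        loop = self._trimmed(_peak(9000, 9100, 1), _peak(20_000, 20_100, 1))
        (out,) = attribute_te([loop], self.REPEATS)
        assert not out.te_derived


class TestClassifyLoop:
    def test_coherent_target_loop_is_conserved(self):
        q = _loop(100, 200, 5000, 5100)
        t = _loop(150, 250, 4950, 5050, cell="t", loop_id="T0")
        cls = classify_loop(q, [t], FULL_CHAIN)
        assert cls.label == "C" and cls.same_loop_ids == {"T0"}

    def test_cross_loop_matches_are_b2(self):
        q = _loop(100, 200, 5000, 5100)
        t1 = _loop(150, 250, 2000, 2100, cell="t", loop_id="T1")
        t2 = _loop(3000, 3100, 4950, 5050, cell="t", loop_id="T2")
        cls = classify_loop(q, [t1, t2], FULL_CHAIN)
        assert cls.label == "B2" and not cls.same_loop_ids

    def test_single_anchor_match_is_b1(self):
        q = _loop(100, 200, 5000, 5100)
        t = _loop(150, 250, 2000, 2100, cell="t", loop_id="T1")
        assert classify_loop(q, [t], FULL_CHAIN).label == "B1"

    def test_no_matches_is_b0(self):
        q = _loop(100, 200, 5000, 5100)
        t = _loop(8000, 8100, 9000, 9100, cell="t", loop_id="T1")
        assert classify_loop(q, [t], FULL_CHAIN).label == "B0"

    GAPPY = [ChainAlignment(1, 1.0, "chr1", 1_000_000, "chr1", 1_000_000,
                            "+", ((4000, 1_000_000, 4000, 1_000_000),))]

    def test_unmappable_plus_match_is_n1a(self):
        q = _loop(100, 200, 5000, 5100)   # left in the gap
        t = _loop(4950, 5050, 9000, 9100, cell="t", loop_id="T1")
        assert classify_loop(q, [t], self.GAPPY).label == "N1A"

    def test_unmappable_without_match_is_n1b(self):
        q = _loop(100, 200, 5000, 5100)
        t = _loop(8000, 8100, 9000, 9100, cell="t", loop_id="T1")
        assert classify_loop(q, [t], self.GAPPY).label == "N1B"

    def test_both_unmappable_is_n0(self):
        q = _loop(100, 200, 3000, 3100)
        assert classify_loop(q, [], self.GAPPY).label == "N0"

    def test_order_invariance(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            inst = random_instance(rng)
            base = classify_loop(inst.query, inst.targets, inst.chains)
            perm = list(inst.targets)
            rng.shuffle(perm)
            assert classify_loop(inst.query, perm, inst.chains).label \
                == base.label

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(16)
        for _ in range(60):
            inst = random_instance(rng)
            got = classify_loop(inst.query, inst.targets, inst.chains).label
            assert got == bruteforce_classify(inst.query, inst.targets,
                                              inst.chains)

    def test_identity_chains_never_produce_n_classes(self, fx42):
        chains = identity_chains(fx42.truth.chrom_sizes_a)
        classes = classify_all(fx42.query_loops[:60], fx42.query_loops,
                               chains, flank=0)
        labels = {c.label for c in classes.values()}
        assert labels == {"C"}  # each loop matches itself exactly

    def test_partition_property(self, fx42):
        classes = classify_all(fx42.query_loops, fx42.target_loops,
                               fx42.chains_ab, flank=0)
        assert len(classes) == len(fx42.query_loops)
        counts = {}
        for c in classes.values():
            counts[c.label] = counts.get(c.label, 0) + 1
        assert sum(counts.values()) == len(fx42.query_loops)


class TestTEInVariableAnchor:
    def _cls(self, label, lm=(), rm=(), same=()):
        return Classification(label, True, True, frozenset(lm),
                              frozenset(rm), frozenset(same))

    def _teloop(self, te_left=False, te_right=False):
        te = TEAnnotation(GenomeInterval("chr1", 0, 100), "Alu", "SINE", 1.0)
        return Loop(cell="q", left=GenomeInterval("chr1", 0, 100),
                    right=GenomeInterval("chr1", 500, 600), strength=1.0,
                    te_left=te if te_left else None,
                    te_right=te if te_right else None, loop_id="L")

    def test_b1_te_on_matched_anchor_not_counted(self):
        cls = self._cls("B1", lm=[("T1", "left")])
        assert not te_in_variable_anchor(self._teloop(te_left=True), cls)

    def test_b1_te_on_unmatched_anchor_counted(self):
        cls = self._cls("B1", lm=[("T1", "left")])
        assert te_in_variable_anchor(self._teloop(te_right=True), cls)

    def test_conserved_loop_counts_te_anywhere(self):
        cls = self._cls("C", lm=[("T1", "left")], rm=[("T1", "right")],
                        same=["T1"])
        assert te_in_variable_anchor(self._teloop(te_right=True), cls)
        assert te_in_variable_anchor(self._teloop(te_left=True), cls)

    def test_no_te_never_counts(self):
        assert not te_in_variable_anchor(self._teloop(), self._cls("C"))


class TestMatchTads:
    TADS = [TAD(GenomeInterval("chr1", 100_000, 400_000), "q")]

    def test_anchors_exactly_on_boundaries_match(self):
        loop = _loop(99_950, 100_050, 399_950, 400_050, loop_id="L1")
        assert "L1" in match_tads([loop], self.TADS)

    def test_anchor_beyond_10kb_window_no_match(self):
        loop = _loop(110_001, 110_101, 399_950, 400_050, loop_id="L1")
        assert match_tads([loop], self.TADS) == {}

    def test_nested_tads_both_reported(self):
        tads = self.TADS + [TAD(GenomeInterval("chr1", 95_000, 405_000), "q")]
        loop = _loop(99_000, 101_000, 399_000, 401_000, loop_id="L1")
        assert len(match_tads([loop], tads)["L1"]) == 2

    def test_other_cell_ignored(self):
        tads = [TAD(GenomeInterval("chr1", 100_000, 400_000), "other")]
        loop = _loop(99_950, 100_050, 399_950, 400_050, loop_id="L1")
        assert match_tads([loop], tads) == {}


class TestGroupwiseCompare:
    def test_identical_groups_p_near_one(self):
        vals = list(np.arange(30))
        mat = groupwise_compare({"a": vals, "b": vals})
        assert mat.loc["a", "b"] >= 0.99

    def test_shifted_group_detected_one_sided(self):
        rng = np.random.default_rng(42)
        base = rng.normal(0, 1, 50)
        shifted = rng.normal(1, 1, 50)      # shift of 1 SD
        mat = groupwise_compare({"hi": list(shifted), "lo": list(base)},
                                alternative="greater")
        assert mat.loc["hi", "lo"] < 0.05

    def test_two_sided_symmetric(self):
        rng = np.random.default_rng(17)
        g = {k: list(rng.normal(size=20)) for k in "abc"}
        mat = groupwise_compare(g)
        for i in "abc":
            for j in "abc":
                if i != j:
                    assert mat.loc[i, j] == pytest.approx(mat.loc[j, i])

    def test_empty_group_flagged_missing(self):
        mat = groupwise_compare({"a": [1, 2, 3], "b": []})
        assert np.isnan(mat.loc["a", "b"])
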