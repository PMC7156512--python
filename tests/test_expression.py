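"""Nearest-TSS annotation, EP/PP/EE calls, ΔTPM, and signal profiles."""

import numpy as np
import pandas as pd
import pytest

from loopevo.core import ExpressionTable, GenomeInterval, SignalTrack
from loopevo.expression import (AnchorAnnotation, TSSIndex,
                                annotate_nearest_tss, classify_interaction,
                                delta_tpm, delta_tpm_analysis, profile_signal)
from loopevo.loops import Classification, Loop


class TestNearestTSS:
    TSS = [("chr1", 1000, "A"), ("chr1", 2200, "B")]

    def test_nearest_by_distance(self):
        idx = TSSIndex(self.TSS)
        assert idx.nearest("chr1", 1500) == ("A", 500)
        assert idx.nearest("chr1", 1900) == ("B", 300)

    def test_equidistant_tie_prefers_upstream_gene(self):
        idx = TSSIndex(self.TSS)
        assert idx.nearest("chr1", 1600) == ("A", 600)

    def test_point_on_tss_distance_zero(self):
        assert TSSIndex(self.TSS).nearest("chr1", 2200) == ("B", 0)

    def test_missing_chromosome_returns_none(self):
        assert TSSIndex(self.TSS).nearest("chrX", 10) is None

    def test_anchor_annotation_uses_midpoint(self):
        loop = Loop(cell="q", left=GenomeInterval("chr1", 900, 1100),
                    right=GenomeInterval("chr1", 5000, 5200),
                    strength=1.0, loop_id="L")
        ann = annotate_nearest_tss([loop], self.TSS)
        assert ann[("L", "left")].nearest_gene == "A"
        assert ann[("L", "left")].tss_distance == 0   # midpoint 1000
        assert ann[("L", "right")].nearest_gene == "B"


class TestClassifyInteraction:
    def _ann(self, me3, me1):
        return AnchorAnnotation("L", "left", None, None, me3, me1)

    def test_promoter_enhancer_pair_is_ep(self):
        assert classify_interaction(self._ann(0.9, 0.1),
                                    self._ann(0.1, 0.9)) == "EP"

    def test_promoter_dominates_enhancer_mark(self):
        # high me3 anchor is a promoter even with high me1
        assert classify_interaction(self._ann(0.9, 0.9),
                                    self._ann(0.9, 0.1)) == "PP"

    def test_below_thresholds_is_other(self):
        assert classify_interaction(self._ann(0.2, 0.2),
                                    self._ann(0.2, 0.2)) == "other"

    def test_zero_thresholds_saturate(self):
        got = classify_interaction(self._ann(0.0, 0.0), self._ann(0.0, 0.0),
                                   t_promoter=0.0, t_enhancer=0.0)
        assert got == "PP"


def _expr(genes_q_t: dict[str, tuple[float, float]]) -> ExpressionTable:
    df = pd.DataFrame({g: {"q": q, "t": t}
                       for g, (q, t) in genes_q_t.items()}).T
    return ExpressionTable(df)


class TestDeltaTPM:
    def test_basic_arithmetic(self):
        expr = _expr({"g": (5.0, 3.0)})
        assert delta_tpm(expr, "g", "q", "t") == 2.0

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(18)
        genes = {f"g{i}": (float(a), float(b))
                 for i, (a, b) in enumerate(rng.uniform(0, 100, (50, 2)))}
        expr = _expr(genes)
        for g in genes:
            d1 = delta_tpm(expr, g, "q", "t")
            d2 = delta_tpm(expr, g, "t", "q")
            assert d1 == d2 >= 0

    def test_unknown_cell_rejected(self):
        with pytest.raises(KeyError, match="cell"):
            _expr({"g": (1, 1)}).tpm("g", "nope")


def _ep_loop(i, chrom="chr1", cls="C", te=False):
    """A loop whose left anchor sits on a TSS and right anchor is distal."""
    base = 100_000 * (i + 1)
    left = GenomeInterval(chrom, base - 100, base + 100)
    right = GenomeInterval(chrom, base + 10_000, base + 10_200)
    from loopevo.core import TEAnnotation
    te_ann = TEAnnotation(left, "Alu", "SINE", 5.0) if te else None
    return Loop(cell="q", left=left, right=right, strength=1.0,
                te_left=te_ann, loop_id=f"L{i}")


class TestDeltaTPMAnalysis:
    def _setup(self, n_per_group=50, effect=20.0, noise_sd=5.0, seed=42):
        rng = np.random.default_rng(seed)
        loops, classes, annotations, genes = [], {}, {}, {}
        i = 0
        for cls, n in (("C", n_per_group), ("B0", n_per_group)):
            for _ in range(n):
                loop = _ep_loop(i, cls=cls, te=(i % 2 == 0))
                loops.append(loop)
                classes[loop.loop_id] = Classification(
                    cls, True, True, frozenset(), frozenset(), frozenset())
                gene = f"g{i}"
                annotations[(loop.loop_id, "left")] = AnchorAnnotation(
                    loop.loop_id, "left", gene, 100)
                annotations[(loop.loop_id, "right")] = AnchorAnnotation(
                    loop.loop_id, "right", gene, 9_000)
                base = rng.uniform(30, 80)
                shift = effect if cls != "C" else 0.0
                genes[gene] = (base + rng.normal(0, noise_sd),
                               base + shift + rng.normal(0, noise_sd))
                i += 1
        return loops, classes, annotations, _expr(genes)

    def test_planted_effect_detected(self):
        loops, classes, ann, expr = self._setup()
        res = delta_tpm_analysis(loops, classes, ann, expr, "q", "t")
        assert res.p_values["te_derived"] <= 0.01
        assert res.p_values["native"] <= 0.01
        assert res.group("native", "variable").mean_delta > \
            res.group("native", "conserved").mean_delta

    def test_identical_expression_gives_large_p(self):
        loops, classes, ann, expr = self._setup(effect=0.0, noise_sd=0.0)
        res = delta_tpm_analysis(loops, classes, ann, expr, "q", "t")
        assert all(p >= 0.5 for p in res.p_values.values())
        assert res.group("native", "variable").mean_delta == 0.0

    def test_distance_filters_exclude_loops(self):
        loops, classes, ann, expr = self._setup(n_per_group=5)
        # push one proximal anchor beyond 1 kb: loop drops out
        ann[("L0", "left")] = AnchorAnnotation("L0", "left", "g0", 1_500)
        res = delta_tpm_analysis(loops, classes, ann, expr, "q", "t")
        assert sum(g.n for g in res.groups) == 9

    def test_empty_group_skips_test(self):
        loops, classes, ann, expr = self._setup(n_per_group=2)
        only_c = {k: v for k, v in classes.items() if v.label == "C"}
        res = delta_tpm_analysis(loops, only_c, ann, expr, "q", "t")
        assert res.p_values == {}


class TestProfileSignal:
    def _const_track(self, value=3.0, size=10_000):
        track = SignalTrack({"chr1": size})
        track.set_values("chr1", 0, np.full(size, value))
        return track

    def test_constant_track_gives_constant_profile(self):
        track = self._const_track(3.0)
        (prof,) = profile_signal({"C": [("chr1", 5000)]}, track,
                                 window=100).values()
        assert prof.shape == (100,)
        assert np.allclose(prof, 3.0)

    def test_flip_invariant_on_mirror_symmetric_records(self):
        track = SignalTrack({"chr1": 1000})
        vals = np.zeros(1000)
        vals[480:520] = 5.0                       # symmetric around 500
        track.set_values("chr1", 0, vals)
        anchors = {"C": [("chr1", 500)]}
        a = profile_signal(anchors, track, window=200, flip=False)["C"]
        b = profile_signal(anchors, track, window=200, flip=True)["C"]
        assert np.allclose(a, b)

    def test_normalization_by_constant_background_is_one(self):
        track = self._const_track(7.0)
        prof = profile_signal({"C": [("chr1", 5000)]}, track, window=100,
                              normalize=True, n_background=50, seed=0)["C"]
        assert np.allclose(prof, 1.0)

    def test_edge_record_padded_with_sentinel(self):
        track = self._const_track(2.0, size=1000)
        prof = profile_signal({"C": [("chr1", 10)]}, track, window=100)["C"]
        assert np.isnan(prof[:40]).all() and np.allclose(prof[40:], 2.0)

    def test_record_order_invariant(self):
        track = self._const_track(1.0)
        recs = [("chr1", 100), ("chr1", 5000), ("chr1", 9000)]
        a = profile_signal({"C": recs}, track, window=50)["C"]
        b = profile_signal({"C": recs[::-1]}, track, window=50)["C"]
        assert np.allclose(a, b, equal_nan=True)

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError, match="even"):
            profile_signal({}, self._const_track(), window=101)
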