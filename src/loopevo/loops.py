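"""Loop filtering, TE attribution, the 7-class conservation classifier,
and TAD correspondence.

Conservation classes (query loop vs a target loop set, through a chain):

* ``C``   — both anchors map and land on the two anchors of one target loop.
* ``B2``  — both anchors map and overlap target anchors, but no single
  target loop accounts for both.
* ``B1``  — both anchors map; exactly one overlaps a target anchor.
* ``B0``  — both anchors map; neither overlaps a target anchor.
* ``N1A`` — one anchor unmappable; the mapped one overlaps a target anchor.
* ``N1B`` — one anchor unmappable; the mapped one overlaps nothing.
* ``N0``  — both anchors in non-orthologous sequence.

Within-species (cell vs cell) comparisons use identity chains, so the
N-classes can only arise between species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import BedpeRecord, GenomeInterval, Peak, TEAnnotation
from .crossmap import ChainIndex, map_feature

logger = logging.getLogger("loopevo")

CLASSES = ("C", "B2", "B1", "B0", "N1A", "N1B", "N0")

#: Ordering used for the flank-monotonicity property: larger is more
#: conserved within each mappability stratum.
CLASS_RANK = {"C": 6, "B2": 5, "B1": 4, "B0": 3, "N1A": 2, "N1B": 1, "N0": 0}


@dataclass(frozen=True)
class Loop:
    """A CTCF-anchored loop: two same-chromosome anchors with their
    embedded CTCF peaks, a contact/PET strength, and TE attributions."""

    cell: str
    left: GenomeInterval
    right: GenomeInterval
    strength: float
    left_peak: Peak | None = None
    right_peak: Peak | None = None
    te_left: TEAnnotation | None = None
    te_right: TEAnnotation | None = None
    orientation: str | None = None
    loop_id: str = ""

    def __post_init__(self) -> None:
        if self.left.chrom != self.right.chrom:
            raise ValueError("loop anchors on different chromosomes")
        if self.left.start > self.right.start:
            raise ValueError("left anchor must come first")

    @property
    def chrom(self) -> str:
        return self.left.chrom

    @property
    def te_derived(self) -> bool:
        return self.te_left is not None or self.te_right is not None

    @property
    def anchors(self) -> tuple[GenomeInterval, GenomeInterval]:
        return self.left, self.right


def loops_from_bedpe(records: Sequence[BedpeRecord], cell: str) -> list[Loop]:
    loops = []
    for i, r in enumerate(records):
        try:
            strength = float(r.score)
        except ValueError:
            strength = 0.0
        loops.append(Loop(cell=cell, left=r.left, right=r.right,
                          strength=strength,
                          loop_id=r.name if r.name != "." else f"{cell}_loop{i}"))
    return loops


def filter_and_trim(raw_loops: Iterable[Loop], ctcf_peaks: Sequence[Peak],
                    ) -> list[Loop]:
    """Keep loops with a CTCF peak at both anchors and trim each anchor to
    its strongest overlapping peak (ties: leftmost); the peak summit is
    carried on the record."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in ctcf_peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for peaks in by_chrom.values():
        peaks.sort(key=lambda p: p.interval.start)

    def _strongest(anchor: GenomeInterval) -> Peak | None:
        best = None
        for p in by_chrom.get(anchor.chrom, ()):
            if p.interval.overlaps(anchor):
                if best is None or p.signal > best.signal:
                    best = p
        return best

    out = []
    for loop in raw_loops:
        lp, rp = _strongest(loop.left), _strongest(loop.right)
        if lp is None or rp is None:
            continue
        trimmed = replace(loop, left=lp.interval, right=rp.interval,
                          left_peak=lp, right_peak=rp)
        if trimmed.left.start > trimmed.right.start:
            trimmed = replace(trimmed, left=rp.interval, right=lp.interval,
                              left_peak=rp, right_peak=lp)
        out.append(trimmed)
    return out


def attribute_te(loops: Iterable[Loop], repeats: Sequence[TEAnnotation],
                 halfwidth: int = 50) -> list[Loop]:
    """Attach a TE to each anchor whose peak summit lies within
    ±halfwidth of the TE (same rule as the CTCF-site/TE association)."""
    from .landscape import nearest_te  # shared ±50 bp tie-break logic

    by_chrom: dict[str, list[TEAnnotation]] = {}
    for te in repeats:
        by_chrom.setdefault(te.interval.chrom, []).append(te)

    out = []
    for loop in loops:
        te_l = te_r = None
        if loop.left_peak is not None and loop.left_peak.summit is not None:
            te_l = nearest_te(by_chrom.get(loop.left.chrom, ()),
                              loop.left_peak.summit, halfwidth)
        if loop.right_peak is not None and loop.right_peak.summit is not None:
            te_r = nearest_te(by_chrom.get(loop.right.chrom, ()),
                              loop.right_peak.summit, halfwidth)
        out.append(replace(loop, te_left=te_l, te_right=te_r))
    return out


# ---------------------------------------------------------------------------
# Conservation classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Classification:
    """Class label plus the anchor-overlap evidence used to reach it.

    ``left_matches``/``right_matches`` hold (target loop_id, side) pairs the
    mapped query anchors overlap; ``same_loop_ids`` are target loops whose
    two anchors account for both query anchors (non-empty iff class C).
    """

    label: str
    left_mapped: bool
    right_mapped: bool
    left_matches: frozenset[tuple[str, str]]
    right_matches: frozenset[tuple[str, str]]
    same_loop_ids: frozenset[str]


def _extended(iv: GenomeInterval, flank: int) -> GenomeInterval:
    return GenomeInterval(iv.chrom, max(0, iv.start - flank), iv.end + flank,
                          iv.strand)


def classify_loop(
    query: Loop,
    target_loops: Sequence[Loop],
    chains: ChainIndex | Sequence,
    flank: int = 0,
) -> Classification:
    """Assign one of the 7 conservation classes to a query loop.

    Anchors are cross-mapped without coordinate extension; ``flank``
    symmetrically extends the *mapped* anchors before the overlap test
    (0 by default; 10–50 kb relaxes the match).
    """
    if not isinstance(chains, ChainIndex):
        chains = ChainIndex(chains)
    mapped_l = map_feature(query.left, chains).target
    mapped_r = map_feature(query.right, chains).target

    def _matches(mapped: GenomeInterval | None) -> frozenset[tuple[str, str]]:
        if mapped is None:
            return frozenset()
        probe = _extended(mapped, flank) if flank else mapped
        found = set()
        for t in target_loops:
            if probe.overlaps(t.left):
                found.add((t.loop_id, "left"))
            if probe.overlaps(t.right):
                found.add((t.loop_id, "right"))
        return frozenset(found)

    lm, rm = _matches(mapped_l), _matches(mapped_r)
    same = frozenset(
        lid for lid, side in lm
        if (lid, "left" if side == "right" else "right") in rm
    )

    if mapped_l is not None and mapped_r is not None:
        if same:
            label = "C"
        elif lm and rm:
            label = "B2"
        elif lm or rm:
            label = "B1"
        else:
            label = "B0"
    elif mapped_l is None and mapped_r is None:
        label = "N0"
    else:
        hit = lm if mapped_l is not None else rm
        label = "N1A" if hit else "N1B"
    return Classification(
        label=label,
        left_mapped=mapped_l is not None,
        right_mapped=mapped_r is not None,
        left_matches=lm, right_matches=rm, same_loop_ids=same,
    )


def classify_all(query_loops: Sequence[Loop], target_loops: Sequence[Loop],
                 chains, flank: int = 0) -> dict[str, Classification]:
    if not isinstance(chains, ChainIndex):
        chains = ChainIndex(chains)
    return {q.loop_id: classify_loop(q, target_loops, chains, flank)
            for q in query_loops}


def te_in_variable_anchor(query: Loop, cls: Classification) -> bool:
    """Does a TE insertion count toward this loop's TE-derived total?

    For cell/species-specific configurations the TE must overlap the
    anchor(s) unique to the query cell: for B1/N1A that is the non-matching
    anchor; for B2/N1B any anchor lacking a same-loop match (all of them,
    by construction); C/B0/N0 count a TE on either anchor.
    """
    has_l, has_r = query.te_left is not None, query.te_right is not None
    if not (has_l or has_r):
        return False
    label = cls.label
    if label in ("C", "B0", "N0"):
        return True
    if label in ("B1", "N1A"):
        left_matched = bool(cls.left_matches)
        return has_r if left_matched else has_l
    # B2 / N1B: count anchors lacking a same-loop match
    def _same_loop_matched(matches: frozenset[tuple[str, str]]) -> bool:
        return any(lid in cls.same_loop_ids for lid, _ in matches)
    ok_l = has_l and not _same_loop_matched(cls.left_matches)
    ok_r = has_r and not _same_loop_matched(cls.right_matches)
    return ok_l or ok_r


# ---------------------------------------------------------------------------
# TADs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TAD:
    """A topologically associating domain spanning boundary X to Y."""

    interval: GenomeInterval
    cell: str

    def __post_init__(self) -> None:
        if len(self.interval) <= 0:
            raise ValueError("TAD must have positive span")


def match_tads(loops: Sequence[Loop], tads: Sequence[TAD],
               boundary_halfwidth: int = 10_000,
               boundary_only: bool = False) -> dict[str, list[TAD]]:
    """Loops corresponding to whole TADs of the same cell.

    A loop matches a TAD when its upstream anchor overlaps the ±halfwidth
    window around X and its downstream anchor the window around Y of one
    TAD. With ``boundary_only`` a single-boundary overlap suffices (the
    Dixon-style alternative definition). Nested TADs can both match; the
    caller disambiguates.
    """
    out: dict[str, list[TAD]] = {}
    for loop in loops:
        hits = []
        for tad in tads:
            if tad.cell != loop.cell or tad.interval.chrom != loop.chrom:
                continue
            x, y = tad.interval.start, tad.interval.end
            up = GenomeInterval(tad.interval.chrom,
                                max(0, x - boundary_halfwidth),
                                x + boundary_halfwidth + 1)
            down = GenomeInterval(tad.interval.chrom,
                                  max(0, y - boundary_halfwidth),
                                  y + boundary_halfwidth + 1)
            match_up = loop.left.overlaps(up)
            match_down = loop.right.overlaps(down)
            if (match_up and match_down) or (boundary_only and
                                             (match_up or match_down)):
                hits.append(tad)
        if hits:
            out[loop.loop_id] = hits
    return out


def read_tad_bed(path: str, cell: str) -> list[TAD]:
    """BED with start/end as the X/Y boundary coordinates of each TAD."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(TAD(GenomeInterval(f[0], int(f[1]), int(f[2])), cell))
    return out


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def groupwise_compare(groups: Mapping[str, Sequence[float]],
                      alternative: str = "two-sided") -> "pd.DataFrame":
    """Wilcoxon rank-sum p-values over all ordered group pairs.

    Entry (row g1, col g2) is the p-value testing g1 vs g2 with the given
    alternative; empty groups yield NaN. Serves the loop-strength,
    TE-age-by-class, and enrichment-contribution comparisons alike.
    """
    import pandas as pd

    labels = list(groups)
    mat = np.full((len(labels), len(labels)), np.nan)
    for i, g1 in enumerate(labels):
        for j, g2 in enumerate(labels):
            if i == j:
                continue
            x, y = np.asarray(groups[g1], float), np.asarray(groups[g2], float)
            if len(x) < 1 or len(y) < 1:
                continue
            try:
                mat[i, j] = stats.mannwhitneyu(x, y,
                                               alternative=alternative).pvalue
            except ValueError:
                continue
    return pd.DataFrame(mat, index=labels, columns=labels)
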