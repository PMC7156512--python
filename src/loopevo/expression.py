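"""Anchor regulatory annotation, nearest-TSS assignment, the ΔTPM
statistic over conserved vs variable loops, and windowed signal profiles.

ΔTPM for a gene i between a query and a target cell is |TPM_i(q) − TPM_i(t)|.
Enhancer–promoter loops are isolated by TSS distance (one anchor <= 1 kb,
the other >= 3 kb from its nearest TSS), and a one-sided rank-sum test asks
whether variable loops (any class but C) carry larger ΔTPM than conserved
ones, separately for TE-derived and native loops.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import ExpressionTable, GenomeInterval, SignalTrack
from .loops import Classification, Loop

logger = logging.getLogger("loopevo")

PROMOTER = "promoter"
ENHANCER = "enhancer"
OTHER = "other"

EP = "EP"
PP = "PP"
EE = "EE"

#: Default TSS-distance filters for enhancer-promoter loop isolation (bp).
PROXIMAL_MAX = 1_000
DISTAL_MIN = 3_000


@dataclass(frozen=True)
class AnchorAnnotation:
    """Regulatory annotation of one loop anchor."""

    loop_id: str
    side: str  # "left" | "right"
    nearest_gene: str | None
    tss_distance: int | None
    h3k4me3_scaled: float = np.nan
    h3k4me1_scaled: float = np.nan

    def role(self, t_promoter: float = 0.5, t_enhancer: float = 0.5) -> str:
        if self.h3k4me3_scaled >= t_promoter:
            return PROMOTER
        if self.h3k4me1_scaled >= t_enhancer:
            return ENHANCER
        return OTHER


class TSSIndex:
    """Per-chromosome sorted TSS positions for nearest-gene queries."""

    def __init__(self, tss: Sequence[tuple[str, int, str]]):
        self._by_chrom: dict[str, tuple[list[int], list[str]]] = {}
        for chrom, pos, gene in sorted(tss, key=lambda t: (t[0], t[1], t[2])):
            positions, genes = self._by_chrom.setdefault(chrom, ([], []))
            positions.append(pos)
            genes.append(gene)

    def nearest(self, chrom: str, point: int) -> tuple[str, int] | None:
        """(gene, distance) of the nearest TSS; equidistant ties go to the
        upstream (smaller-coordinate) gene. None when the chromosome has
        no TSS."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        positions, genes = entry
        i = bisect_left(positions, point)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = abs(positions[j] - point)
                if best is None or d < best[1]:
                    best = (genes[j], d, positions[j])
        return best[0], best[1]


def annotate_nearest_tss(
    loops: Sequence[Loop],
    tss: Sequence[tuple[str, int, str]] | TSSIndex,
) -> dict[tuple[str, str], AnchorAnnotation]:
    """Annotate every loop anchor with its nearest gene by anchor-midpoint
    to TSS distance. Keys are (loop_id, side)."""
    index = tss if isinstance(tss, TSSIndex) else TSSIndex(tss)
    out: dict[tuple[str, str], AnchorAnnotation] = {}
    for loop in loops:
        for side, anchor in (("left", loop.left), ("right", loop.right)):
            hit = index.nearest(anchor.chrom, anchor.midpoint)
            if hit is None:
                logger.warning("no TSS on %s; anchor %s/%s unannotated",
                               anchor.chrom, loop.loop_id, side)
                out[(loop.loop_id, side)] = AnchorAnnotation(
                    loop.loop_id, side, None, None)
            else:
                gene, dist = hit
                out[(loop.loop_id, side)] = AnchorAnnotation(
                    loop.loop_id, side, gene, dist)
    return out


def scale_marks(
    annotations: Mapping[tuple[str, str], AnchorAnnotation],
    loops: Sequence[Loop],
    h3k4me3: SignalTrack,
    h3k4me1: SignalTrack,
) -> dict[tuple[str, str], AnchorAnnotation]:
    """Attach min-max-scaled (within this sample) maximal H3K4me3/H3K4me1
    signal over each anchor."""
    raw3, raw1, keys = [], [], []
    for loop in loops:
        for side, anchor in (("left", loop.left), ("right", loop.right)):
            v3 = h3k4me3.values(anchor.chrom, anchor.start, anchor.end)
            v1 = h3k4me1.values(anchor.chrom, anchor.start, anchor.end)
            raw3.append(np.nanmax(v3) if np.isfinite(v3).any() else np.nan)
            raw1.append(np.nanmax(v1) if np.isfinite(v1).any() else np.nan)
            keys.append((loop.loop_id, side))

    def _scale(vals: list[float]) -> np.ndarray:
        arr = np.asarray(vals, float)
        lo, hi = np.nanmin(arr), np.nanmax(arr)
        if not np.isfinite(hi - lo) or hi == lo:
            return np.zeros_like(arr)
        return (arr - lo) / (hi - lo)

    s3, s1 = _scale(raw3), _scale(raw1)
    out = dict(annotations)
    for k, v3, v1 in zip(keys, s3, s1):
        a = out[k]
        out[k] = AnchorAnnotation(a.loop_id, a.side, a.nearest_gene,
                                  a.tss_distance, float(v3), float(v1))
    return out


def classify_interaction(left: AnchorAnnotation, right: AnchorAnnotation,
                         t_promoter: float = 0.5, t_enhancer: float = 0.5,
                         ) -> str:
    """EP / PP / EE / other from the two anchors' scaled marks."""
    roles = {left.role(t_promoter, t_enhancer),
             right.role(t_promoter, t_enhancer)}
    if roles == {PROMOTER, ENHANCER}:
        return EP
    if roles == {PROMOTER}:
        return PP
    if roles == {ENHANCER}:
        return EE
    return OTHER


# ---------------------------------------------------------------------------
# ΔTPM
# ---------------------------------------------------------------------------

def delta_tpm(expr: ExpressionTable, gene: str, q_cell: str, t_cell: str,
              ) -> float:
    """|TPM(q) − TPM(t)| for one gene."""
    return abs(expr.tpm(gene, q_cell) - expr.tpm(gene, t_cell))


@dataclass(frozen=True)
class DeltaTPMGroup:
    te_status: str          # "te_derived" | "native"
    conservation: str       # "conserved" | "variable"
    n: int
    mean_delta: float | None
    values: tuple[float, ...]


@dataclass(frozen=True)
class DeltaTPMResult:
    groups: tuple[DeltaTPMGroup, ...]
    p_values: dict[str, float]  # te_status -> one-sided p (variable > conserved)

    def group(self, te_status: str, conservation: str) -> DeltaTPMGroup:
        for g in self.groups:
            if g.te_status == te_status and g.conservation == conservation:
                return g
        raise KeyError((te_status, conservation))


def delta_tpm_analysis(
    loops: Sequence[Loop],
    classes: Mapping[str, Classification],
    annotations: Mapping[tuple[str, str], AnchorAnnotation],
    expr: ExpressionTable,
    q_cell: str,
    t_cell: str,
    prox_max: int = PROXIMAL_MAX,
    dist_min: int = DISTAL_MIN,
    dedupe_gene: bool = False,
) -> DeltaTPMResult:
    """ΔTPM contrast between conserved (class C) and variable loops.

    Only enhancer–promoter-style loops are used: one anchor <= prox_max
    from its nearest TSS, the other >= dist_min. The proximal anchor's
    gene supplies ΔTPM between the query and target cells. Groups are
    {conserved, variable} × {TE-derived, native}; the one-sided rank-sum
    test asks whether variable > conserved within each TE status.
    """
    buckets: dict[tuple[str, str], list[float]] = {
        (ts, cv): [] for ts in ("te_derived", "native")
        for cv in ("conserved", "variable")
    }
    seen_genes: dict[tuple[str, str], set[str]] = {k: set() for k in buckets}
    for loop in loops:
        cls = classes.get(loop.loop_id)
        if cls is None:
            continue
        la = annotations.get((loop.loop_id, "left"))
        ra = annotations.get((loop.loop_id, "right"))
        if la is None or ra is None:
            continue
        if la.tss_distance is None or ra.tss_distance is None:
            continue
        if la.tss_distance <= prox_max and ra.tss_distance >= dist_min:
            proximal = la
        elif ra.tss_distance <= prox_max and la.tss_distance >= dist_min:
            proximal = ra
        else:
            continue
        if proximal.nearest_gene is None or proximal.nearest_gene not in expr:
            continue
        key = ("te_derived" if loop.te_derived else "native",
               "conserved" if cls.label == "C" else "variable")
        if dedupe_gene:
            if proximal.nearest_gene in seen_genes[key]:
                continue
            seen_genes[key].add(proximal.nearest_gene)
        buckets[key].append(delta_tpm(expr, proximal.nearest_gene,
                                      q_cell, t_cell))

    groups = tuple(
        DeltaTPMGroup(ts, cv, len(vals),
                      float(np.mean(vals)) if vals else None, tuple(vals))
        for (ts, cv), vals in buckets.items()
    )
    p_values: dict[str, float] = {}
    for ts in ("te_derived", "native"):
        var = buckets[(ts, "variable")]
        cons = buckets[(ts, "conserved")]
        if not var or not cons:
            logger.warning("delta_tpm_analysis: empty group for %s; "
                           "test skipped", ts)
            continue
        p_values[ts] = float(
            stats.mannwhitneyu(var, cons, alternative="greater").pvalue
        )
    return DeltaTPMResult(groups, p_values)


# ---------------------------------------------------------------------------
# Windowed signal profiles
# ---------------------------------------------------------------------------

def profile_signal(
    anchors_by_class: Mapping[str, Sequence[tuple[str, int]]],
    track: SignalTrack,
    window: int,
    flip: bool = False,
    normalize: bool = False,
    n_background: int = 1000,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-class mean signal vector over windows centered on anchor summits.

    ``anchors_by_class`` maps a class label to (chrom, summit) pairs.
    ``window`` must be even; each record contributes the track values over
    [summit − window/2, summit + window/2), padded with the missing
    sentinel at chromosome edges (those bases drop out of the column
    means). With ``flip``, a record whose right half carries more signal
    than its left is reversed before averaging. With ``normalize``, column
    means are divided by the matching profile of ``n_background`` seeded
    random windows (chromosome drawn proportional to length).
    """
    if window % 2:
        raise ValueError("window must be even")
    half = window // 2

    def _profile(records: Sequence[tuple[str, int]]) -> np.ndarray:
        rows = []
        for chrom, summit in records:
            vals = track.values(chrom, summit - half, summit + half)
            if flip:
                left, right = vals[:half], vals[half:]
                if np.nansum(right) > np.nansum(left):
                    vals = vals[::-1]
            rows.append(vals)
        if not rows:
            return np.full(window, np.nan)
        stacked = np.vstack(rows)
        out = np.full(window, np.nan)
        have = np.isfinite(stacked).any(axis=0)  # all-NaN columns stay NaN
        out[have] = np.nanmean(stacked[:, have], axis=0)
        return out

    background = None
    if normalize:
        rng = np.random.default_rng(seed)
        chroms = sorted(track.chrom_sizes)
        lengths = np.array([track.chrom_sizes[c] for c in chroms], float)
        weights = lengths / lengths.sum()
        rand = []
        for _ in range(n_background):
            ci = rng.choice(len(chroms), p=weights)
            center = int(rng.integers(half, int(lengths[ci]) - half))
            rand.append((chroms[ci], center))
        background = _profile(rand)

    out = {}
    for label, records in anchors_by_class.items():
        prof = _profile(records)
        if background is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                prof = prof / background
        out[label] = prof
    return out
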