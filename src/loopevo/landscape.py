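"""Species-wise union CTCF sets, cross-species occupancy labels, TE
association at summits, and random-background overlap expectations.

Occupancy labels on each reference genome: ``shared`` (bound in both
species at the syntenic locus), ``query_specific`` (native peak without a
cross-species partner), ``target_specific`` (peak mapped in from the other
species with no native partner). Native peaks that fail to cross-map are
retained as species-specific, non-orthologous records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .core import GenomeInterval, Peak, TEAnnotation
from .crossmap import ChainIndex, map_feature

logger = logging.getLogger("loopevo")

SHARED = "shared"
QUERY_SPECIFIC = "query_specific"
TARGET_SPECIFIC = "target_specific"

#: TE association window: the TE must come within this many bases of the
#: ChIP-seq peak summit.
TE_SUMMIT_HALFWIDTH = 50


@dataclass(frozen=True)
class CTCFSite:
    """One union-set CTCF site on a reference genome."""

    peak: Peak
    species_label: str
    orthologous: bool
    cells_bound: frozenset[str] = frozenset()
    te: TEAnnotation | None = None

    @property
    def te_derived(self) -> bool:
        return self.te is not None


def _overlaps_any(iv: GenomeInterval, peaks: Sequence[Peak]) -> bool:
    return any(iv.overlaps(p.interval) for p in peaks)


def build_union(
    species_a_peaks: Sequence[Peak],
    species_b_peaks: Sequence[Peak],
    chains_ab,
    chains_ba,
    cells_a: Iterable[str] = (),
    cells_b: Iterable[str] = (),
) -> tuple[list[CTCFSite], list[CTCFSite]]:
    """Union CTCF sets on both reference genomes with occupancy labels.

    ``chains_ab`` map A coordinates to B; ``chains_ba`` the reverse. Peaks
    must already be merged per species. Returns (sites on A, sites on B);
    every input peak contributes exactly one record per reference.
    """
    idx_ab = chains_ab if isinstance(chains_ab, ChainIndex) else ChainIndex(chains_ab)
    idx_ba = chains_ba if isinstance(chains_ba, ChainIndex) else ChainIndex(chains_ba)

    chroms_a = {p.interval.chrom for p in species_a_peaks}
    if chroms_a and idx_ab.chromosomes and not (chroms_a & idx_ab.chromosomes):
        raise ValueError(
            "chain/genome mismatch: no chromosome of the A peak set occurs "
            "in the A->B chains"
        )

    cells_a, cells_b = frozenset(cells_a), frozenset(cells_b)
    sites_a = _label_one_reference(species_a_peaks, species_b_peaks,
                                   idx_ab, idx_ba, cells_a, cells_b)
    sites_b = _label_one_reference(species_b_peaks, species_a_peaks,
                                   idx_ba, idx_ab, cells_b, cells_a)
    return sites_a, sites_b


def _label_one_reference(native: Sequence[Peak], other: Sequence[Peak],
                         chains_fwd: ChainIndex, chains_rev: ChainIndex,
                         cells_native: frozenset[str],
                         cells_other: frozenset[str]) -> list[CTCFSite]:
    sites: list[CTCFSite] = []
    for p in native:
        m = map_feature(p.interval, chains_fwd)
        if m.target is None:
            sites.append(CTCFSite(p, QUERY_SPECIFIC, orthologous=False,
                                  cells_bound=cells_native))
        elif _overlaps_any(m.target, other):
            sites.append(CTCFSite(p, SHARED, orthologous=True,
                                  cells_bound=cells_native | cells_other))
        else:
            sites.append(CTCFSite(p, QUERY_SPECIFIC, orthologous=True,
                                  cells_bound=cells_native))
    # peaks from the other species mapped onto this reference with no
    # native partner appear as target-specific records
    for p in other:
        m = map_feature(p.interval, chains_rev, summit=p.summit)
        if m.target is None or _overlaps_any(m.target, native):
            continue
        mapped_summit = m.mapped_summit
        if mapped_summit is None or not m.target.contains(mapped_summit):
            mapped_summit = m.target.midpoint
        mapped_peak = Peak(m.target, p.signal, mapped_summit, p.name)
        sites.append(CTCFSite(mapped_peak, TARGET_SPECIFIC, orthologous=True,
                              cells_bound=cells_other))
    return sites


# ---------------------------------------------------------------------------
# TE association
# ---------------------------------------------------------------------------

def nearest_te(candidates: Iterable[TEAnnotation], summit: int,
               halfwidth: int = TE_SUMMIT_HALFWIDTH) -> TEAnnotation | None:
    """The TE associated with a peak summit, or None.

    Eligible TEs intersect [summit − halfwidth, summit + halfwidth].
    Tie-break among several: a TE containing the summit wins, then the
    nearest edge, then the longest interval.
    """
    eligible = [te for te in candidates
                if te.interval.distance_to(summit) <= halfwidth]
    if not eligible:
        return None
    return min(eligible, key=lambda te: (
        not te.interval.contains(summit),
        te.interval.distance_to(summit),
        -len(te.interval),
    ))


def associate_te(sites: Sequence[CTCFSite], repeats: Sequence[TEAnnotation],
                 halfwidth: int = TE_SUMMIT_HALFWIDTH) -> list[CTCFSite]:
    """Attach to each site the TE within ±halfwidth of its peak summit."""
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for te in repeats:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    out = []
    for s in sites:
        te = None
        if s.peak.summit is not None:
            te = nearest_te(by_chrom.get(s.peak.interval.chrom, ()),
                            s.peak.summit, halfwidth)
        out.append(replace(s, te=te))
    return out


# ---------------------------------------------------------------------------
# Random-background overlap expectation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapExpectation:
    observed: int
    expected_median: float
    expected_mean: float
    fold: float            # observed / expected (inf when expectation is 0)
    n_trials: int


def expected_te_overlap(
    specific_sites: Sequence[GenomeInterval],
    te_derived_sizes: Sequence[int],
    chrom_sizes: dict[str, int],
    n_trials: int = 1000,
    seed: int | None = None,
    observed: int | None = None,
    te_derived_chroms: Sequence[str] | None = None,
) -> OverlapExpectation:
    """Expected TE/CTCF overlap count under uniform random placement.

    Per trial, N intervals (N = len(te_derived_sizes)) with exactly the
    TE-derived size multiset are placed uniformly over the genome
    (chromosome drawn proportional to length; pass ``te_derived_chroms``
    to pin each placement to its source chromosome instead), and the
    number of placed intervals overlapping >=1 species-specific site is
    counted. The expectation is the median over trials; fold =
    observed / median, with a mean fallback when the median is 0 and an
    infinity flag when both vanish.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    sizes = np.asarray(te_derived_sizes, dtype=np.int64)
    n = len(sizes)
    if observed is None:
        observed = n
    if n == 0:
        return OverlapExpectation(observed, 0.0, 0.0, _inf_or_nan(observed),
                                  n_trials)
    chroms = sorted(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if sizes.max() > lengths.max():
        raise ValueError("genome shorter than the largest interval")

    # sorted site arrays per chromosome for vectorized overlap queries
    site_starts: dict[str, np.ndarray] = {}
    site_ends: dict[str, np.ndarray] = {}
    for c in chroms:
        ivs = sorted((s.start, s.end) for s in specific_sites if s.chrom == c)
        site_starts[c] = np.array([s for s, _ in ivs], dtype=np.int64)
        site_ends[c] = np.array([e for _, e in ivs], dtype=np.int64)

    rng = np.random.default_rng(seed)
    counts = np.empty(n_trials, dtype=np.int64)
    weights = lengths / lengths.sum()
    fixed_idx = None
    if te_derived_chroms is not None:
        if len(te_derived_chroms) != n:
            raise ValueError("te_derived_chroms must align with sizes")
        lookup = {c: i for i, c in enumerate(chroms)}
        fixed_idx = np.array([lookup[c] for c in te_derived_chroms])
    for t in range(n_trials):
        chrom_idx = (fixed_idx if fixed_idx is not None
                     else rng.choice(len(chroms), size=n, p=weights))
        hits = 0
        for ci in np.unique(chrom_idx):
            c = chroms[ci]
            sel = chrom_idx == ci
            sz = sizes[sel]
            max_start = np.maximum(lengths[ci] - sz, 0)
            starts = (rng.random(sz.size) * (max_start + 1)).astype(np.int64)
            ends = starts + sz
            ss, se = site_starts[c], site_ends[c]
            if ss.size == 0:
                continue
            # a placement [s, e) overlaps some site iff any site with
            # start < e has end > s; sites sorted by start
            j = np.searchsorted(ss, ends, side="left")
            prefix_end_max = np.concatenate(([np.iinfo(np.int64).min],
                                         np.maximum.accumulate(se)))
            hits += int((prefix_end_max[j] > starts).sum())
        counts[t] = hits

    med = float(np.median(counts))
    mean = float(counts.mean())
    if med > 0:
        fold = observed / med
    elif mean > 0:
        fold = observed / mean
    else:
        fold = _inf_or_nan(observed)
    return OverlapExpectation(observed, med, mean, fold, n_trials)


def _inf_or_nan(observed: int) -> float:
    return float("inf") if observed > 0 else float("nan")
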