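"""Chain-based feature mapping between genomes and parsimony gain/loss labels.

Mapping follows the liftOver convention for features spanning several
chains: the single chain whose aligned blocks cover the most source bases
is used, and the target interval is the span of the feature's aligned bases
within that chain only. Gain/loss labeling is sequence-level parsimony
against outgroup genomes on a fixed ((ingroup pair),(outgroups)) topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import ChainAlignment, GenomeInterval

ORTHOLOG = "ortholog"
GAIN_QUERY = "gain_query"
LOSS_TARGET = "loss_target"


@dataclass(frozen=True)
class MappedFeature:
    """Result of mapping one interval through a chain set."""

    source: GenomeInterval
    target: GenomeInterval | None
    mapped_summit: int | None
    chain_id: int | None
    mapped_fraction: float

    @property
    def mapped(self) -> bool:
        return self.target is not None


class ChainIndex:
    """Chains grouped by source (target-genome-of-the-chain) chromosome,
    for interval queries against their aligned blocks."""

    def __init__(self, chains: Iterable[ChainAlignment]):
        self._by_chrom: dict[str, list[ChainAlignment]] = {}
        for ch in chains:
            self._by_chrom.setdefault(ch.t_name, []).append(ch)

    def overlapping(self, iv: GenomeInterval) -> list[ChainAlignment]:
        out = []
        for ch in self._by_chrom.get(iv.chrom, ()):
            t0, t1 = ch.t_span()
            if iv.start < t1 and t0 < iv.end:
                out.append(ch)
        return out

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)


def _aligned_cover(ch: ChainAlignment, iv: GenomeInterval) -> int:
    """Source bases of iv inside aligned blocks of ch."""
    cover = 0
    for ts, te, _qs, _qe in ch.blocks:
        lo, hi = max(ts, iv.start), min(te, iv.end)
        if hi > lo:
            cover += hi - lo
    return cover


def map_feature(
    feature: GenomeInterval,
    chains: ChainIndex | Iterable[ChainAlignment],
    summit: int | None = None,
) -> MappedFeature:
    """Map one interval (and optionally its summit base) across genomes.

    Among chains intersecting the feature, the chain covering the most
    source bases wins (ties: higher chain score, then lower chain id).
    The mapped interval spans the first to last target base of the
    feature's aligned bases within that chain. A feature with no aligned
    base is unmapped — a value, not an error.
    """
    if not isinstance(chains, ChainIndex):
        chains = ChainIndex(chains)
    best: ChainAlignment | None = None
    best_key: tuple[int, float, float] | None = None
    for ch in chains.overlapping(feature):
        cover = _aligned_cover(ch, feature)
        if cover == 0:
            continue
        key = (cover, ch.score, -ch.chain_id)
        if best_key is None or key > best_key:
            best, best_key = ch, key
    if best is None:
        return MappedFeature(feature, None, None, None, 0.0)

    positions: list[int] = []
    for ts, te, qs, qe in best.blocks:
        lo, hi = max(ts, feature.start), min(te, feature.end)
        if hi > lo:
            if best.q_strand == "+":
                positions.append(qs + (lo - ts))
                positions.append(qs + (hi - 1 - ts))
            else:
                positions.append(qe - 1 - (lo - ts))
                positions.append(qe - 1 - (hi - 1 - ts))
    q_lo, q_hi = min(positions), max(positions) + 1
    strand = feature.strand
    if best.q_strand == "-" and strand in "+-":
        strand = "+" if strand == "-" else "-"
    target = GenomeInterval(best.q_name, q_lo, q_hi, strand)

    mapped_summit = None
    if summit is not None and feature.contains(summit):
        mapped_summit = best.map_position(summit)

    fraction = best_key[0] / len(feature)
    return MappedFeature(feature, target, mapped_summit, best.chain_id, fraction)


def label_phylogeny(
    feature: GenomeInterval,
    chains_to_target: ChainIndex | Iterable[ChainAlignment],
    chains_to_outgroups: Sequence[ChainIndex | Iterable[ChainAlignment]],
) -> str:
    """Parsimony label for a feature called in the query genome.

    Presence in a genome means chain-mappability of the locus, not feature
    occupancy. A feature that maps to the target genome is an ortholog;
    one that fails to the target but maps to >=1 outgroup was present in
    the query-target ancestor and lost on the target branch; one mappable
    nowhere arose on the query branch.
    """
    if not chains_to_outgroups:
        raise ValueError("labeling undefined without outgroup chains")
    if map_feature(feature, chains_to_target).mapped:
        return ORTHOLOG
    for out_chains in chains_to_outgroups:
        if map_feature(feature, out_chains).mapped:
            return LOSS_TARGET
    return GAIN_QUERY


def identity_chains(chrom_sizes: dict[str, int]) -> list[ChainAlignment]:
    """Self-chains mapping every base to itself — used for within-species
    (cell vs cell) comparisons so one classifier serves both settings."""
    return [
        ChainAlignment(
            chain_id=i + 1, score=float(size), t_name=chrom, t_size=size,
            q_name=chrom, q_size=size, q_strand="+",
            blocks=((0, size, 0, size),),
        )
        for i, (chrom, size) in enumerate(sorted(chrom_sizes.items()))
    ]
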