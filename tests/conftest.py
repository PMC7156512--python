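"""Shared fixtures: the seed-42 planted fixture and a random loop-instance
generator used by the classifier-oracle tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import loopevo as le
from loopevo.core import ChainAlignment, GenomeInterval
from loopevo.loops import Loop


@pytest.fixture(scope="session")
def fx42(tmp_path_factory):
    """The default synthetic two-genome fixture at seed 42."""
    out = tmp_path_factory.mktemp("fixture42")
    return le.generate(str(out), seed=42)


@dataclass
class LoopInstance:
    """One randomized classification problem."""

    query: Loop
    targets: list[Loop]
    chains: list[ChainAlignment]


def random_chain(rng: np.random.Generator, chrom: str = "chr1",
                 size: int = 100_000, chain_id: int = 1) -> ChainAlignment:
    """A random chain over one chromosome: alternating aligned blocks and
    gaps on both genomes."""
    blocks = []
    t = int(rng.integers(0, 2_000))
    q = int(rng.integers(0, 2_000))
    for _ in range(int(rng.integers(2, 8))):
        bl = int(rng.integers(200, 5_000))
        blocks.append((t, t + bl, q, q + bl))
        t += bl + int(rng.integers(1, 3_000))
        q += bl + int(rng.integers(1, 3_000))
    return ChainAlignment(chain_id=chain_id, score=1000.0, t_name=chrom,
                          t_size=size, q_name=chrom, q_size=size,
                          q_strand="+", blocks=tuple(blocks))


def random_instance(rng: np.random.Generator) -> LoopInstance:
    """A random query loop, <=20 random target loops, and a random chain
    set on one chromosome."""
    chains = [random_chain(rng, chain_id=i + 1)
              for i in range(int(rng.integers(1, 3)))]
    span_hi = max(b[1] for ch in chains for b in ch.blocks) + 3_000

    def rand_anchor() -> GenomeInterval:
        s = int(rng.integers(0, span_hi))
        return GenomeInterval("chr1", s, s + int(rng.integers(50, 400)))

    a, b = sorted((rand_anchor(), rand_anchor()),
                  key=lambda iv: iv.start)
    if a.overlaps(b):
        b = GenomeInterval("chr1", a.end + 1, a.end + 1 + len(b))
    query = Loop(cell="q", left=a, right=b, strength=1.0, loop_id="q0")

    targets = []
    for i in range(int(rng.integers(0, 19))):
        x, y = sorted((rand_anchor(), rand_anchor()), key=lambda iv: iv.start)
        if x.overlaps(y):
            y = GenomeInterval("chr1", x.end + 1, x.end + 1 + len(y))
        targets.append(Loop(cell="t", left=x, right=y, strength=1.0,
                            loop_id=f"t{i}"))
    # sometimes plant a coherent partner so class C is exercised too
    if rng.random() < 0.3:
        from loopevo.crossmap import map_feature

        ml = map_feature(query.left, chains).target
        mr = map_feature(query.right, chains).target
        if ml is not None and mr is not None and ml.end <= mr.start:
            jl = int(rng.integers(-30, 30))
            jr = int(rng.integers(-30, 30))
            x = GenomeInterval("chr1", max(0, ml.start + jl), ml.end + jl)
            y = GenomeInterval("chr1", max(0, mr.start + jr), mr.end + jr)
            if x.end <= y.start:
                targets.append(Loop(cell="t", left=x, right=y, strength=1.0,
                                    loop_id="t_planted"))
    return LoopInstance(query, targets, chains)


# ---------------------------------------------------------------------------
# Independent brute-force oracle for mapping + classification
# ---------------------------------------------------------------------------

def bruteforce_map(iv: GenomeInterval, chains) -> GenomeInterval | None:
    """Literal per-base mapping: for each chain count aligned bases of iv
    one base at a time, keep the best chain (score, then lower id on ties),
    and span the images of its aligned bases."""
    best = None
    best_key = None
    for ch in chains:
        if ch.t_name != iv.chrom:
            continue
        covered = 0
        for pos in range(iv.start, iv.end):
            for ts, te, _qs, _qe in ch.blocks:
                if ts <= pos < te:
                    covered += 1
                    break
        if covered == 0:
            continue
        key = (covered, ch.score, -ch.chain_id)
        if best_key is None or key > best_key:
            best, best_key = ch, key
    if best is None:
        return None
    images = []
    for pos in range(iv.start, iv.end):
        for ts, te, qs, qe in best.blocks:
            if ts <= pos < te:
                if best.q_strand == "+":
                    images.append(qs + (pos - ts))
                else:
                    images.append(qe - 1 - (pos - ts))
    return GenomeInterval(best.q_name, min(images), max(images) + 1)


def _ivl_overlap(a: GenomeInterval, b: GenomeInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def bruteforce_classify(query: Loop, targets: list[Loop], chains,
                        flank: int = 0) -> str:
    """All-pairs enumeration of the 7-class decision, written directly from
    the class definitions (independent of the production classifier)."""
    ml = bruteforce_map(query.left, chains)
    mr = bruteforce_map(query.right, chains)

    def grow(iv):
        if iv is None or flank == 0:
            return iv
        return GenomeInterval(iv.chrom, max(0, iv.start - flank),
                              iv.end + flank)

    gl, gr = grow(ml), grow(mr)
    ol = gl is not None and any(
        _ivl_overlap(gl, t.left) or _ivl_overlap(gl, t.right)
        for t in targets)
    orr = gr is not None and any(
        _ivl_overlap(gr, t.left) or _ivl_overlap(gr, t.right)
        for t in targets)
    coherent = False
    if gl is not None and gr is not None:
        for t in targets:
            if (_ivl_overlap(gl, t.left) and _ivl_overlap(gr, t.right)) or \
               (_ivl_overlap(gl, t.right) and _ivl_overlap(gr, t.left)):
                coherent = True
                break
    if ml is not None and mr is not None:
        if coherent:
            return "C"
        if ol and orr:
            return "B2"
        if ol or orr:
            return "B1"
        return "B0"
    if ml is None and mr is None:
        return "N0"
    return "N1A" if (ol or orr) else "N1B"
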