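"""PWM log-odds scanning of sequences, windows, and consensus libraries.

Scores are simple log-odds relative to background nucleotide frequencies
(uniform 0.25 by default). Both strands are scored at every offset; the
reported strand per offset is the higher-scoring one, '+' on ties. Windows
containing N are never scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import GenomeInterval, SignalTrack

logger = logging.getLogger("loopevo")

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Log-odds score at or below which a site is considered unbound; the
#: theoretical threshold for CTCF binding used when interpreting window maxima.
BINDING_SCORE_THRESHOLD = 1.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix as per-position log-odds over {A, C, G, T}.

    ``matrix`` has shape (L, 4), columns ordered A, C, G, T. Entries must be
    finite (pseudocount upstream when building from counts).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must be (L, 4) with L >= 1")
        if not np.isfinite(m).all():
            raise ValueError("PWM log-odds must be finite")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1].copy())

    def score_word(self, word: str) -> float:
        """Log-odds of one L-mer on the + orientation of the matrix."""
        if len(word) != self.width:
            raise ValueError(f"word length {len(word)} != PWM width {self.width}")
        idx = _encode(word)
        if (idx > 3).any():
            raise ValueError("word contains non-ACGT characters")
        return float(self.matrix[np.arange(self.width), idx].sum())

    @classmethod
    def from_counts(cls, counts: np.ndarray, background: Sequence[float] | None = None,
                    pseudocount: float = 0.5) -> "PWM":
        """Build log-odds from a position-count matrix with a pseudocount."""
        counts = np.asarray(counts, dtype=float)
        bg = np.asarray(background if background is not None else [0.25] * 4)
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
        return cls(np.log(probs / bg))

    @classmethod
    def from_file(cls, path: str) -> "PWM":
        """Read a PWM from MEME-minimal (letter-probability matrix) or a
        plain tab matrix of log-odds (L rows x 4 columns)."""
        with open(path) as fh:
            text = fh.read()
        if "letter-probability matrix" in text:
            rows = []
            in_matrix = False
            for line in text.splitlines():
                if "letter-probability matrix" in line:
                    in_matrix = True
                    continue
                if in_matrix:
                    parts = line.split()
                    if len(parts) == 4:
                        rows.append([float(x) for x in parts])
                    elif rows:
                        break
            probs = np.asarray(rows)
            probs = np.clip(probs, 1e-4, None)
            probs /= probs.sum(axis=1, keepdims=True)
            return cls(np.log(probs / 0.25))
        rows = [[float(x) for x in line.split()]
                for line in text.splitlines()
                if line.strip() and not line.startswith("#")]
        return cls(np.asarray(rows))

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# loopevo PWM: per-position log-odds, columns A C G T\n")
            for row in self.matrix:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


@dataclass(frozen=True)
class MotifHit:
    """One PWM match: interval with strand, log-odds score, and the L-mer
    read on the motif strand."""

    interval: GenomeInterval
    score: float
    word: str


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (incl. N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for i, base in enumerate(_ALPHABET):
        table[ord(base)] = i
        table[ord(base.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(idx: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score every offset of an encoded sequence against a log-odds matrix;
    offsets whose window contains a non-ACGT code score NaN."""
    L = matrix.shape[0]
    n = len(idx) - L + 1
    if n <= 0:
        return np.empty(0)
    # pad matrix with a NaN column so code 4 (N) poisons the window sum
    padded = np.hstack([matrix, np.full((L, 1), np.nan)])
    scores = np.zeros(n)
    for j in range(L):
        scores += padded[j, idx[j:j + n]]
    return scores


def scan(seq: str, pwm: PWM, threshold: float = 0.0,
         chrom: str = "seq", offset: int = 0,
         max_hits: int | None = None) -> list[MotifHit]:
    """Scan both strands of ``seq`` with overlapping L-bp windows.

    Returns hits with score strictly above ``threshold``; per offset only
    the higher-scoring strand is reported ('+' on ties). Windows containing
    N are skipped. ``offset`` shifts reported coordinates (for scanning a
    chromosome slice); ``max_hits`` optionally caps output at the strongest
    hits.
    """
    idx = _encode(seq)
    L = pwm.width
    fwd = _window_scores(idx, pwm.matrix)
    rev = _window_scores(idx, pwm.reverse_complement().matrix)
    if fwd.size == 0:
        return []
    hits: list[MotifHit] = []
    use_rev = rev > fwd  # NaN comparisons are False: N windows stay skipped
    best = np.where(use_rev, rev, fwd)
    with np.errstate(invalid="ignore"):
        keep = np.nonzero(best > threshold)[0]
    for i in keep:
        word = seq[i:i + L].upper()
        if use_rev[i]:
            strand, word = "-", reverse_complement(word)
        else:
            strand = "+"
        hits.append(MotifHit(
            GenomeInterval(chrom, offset + int(i), offset + int(i) + L, strand),
            float(best[i]), word,
        ))
    if max_hits is not None and len(hits) > max_hits:
        hits = sorted(hits, key=lambda h: -h.score)[:max_hits]
        hits.sort(key=lambda h: h.interval.start)
    return hits


def max_score_in_window(source: str | SignalTrack, chrom: str, center: int,
                        halfwidth: int, pwm: PWM | None = None) -> float:
    """Maximum log-odds over all offsets (both strands) whose motif start
    lies within ``center ± halfwidth``.

    ``source`` is either a chromosome sequence (scored with ``pwm``) or a
    precomputed per-base best-score SignalTrack. The window is clipped to
    chromosome bounds; a fully off-chromosome window raises.
    """
    if isinstance(source, SignalTrack):
        size = source.chrom_sizes[chrom]
        lo, hi = max(center - halfwidth, 0), min(center + halfwidth + 1, size)
        if hi <= lo:
            raise ValueError("window entirely off chromosome")
        vals = source.values(chrom, lo, hi)
        vals = vals[np.isfinite(vals)]
        return float(vals.max()) if vals.size else float("nan")
    if pwm is None:
        raise ValueError("pwm required when scoring a sequence")
    L = pwm.width
    lo = max(center - halfwidth, 0)
    hi = min(center + halfwidth + 1, len(source) - L + 1)
    if hi <= lo:
        raise ValueError("window entirely off chromosome")
    idx = _encode(source[lo:hi + L - 1])
    fwd = _window_scores(idx, pwm.matrix)
    rev = _window_scores(idx, pwm.reverse_complement().matrix)
    best = np.fmax(fwd, rev)
    best = best[np.isfinite(best)]
    return float(best.max()) if best.size else float("nan")


def score_consensus_library(consensi: dict[str, str], pwm: PWM,
                            n_background: int = 0, seed: int | None = None,
                            ) -> tuple[dict[str, float | None], list[float]]:
    """Best PWM match per TE consensus sequence, plus an optional background
    of length-matched i.i.d.-uniform random sequences.

    Returns (per-type max score or None when unscorable, background maxima).
    Empty records are skipped with a log entry; all-N records report None.
    """
    rng = np.random.default_rng(seed)
    per_type: dict[str, float | None] = {}
    background: list[float] = []
    for name, seq in consensi.items():
        if not seq:
            logger.info("score_consensus_library: skipping empty record %s", name)
            continue
        hits_max = _max_over_sequence(seq, pwm)
        per_type[name] = hits_max
        for _ in range(n_background):
            rand = "".join(rng.choice(list(_ALPHABET), size=len(seq)))
            bg = _max_over_sequence(rand, pwm)
            if bg is not None:
                background.append(bg)
    return per_type, background


def _max_over_sequence(seq: str, pwm: PWM) -> float | None:
    idx = _encode(seq)
    fwd = _window_scores(idx, pwm.matrix)
    rev = _window_scores(idx, pwm.reverse_complement().matrix)
    best = np.fmax(fwd, rev)
    best = best[np.isfinite(best)]
    return float(best.max()) if best.size else None


CONVERGENT = "convergent"
DIVERGENT = "divergent"
TANDEM_LEFT = "tandem_left"
TANDEM_RIGHT = "tandem_right"
MISSING = "missing"


def best_hit_near(hits: Iterable[MotifHit], chrom: str, summit: int,
                  halfwidth: int = 50) -> MotifHit | None:
    """Best-scoring hit whose motif start lies within ±halfwidth of the
    summit, requiring score > 0."""
    best: MotifHit | None = None
    for h in hits:
        if h.interval.chrom != chrom:
            continue
        if abs(h.interval.start - summit) <= halfwidth and h.score > 0:
            if best is None or h.score > best.score:
                best = h
    return best


def anchor_orientation(left_summit: tuple[str, int], right_summit: tuple[str, int],
                       hits: Iterable[MotifHit], halfwidth: int = 50) -> str:
    """Motif-orientation class of a loop from its two anchor summits.

    Convergent (inward-pointing) means the left-anchor motif on '+' and the
    right-anchor motif on '−'. ``missing`` when either anchor lacks a hit
    with positive score within ±halfwidth of its summit.
    """
    hits = list(hits)
    left = best_hit_near(hits, *left_summit, halfwidth=halfwidth)
    right = best_hit_near(hits, *right_summit, halfwidth=halfwidth)
    if left is None or right is None:
        return MISSING
    key = (left.interval.strand, right.interval.strand)
    return {
        ("+", "-"): CONVERGENT,
        ("-", "+"): DIVERGENT,
        ("+", "+"): TANDEM_RIGHT,
        ("-", "-"): TANDEM_LEFT,
    }[key]


def default_ctcf_pwm(strength: float = 1.5, seed: int = 7) -> PWM:
    """A synthetic 20-bp CTCF-like PWM for fixtures and examples.

    Not the published CTCF matrix (supply that via ``PWM.from_file`` for
    real genomes): a deterministic informative matrix whose consensus
    scores ``20 * strength``-ish and whose background expectation is
    negative, so planted motifs are recoverable at threshold 0.
    """
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=20)
    m = np.full((20, 4), fill_value=0.0)
    for j, b in enumerate(consensus):
        m[j, :] = -strength / 2
        m[j, b] = strength
    return PWM(m)
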