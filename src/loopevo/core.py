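"""Coordinate conventions, interval algebra, and file I/O.

Every coordinate in this package is 0-based, half-open (BED convention).
Summits are absolute 0-based positions. All readers produce these types;
all downstream modules consume them.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger("loopevo")

#: RepeatMasker families excluded from every TE analysis (not transposons).
EXCLUDED_REPEAT_FAMILIES = frozenset(
    {"Low_complexity", "Satellite", "Simple_repeat", "tRNA", "rRNA",
     "scRNA", "snRNA", "srpRNA"}
)

STRANDS = ("+", "-", ".")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A located genomic feature: ``chrom:[start, end)`` on ``strand``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end < self.start:
            raise ValueError(f"end < start: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomeInterval") -> bool:
        """>=1 bp overlap (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to(self, pos: int) -> int:
        """Base distance from ``pos`` to the closest base of the interval
        (0 if contained)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak with an enrichment signal and an optional summit."""

    interval: GenomeInterval
    signal: float
    summit: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"negative signal on {self.interval}")
        if self.summit is not None and not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside {self.interval}"
            )


@dataclass(frozen=True)
class TEAnnotation:
    """One RepeatMasker insertion: repeat name/family plus percent divergence
    from the family consensus (the age proxy)."""

    interval: GenomeInterval
    te_type: str
    te_family: str
    pct_divergence: float
    nearest_gene: str | None = None
    tss_distance: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_divergence <= 100.0:
            raise ValueError(
                f"pct_divergence {self.pct_divergence} outside [0, 100]"
            )
        if self.tss_distance is not None and self.tss_distance < 0:
            raise ValueError("negative tss_distance")


class SignalTrack:
    """Per-base signal over a genome, fixed step 1.

    Queries outside covered regions return the missing sentinel (NaN),
    never raise.
    """

    def __init__(self, chrom_sizes: dict[str, int], fill: float = np.nan):
        self._fill = fill
        self._data = {
            c: np.full(n, fill, dtype=float) for c, n in chrom_sizes.items()
        }

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self._data.items()}

    def set_values(self, chrom: str, start: int, values: np.ndarray) -> None:
        arr = self._data[chrom]
        arr[start:start + len(values)] = values

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal for [start, end); out-of-bounds bases yield the sentinel."""
        out = np.full(end - start, self._fill, dtype=float)
        arr = self._data.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start:hi - start] = arr[lo:hi]
        return out

    @classmethod
    def from_bedgraph(cls, path: str, chrom_sizes: dict[str, int]) -> "SignalTrack":
        track = cls(chrom_sizes)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, start, end, value = line.split()[:4]
                s, e = int(start), int(end)
                track.set_values(chrom, s, np.full(e - s, float(value)))
        return track

    @classmethod
    def from_wiggle(cls, path: str, chrom_sizes: dict[str, int]) -> "SignalTrack":
        """Fixed-step wiggle, step=1 span=1 only."""
        track = cls(chrom_sizes)
        chrom, pos = None, 0
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("track"):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(f.split("=") for f in line.split()[1:])
                    if int(kv.get("step", 1)) != 1:
                        raise ValueError("only step=1 fixed-step wiggle supported")
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1  # wiggle is 1-based
                else:
                    track._data[chrom][pos] = float(line)
                    pos += 1
        return track


class ExpressionTable:
    """Gene -> TPM per cell label (quantile-normalized upstream)."""

    def __init__(self, tpm: "pd.DataFrame"):
        import pandas as pd  # local: keep core importable fast

        if (tpm.to_numpy() < 0).any():
            raise ValueError("negative TPM")
        self._tpm = tpm

    @property
    def cells(self) -> list[str]:
        return list(self._tpm.columns)

    @property
    def genes(self) -> list[str]:
        return list(self._tpm.index)

    def tpm(self, gene: str, cell: str) -> float:
        if cell not in self._tpm.columns:
            raise KeyError(f"unknown cell label {cell!r}")
        try:
            return float(self._tpm.at[gene, cell])
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._tpm.index

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionTable":
        import pandas as pd

        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str) -> None:
        self._tpm.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Peak I/O and merging
# ---------------------------------------------------------------------------

def read_peaks(path: str, dialect: str = "narrowPeak") -> list[Peak]:
    """Read an ENCODE narrowPeak (10 col) or broadPeak (9 col) file.

    narrowPeak summit = start + column-10 offset; broadPeak records carry no
    summit, so the interval midpoint stands in for it.
    """
    if dialect not in ("narrowPeak", "broadPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = 10 if dialect == "narrowPeak" else 9
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < ncols:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {ncols} columns for "
                    f"{dialect}, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5] if fields[5] in STRANDS else "."
                signal = float(fields[6])
                if dialect == "narrowPeak":
                    offset = int(fields[9])
                    if offset < 0:
                        raise ValueError(f"negative summit offset {offset}")
                    summit = start + offset
                else:
                    summit = (start + end) // 2
                peaks.append(
                    Peak(GenomeInterval(chrom, start, end, strand),
                         signal, summit, name or None)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str) -> None:
    """Write narrowPeak (canonical 10-column dialect)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            offset = (p.summit - iv.start) if p.summit is not None else -1
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{p.name or f'peak_{i}'}\t0\t{iv.strand}\t"
                f"{p.signal:g}\t-1\t-1\t{offset}\n"
            )


def merge_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Merge overlapping or book-ended peaks (bedtools merge semantics,
    distance 0).

    The merged summit is the centroid (round-half-to-even) of constituent
    summits; the merged signal is the max, so the strongest constituent
    remains representative.
    """
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start,
                                           p.interval.end))
    out: list[Peak] = []
    component: list[Peak] = []

    def _flush() -> None:
        if not component:
            return
        chrom = component[0].interval.chrom
        start = min(p.interval.start for p in component)
        end = max(p.interval.end for p in component)
        summits = [p.summit for p in component if p.summit is not None]
        summit = round(statistics.fmean(summits)) if summits else None
        signal = max(p.signal for p in component)
        name = component[0].name
        out.append(Peak(GenomeInterval(chrom, start, end), signal, summit, name))

    for p in ordered:
        if (component
                and p.interval.chrom == component[0].interval.chrom
                and p.interval.start <= max(q.interval.end for q in component)):
            component.append(p)
        else:
            _flush()
            component = [p]
    _flush()
    return out


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedpeRecord:
    """One intrachromosomal paired-anchor record, left anchor first."""

    left: GenomeInterval
    right: GenomeInterval
    name: str = "."
    score: str = "."
    extra: tuple[str, ...] = ()

    @property
    def chrom(self) -> str:
        return self.left.chrom

    def normalized(self) -> "BedpeRecord":
        if self.right.start < self.left.start:
            return replace(self, left=self.right, right=self.left)
        return self


def read_bedpe(path: str) -> list[BedpeRecord]:
    """Read BEDPE; anchors normalized left-first; interchromosomal records
    are skipped with a logged count (loops here are intrachromosomal)."""
    records: list[BedpeRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                missing = ["chrom1", "start1", "end1",
                           "chrom2", "start2", "end2"][len(fields):]
                raise ValueError(
                    f"{path}:{lineno}: BEDPE needs 6 columns; "
                    f"missing {', '.join(missing)}"
                )
            c1, s1, e1, c2, s2, e2 = fields[:6]
            if c1 != c2:
                skipped += 1
                continue
            rec = BedpeRecord(
                GenomeInterval(c1, int(s1), int(e1)),
                GenomeInterval(c2, int(s2), int(e2)),
                fields[6] if len(fields) > 6 else ".",
                fields[7] if len(fields) > 7 else ".",
                tuple(fields[8:]),
            ).normalized()
            records.append(rec)
    if skipped:
        logger.info("read_bedpe(%s): skipped %d interchromosomal records",
                    path, skipped)
    return records


def write_bedpe(records: Sequence[BedpeRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [r.left.chrom, str(r.left.start), str(r.left.end),
                    r.right.chrom, str(r.right.start), str(r.right.end),
                    r.name, r.score, *r.extra]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# UCSC chain files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainAlignment:
    """One pairwise-alignment chain, blocks in absolute +-strand coordinates
    on both genomes.

    ``blocks`` is a tuple of (t_start, t_end, q_start, q_end). Target
    coordinates increase along the chain; query coordinates increase for
    '+'-strand chains and decrease for '-'-strand chains (reflection through
    q_size puts them on the + strand).
    """

    chain_id: int
    score: float
    t_name: str
    t_size: int
    q_name: str
    q_size: int
    q_strand: str
    blocks: tuple[tuple[int, int, int, int], ...]

    def t_span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    def map_position(self, pos: int) -> int | None:
        """Map one target-genome base to the query genome (+ strand), or
        None if it falls in a gap."""
        for ts, te, qs, qe in self.blocks:
            if ts <= pos < te:
                if self.q_strand == "+":
                    return qs + (pos - ts)
                return qe - 1 - (pos - ts)
        return None


def read_chain(path: str) -> list[ChainAlignment]:
    """Parse a UCSC chain file into absolute, 0-based half-open block pairs.

    '-'-strand query blocks are reflected through q_size onto the + strand.
    Block sizes inconsistent with the header span raise, naming the chain.
    """
    chains: list[ChainAlignment] = []
    with open(path) as fh:
        header: list[str] | None = None
        blocks: list[tuple[int, int, int, int]] = []
        t_cursor = q_cursor = 0

        def _finish() -> None:
            nonlocal header
            if header is None:
                return
            (_, score, t_name, t_size, _t_strand, t_start, t_end,
             q_name, q_size, q_strand, q_start, q_end, cid) = header
            if t_cursor != int(t_end) or q_cursor != int(q_end):
                raise ValueError(
                    f"chain {cid}: block sizes inconsistent with header span "
                    f"(t ends at {t_cursor}, expected {t_end}; "
                    f"q ends at {q_cursor}, expected {q_end})"
                )
            chains.append(ChainAlignment(
                chain_id=int(cid), score=float(score),
                t_name=t_name, t_size=int(t_size),
                q_name=q_name, q_size=int(q_size), q_strand=q_strand,
                blocks=tuple(blocks),
            ))
            header = None

        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                _finish()
                header = line.split()
                if len(header) != 13:
                    raise ValueError(f"malformed chain header: {line!r}")
                blocks = []
                t_cursor = int(header[5])
                q_cursor = int(header[10])
            else:
                parts = line.split()
                size = int(parts[0])
                q_size_total = int(header[8])
                q_strand = header[9]
                ts, te = t_cursor, t_cursor + size
                if q_strand == "+":
                    qs, qe = q_cursor, q_cursor + size
                else:  # reflect strand coordinates through q_size
                    qs = q_size_total - (q_cursor + size)
                    qe = q_size_total - q_cursor
                blocks.append((ts, te, qs, qe))
                if len(parts) == 3:
                    t_cursor += size + int(parts[1])
                    q_cursor += size + int(parts[2])
                else:
                    t_cursor += size
                    q_cursor += size
        _finish()
    return chains


def write_chain(chains: Sequence[ChainAlignment], path: str) -> None:
    """Write chains back to UCSC chain format (canonical form)."""
    with open(path, "w") as fh:
        for ch in chains:
            t_start, t_end = ch.blocks[0][0], ch.blocks[-1][1]
            if ch.q_strand == "+":
                q_start, q_end = ch.blocks[0][2], ch.blocks[-1][3]
            else:
                # strand coordinates: reflect the +-strand extremes back
                q_start = ch.q_size - ch.blocks[0][3]
                q_end = ch.q_size - ch.blocks[-1][2]
            fh.write(
                f"chain {ch.score:g} {ch.t_name} {ch.t_size} + "
                f"{t_start} {t_end} {ch.q_name} {ch.q_size} {ch.q_strand} "
                f"{q_start} {q_end} {ch.chain_id}\n"
            )
            for i, (ts, te, qs, qe) in enumerate(ch.blocks):
                size = te - ts
                if i == len(ch.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    nts = ch.blocks[i + 1][0]
                    dt = nts - te
                    if ch.q_strand == "+":
                        dq = ch.blocks[i + 1][2] - qe
                    else:
                        dq = qs - ch.blocks[i + 1][3]
                    fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# RepeatMasker-style TE BED and TSS BED
# ---------------------------------------------------------------------------

def read_repeats(path: str, exclude_families: frozenset[str] = EXCLUDED_REPEAT_FAMILIES,
                 ) -> list[TEAnnotation]:
    """Read a BED6+ TE table: chrom start end te_type score strand
    te_family pct_divergence [nearest_gene tss_distance].

    Families in ``exclude_families`` (simple/low-complexity/structural-RNA
    repeats, which are not transposons) are dropped on load.
    """
    out: list[TEAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{lineno}: need >= 8 columns")
            family = f[6]
            if family in exclude_families:
                continue
            gene = f[8] if len(f) > 8 and f[8] != "." else None
            dist = int(f[9]) if len(f) > 9 and f[9] != "." else None
            out.append(TEAnnotation(
                GenomeInterval(f[0], int(f[1]), int(f[2]),
                               f[5] if f[5] in STRANDS else "."),
                te_type=f[3], te_family=family,
                pct_divergence=float(f[7]),
                nearest_gene=gene, tss_distance=dist,
            ))
    return out


def write_repeats(repeats: Sequence[TEAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for te in repeats:
            iv = te.interval
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end), te.te_type, "0",
                iv.strand, te.te_family, f"{te.pct_divergence:g}",
                te.nearest_gene or ".",
                str(te.tss_distance) if te.tss_distance is not None else ".",
            ]) + "\n")


def read_tss_bed(path: str) -> list[tuple[str, int, str]]:
    """Read a TSS BED (one furthest-5' TSS per gene): (chrom, pos, gene)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), f[3] if len(f) > 3 else "."))
    return out


def write_tss_bed(tss: Sequence[tuple[str, int, str]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, pos, gene in tss:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{gene}\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load a (small) FASTA into memory as upper-case strings."""
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
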