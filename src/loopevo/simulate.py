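"""Synthetic two-genome fixture with planted ground truth.

The generator builds the chain first and places every feature relative to
its aligned blocks and gaps, so each loop's intended conservation class is
guaranteed by construction (anchors meant to be non-orthologous sit wholly
inside alignment gaps). Sequence content is i.i.d. uniform except planted
CTCF motifs, which makes motif-recovery expectations analytic. A JSON
manifest records every planted label; recovery tests read the manifest,
never external data.

Planted study conditions (defaults): two genomes of 2 chromosomes x 2 Mb;
12 TE types of which 2 are CTCF-enriched at 10x the null binding rate;
300 loops in the query cell with class mix
C 25% / B2 10% / B1 15% / B0 15% / N1A 10% / N1B 15% / N0 10%;
a 20-TPM expression effect on the genes of variable loops with 5-TPM
per-cell noise.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import (ChainAlignment, GenomeInterval, Peak, TEAnnotation,
                   write_bedpe, write_chain, write_fasta, write_peaks,
                   write_repeats, write_tss_bed, BedpeRecord)
from .crossmap import ChainIndex
from .enrichment import HUMAN_RATE
from .loops import Loop, classify_all
from .motif import PWM, default_ctcf_pwm, reverse_complement

SCHEMA_VERSION = 2

DEFAULT_CLASS_MIX = {"C": 0.25, "B2": 0.10, "B1": 0.15, "B0": 0.15,
                     "N1A": 0.10, "N1B": 0.15, "N0": 0.10}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted parameters of the two-genome fixture."""

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_te_types: int = 12
    n_enriched_types: int = 2
    copies_enriched: int = 200
    copies_null: int = 150
    null_binding_rate: float = 0.02
    enrichment_fold: float = 10.0
    n_loops: int = 300
    class_mix: tuple[tuple[str, float], ...] = tuple(DEFAULT_CLASS_MIX.items())
    te_anchor_fraction: float = 0.3
    expression_effect: float = 20.0
    expression_noise_sd: float = 5.0
    base_tpm_range: tuple[float, float] = (30.0, 80.0)
    te_length: int = 300
    anchor_halfwidth: int = 100       # peak = summit +/- halfwidth
    motif_strength: float = 1.5
    query_cell: str = "qcell"
    target_cell: str = "tcell"
    min_age_years: float = 1.0e7
    max_age_years: float = 1.2e8
    substitution_rate: float = HUMAN_RATE

    @property
    def enriched_binding_rate(self) -> float:
        return self.null_binding_rate * self.enrichment_fold


@dataclass
class PlantedLoop:
    loop_id: str
    chrom: str
    conservation_class: str
    te_derived: bool
    te_side: str | None
    te_type: str | None
    gene: str
    l_summit: int
    r_summit: int
    strength: float
    target_loop_ids: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery assertions."""

    config: SyntheticConfig
    chrom_sizes_a: dict[str, int]
    chrom_sizes_b: dict[str, int]
    te_types: dict[str, dict]          # type -> family, age, divergence, counts
    enriched_types: tuple[str, ...]
    loops: list[PlantedLoop]
    genes: dict[str, dict]             # gene -> base tpm, effect applied
    expected_delta_tpm_effect: float   # analytic observable contrast
    motif_consensus: str
    n_shared_sites: int
    n_a_only_sites: int
    n_b_only_sites: int

    def class_of(self, loop_id: str) -> str:
        for pl in self.loops:
            if pl.loop_id == loop_id:
                return pl.conservation_class
        raise KeyError(loop_id)


@dataclass
class SyntheticFixture:
    """In-memory handles plus on-disk paths of one generated fixture."""

    truth: SyntheticTruth
    paths: dict[str, str]
    query_loops: list[Loop]
    target_loops: list[Loop]
    chains_ab: list[ChainAlignment]
    chains_ba: list[ChainAlignment]
    query_peaks: list[Peak]
    target_peaks: list[Peak]
    repeats: list[TEAnnotation]
    tss: list[tuple[str, int, str]]
    pwm: PWM


class _ChromBuilder:
    """Sequential two-genome layout for one chromosome: advances query and
    target cursors through aligned and one-sided segments, accumulating
    chain blocks."""

    def __init__(self, chrom: str, start: int = 1000):
        self.chrom = chrom
        self.q = start
        self.t = start
        self.blocks: list[list[int]] = []  # [t_on_A, end_A, start_B, end_B]

    def aligned(self, n: int) -> tuple[int, int]:
        q0, t0 = self.q, self.t
        if self.blocks and self.blocks[-1][1] == q0 and self.blocks[-1][3] == t0:
            self.blocks[-1][1] += n
            self.blocks[-1][3] += n
        else:
            self.blocks.append([q0, q0 + n, t0, t0 + n])
        self.q += n
        self.t += n
        return q0, t0

    def q_only(self, n: int) -> int:
        q0 = self.q
        self.q += n
        return q0

    def t_only(self, n: int) -> int:
        t0 = self.t
        self.t += n
        return t0


def folded_normal_mean(mu: float, sigma: float) -> float:
    """E|X| for X ~ N(mu, sigma)."""
    if sigma == 0:
        return abs(mu)
    from scipy.stats import norm

    return (sigma * math.sqrt(2 / math.pi) * math.exp(-mu**2 / (2 * sigma**2))
            + mu * (1 - 2 * norm.cdf(-mu / sigma)))


def expected_observable_effect(effect: float, noise_sd: float) -> float:
    """Analytic E[dTPM | variable] - E[dTPM | conserved] under independent
    per-cell noise: the folded-normal contrast, not the raw planted shift."""
    s = noise_sd * math.sqrt(2.0)
    return folded_normal_mean(effect, s) - folded_normal_mean(0.0, s)


def _class_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    counts = {c: int(round(f * n)) for c, f in mix.items()}
    drift = n - sum(counts.values())
    order = sorted(mix, key=lambda c: -mix[c])
    i = 0
    while drift != 0:
        counts[order[i % len(order)]] += 1 if drift > 0 else -1
        drift += -1 if drift > 0 else 1
        i += 1
    return counts


def generate(out_dir: str, seed: int,
             config: SyntheticConfig | None = None,
             self_check: bool = True) -> SyntheticFixture:
    """Write the full fixture to ``out_dir`` and return in-memory handles.

    Deterministic given (config, seed). With ``self_check`` the generated
    query loops are classified against the generated target set and any
    loop whose recovered class differs from the intended one raises.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)

    pwm = default_ctcf_pwm(strength=cfg.motif_strength)
    consensus = pwm.consensus
    half = cfg.anchor_halfwidth

    te_type_names = [f"TE{i + 1:02d}" for i in range(cfg.n_te_types)]
    enriched = tuple(te_type_names[:cfg.n_enriched_types])
    families = ["SINE", "LINE", "LTR", "DNA"]
    ages = np.linspace(cfg.min_age_years, cfg.max_age_years, cfg.n_te_types)
    te_info = {
        name: {
            "family": families[i % len(families)],
            "age_years": float(ages[i]),
            "pct_divergence": float(ages[i] * cfg.substitution_rate * 100.0),
            "enriched": name in enriched,
            "n_copies": 0,
            "n_bound": 0,
        }
        for i, name in enumerate(te_type_names)
    }

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    builders = {c: _ChromBuilder(c) for c in chroms}

    # planted-motif registries: (chrom, start, strand) per genome
    motifs_a: list[tuple[str, int, str]] = []
    motifs_b: list[tuple[str, int, str]] = []
    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    repeats: list[TEAnnotation] = []
    tss: list[tuple[str, int, str]] = []
    query_loops: list[Loop] = []
    target_loops: list[Loop] = []
    tads: list[tuple[str, int, int]] = []
    planted_loops: list[PlantedLoop] = []
    genes: dict[str, dict] = {}

    def _plant_site(genome: str, chrom: str, summit: int, strand: str,
                    signal: float, name: str) -> Peak:
        motif_start = summit - pwm.width // 2
        peak = Peak(GenomeInterval(chrom, summit - half, summit + half),
                    signal, summit, name)
        if genome == "A":
            motifs_a.append((chrom, motif_start, strand))
            peaks_a.append(peak)
        else:
            motifs_b.append((chrom, motif_start, strand))
            peaks_b.append(peak)
        return peak

    # ---- loops ------------------------------------------------------------
    class_counts = _class_counts(dict(cfg.class_mix), cfg.n_loops)
    class_seq: list[str] = []
    for c, k in class_counts.items():
        class_seq.extend([c] * k)
    rng.shuffle(class_seq)

    per_chrom = math.ceil(cfg.n_loops / cfg.n_chroms) if cfg.n_loops else 0
    t_loop_counter = 0
    for i, cls in enumerate(class_seq):
        chrom = chroms[min(i // per_chrom, cfg.n_chroms - 1)]
        b = builders[chrom]
        te_flag = rng.random() < cfg.te_anchor_fraction
        loop_id = f"{cfg.query_cell}_{i:04d}"
        signal_l = float(rng.uniform(5, 50))
        signal_r = float(rng.uniform(5, 50))

        b.aligned(1000)
        # left anchor zone
        l_mappable = cls not in ("N1A", "N1B", "N0")
        if l_mappable:
            q0, t0 = b.aligned(600)
            l_summit, tl_summit = q0 + 300, t0 + 300
        else:
            q0 = b.q_only(600)
            b.t_only(600)
            l_summit, tl_summit = q0 + 300, None
        # mid region with two potential decoy target anchors
        _q1, t1 = b.aligned(1500)
        p1_summit = t1 + 750
        _q2, t2 = b.aligned(1500)
        p2_summit = t2 + 750
        b.aligned(1000)
        # right anchor zone
        r_mappable = cls != "N0"
        if r_mappable:
            q0, t0 = b.aligned(600)
            r_summit, tr_summit = q0 + 300, t0 + 300
        else:
            q0 = b.q_only(600)
            b.t_only(600)
            r_summit, tr_summit = q0 + 300, None
        b.aligned(1500)

        lp = _plant_site("A", chrom, l_summit, "+", signal_l, f"{loop_id}_L")
        rp = _plant_site("A", chrom, r_summit, "-", signal_r, f"{loop_id}_R")
        strength = float(rng.poisson(30 if cls == "C" else 15) + 1)
        query_loops.append(Loop(
            cell=cfg.query_cell, left=lp.interval, right=rp.interval,
            strength=strength, left_peak=lp, right_peak=rp, loop_id=loop_id,
        ))

        # target-side loops establishing the intended class
        def _target_loop(ls: int, rs: int) -> str:
            nonlocal t_loop_counter
            tid = f"{cfg.target_cell}_{t_loop_counter:04d}"
            t_loop_counter += 1
            tlp = _plant_site("B", chrom, ls, "+", float(rng.uniform(5, 50)),
                              f"{tid}_L")
            trp = _plant_site("B", chrom, rs, "-", float(rng.uniform(5, 50)),
                              f"{tid}_R")
            target_loops.append(Loop(
                cell=cfg.target_cell, left=tlp.interval, right=trp.interval,
                strength=float(rng.poisson(20) + 1),
                left_peak=tlp, right_peak=trp, loop_id=tid,
            ))
            return tid

        matched: tuple[str, ...] = ()
        if cls == "C":
            matched = (_target_loop(tl_summit, tr_summit),)
        elif cls == "B2":
            matched = (_target_loop(tl_summit, p1_summit),
                       _target_loop(p2_summit, tr_summit))
        elif cls == "B1":
            matched = (_target_loop(tl_summit, p1_summit),)
        elif cls == "N1A":
            matched = (_target_loop(p1_summit, tr_summit),)
        # B0, N1B, N0: no target loop in this slot

        # TE attribution on the anchor that counts toward the class
        te_side = te_type = None
        if te_flag:
            te_side = "right" if cls == "B1" else "left"
            te_type = enriched[int(rng.integers(len(enriched)))] if enriched \
                else None
        if te_side and te_type:
            summit = l_summit if te_side == "left" else r_summit
            info = te_info[te_type]
            repeats.append(TEAnnotation(
                GenomeInterval(chrom, summit - cfg.te_length // 2,
                               summit + cfg.te_length // 2),
                te_type=te_type, te_family=info["family"],
                pct_divergence=info["pct_divergence"],
            ))
            info["n_copies"] += 1
            info["n_bound"] += 1
        else:
            te_side = te_type = None

        gene = f"g_{loop_id}"
        tss.append((chrom, l_summit + 300, gene))
        if i % 10 == 0:
            tads.append((chrom, l_summit, r_summit))
        planted_loops.append(PlantedLoop(
            loop_id=loop_id, chrom=chrom, conservation_class=cls,
            te_derived=te_type is not None, te_side=te_side, te_type=te_type,
            gene=gene, l_summit=l_summit, r_summit=r_summit,
            strength=strength, target_loop_ids=matched,
        ))

    # ---- native CTCF landscape sites (shared / A-only / B-only) -----------
    n_shared, n_a_only, n_b_only = 60, 40, 30
    site_kinds = (["shared"] * n_shared + ["a_only"] * n_a_only
                  + ["b_only"] * n_b_only)
    for i, kind in enumerate(site_kinds):
        chrom = chroms[i % cfg.n_chroms]
        b = builders[chrom]
        q0, t0 = b.aligned(500)
        sig = float(rng.uniform(5, 50))
        if kind in ("shared", "a_only"):
            _plant_site("A", chrom, q0 + 250, "+", sig, f"native_a_{i}")
        if kind in ("shared", "b_only"):
            _plant_site("B", chrom, t0 + 250, "+", sig, f"native_b_{i}")

    # a few intergenic genes so TE-region TSS distances spread over bins
    for chrom in chroms:
        b = builders[chrom]
        for j in range(5):
            q0, _ = b.aligned(400)
            gname = f"g_bg_{chrom}_{j}"
            tss.append((chrom, q0 + 200, gname))
            genes[gname] = {"base": float(rng.uniform(*cfg.base_tpm_range)),
                            "effect": 0.0}
        b.aligned(2000)

    # ---- TE catalog in query-only sequence (species-specific insertions) --
    copy_plan: list[str] = []
    for name in te_type_names:
        n_copies = (cfg.copies_enriched if name in enriched
                    else cfg.copies_null)
        copy_plan.extend([name] * n_copies)
    rng.shuffle(copy_plan)
    for i, name in enumerate(copy_plan):
        chrom = chroms[i % cfg.n_chroms]
        b = builders[chrom]
        b.q_only(100)
        q0 = b.q_only(cfg.te_length)
        b.q_only(100)
        info = te_info[name]
        repeats.append(TEAnnotation(
            GenomeInterval(chrom, q0, q0 + cfg.te_length),
            te_type=name, te_family=info["family"],
            pct_divergence=info["pct_divergence"],
        ))
        info["n_copies"] += 1
        rate = (cfg.enriched_binding_rate if info["enriched"]
                else cfg.null_binding_rate)
        if rng.random() < rate:
            summit = q0 + cfg.te_length // 2
            _plant_site("A", chrom, summit, "+", float(rng.uniform(5, 50)),
                        f"te_site_{i}")
            info["n_bound"] += 1

    # ---- chains and chromosome sizes --------------------------------------
    for c in chroms:
        b = builders[c]
        if b.q > cfg.chrom_length or b.t > cfg.chrom_length:
            raise ValueError(
                f"layout for {c} exceeds chrom_length={cfg.chrom_length} "
                f"(q={b.q}, t={b.t}); enlarge chrom_length or shrink counts"
            )
    sizes_a = {c: cfg.chrom_length for c in chroms}
    sizes_b = {c: cfg.chrom_length for c in chroms}
    chains_ab = [
        ChainAlignment(chain_id=i + 1, score=1e6, t_name=c,
                       t_size=sizes_a[c], q_name=c, q_size=sizes_b[c],
                       q_strand="+",
                       blocks=tuple(tuple(blk) for blk in builders[c].blocks))
        for i, c in enumerate(chroms)
    ]
    chains_ba = [
        ChainAlignment(chain_id=ch.chain_id, score=ch.score,
                       t_name=ch.q_name, t_size=ch.q_size,
                       q_name=ch.t_name, q_size=ch.t_size, q_strand="+",
                       blocks=tuple((qs, qe, ts, te)
                                    for ts, te, qs, qe in ch.blocks))
        for ch in chains_ab
    ]

    # ---- sequences with planted motifs ------------------------------------
    seqs_a = {c: rng.integers(0, 4, size=sizes_a[c], dtype=np.uint8)
              for c in chroms}
    seqs_b = {c: rng.integers(0, 4, size=sizes_b[c], dtype=np.uint8)
              for c in chroms}
    lut = {b: i for i, b in enumerate("ACGT")}
    fwd_codes = np.array([lut[x] for x in consensus], dtype=np.uint8)
    rev_codes = np.array([lut[x] for x in reverse_complement(consensus)],
                         dtype=np.uint8)
    for seqs, motifs in ((seqs_a, motifs_a), (seqs_b, motifs_b)):
        for chrom, start, strand in motifs:
            seqs[chrom][start:start + pwm.width] = (
                fwd_codes if strand == "+" else rev_codes
            )

    def _decode(codes: np.ndarray) -> str:
        return _BASES[codes].tobytes().decode("ascii")

    fasta_a = {c: _decode(seqs_a[c]) for c in chroms}
    fasta_b = {c: _decode(seqs_b[c]) for c in chroms}

    # ---- expression -------------------------------------------------------
    rows = []
    for pl in planted_loops:
        base = float(rng.uniform(*cfg.base_tpm_range))
        effect = cfg.expression_effect if pl.conservation_class != "C" else 0.0
        genes[pl.gene] = {"base": base, "effect": effect}
    for gname, info in genes.items():
        noise_q = float(rng.normal(0, cfg.expression_noise_sd))
        noise_t = float(rng.normal(0, cfg.expression_noise_sd))
        q_tpm = max(0.0, info["base"] + noise_q)
        t_tpm = max(0.0, info["base"] + info["effect"] + noise_t)
        rows.append((gname, q_tpm, t_tpm))

    # ---- write everything --------------------------------------------------
    paths = {key: os.path.join(out_dir, fname) for key, fname in {
        "genome_a": "genomeA.fa", "genome_b": "genomeB.fa",
        "chain_ab": "a_to_b.chain", "chain_ba": "b_to_a.chain",
        "peaks_q": f"{cfg.query_cell}.genomeA.narrowPeak",
        "peaks_t": f"{cfg.target_cell}.genomeB.narrowPeak",
        "repeats": "repeats.genomeA.bed",
        "loops_q": f"{cfg.query_cell}.loops.bedpe",
        "loops_t": f"{cfg.target_cell}.loops.bedpe",
        "tads": f"tads.{cfg.query_cell}.bed",
        "tss": "tss.genomeA.bed",
        "expression": "expression.tsv",
        "h3k4me3": f"h3k4me3.{cfg.query_cell}.bedgraph",
        "h3k4me1": f"h3k4me1.{cfg.query_cell}.bedgraph",
        "phastcons": "phastcons.genomeA.bedgraph",
        "pwm": "ctcf_pwm.txt",
        "manifest": "manifest.json",
    }.items()}

    write_fasta(fasta_a, paths["genome_a"])
    write_fasta(fasta_b, paths["genome_b"])
    write_chain(chains_ab, paths["chain_ab"])
    write_chain(chains_ba, paths["chain_ba"])
    write_peaks(peaks_a, paths["peaks_q"])
    write_peaks(peaks_b, paths["peaks_t"])
    write_repeats(repeats, paths["repeats"])
    write_tss_bed(sorted(tss), paths["tss"])
    pwm.to_file(paths["pwm"])

    def _loops_to_bedpe(loops: list[Loop]) -> list[BedpeRecord]:
        return [BedpeRecord(l.left, l.right, l.loop_id, f"{l.strength:g}")
                for l in loops]

    write_bedpe(_loops_to_bedpe(query_loops), paths["loops_q"])
    write_bedpe(_loops_to_bedpe(target_loops), paths["loops_t"])

    with open(paths["tads"], "w") as fh:
        for chrom, x, y in tads:
            fh.write(f"{chrom}\t{x}\t{y}\ttad\n")

    with open(paths["expression"], "w") as fh:
        fh.write(f"gene\t{cfg.query_cell}\t{cfg.target_cell}\n")
        for gname, q_tpm, t_tpm in sorted(rows):
            fh.write(f"{gname}\t{q_tpm:.4f}\t{t_tpm:.4f}\n")

    def _write_bedgraph(path: str, regions: list[tuple[str, int, int, float]],
                        baseline: float) -> None:
        with open(path, "w") as fh:
            for c in chroms:
                fh.write(f"{c}\t0\t{sizes_a[c]}\t{baseline:g}\n")
            for chrom, s, e, v in regions:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    _write_bedgraph(paths["h3k4me3"],
                    [(pl.chrom, pl.l_summit - 200, pl.l_summit + 200, 10.0)
                     for pl in planted_loops], 0.1)
    _write_bedgraph(paths["h3k4me1"],
                    [(pl.chrom, pl.r_summit - 200, pl.r_summit + 200, 8.0)
                     for pl in planted_loops], 0.1)
    _write_bedgraph(paths["phastcons"],
                    [(pl.chrom, s - 250, s + 250,
                      0.8 if pl.conservation_class == "C" else 0.4)
                     for pl in planted_loops
                     for s in (pl.l_summit, pl.r_summit)], 0.1)

    truth = SyntheticTruth(
        config=cfg, chrom_sizes_a=sizes_a, chrom_sizes_b=sizes_b,
        te_types=te_info, enriched_types=enriched, loops=planted_loops,
        genes=genes,
        expected_delta_tpm_effect=expected_observable_effect(
            cfg.expression_effect, cfg.expression_noise_sd),
        motif_consensus=consensus,
        n_shared_sites=n_shared, n_a_only_sites=n_a_only,
        n_b_only_sites=n_b_only,
    )
    with open(paths["manifest"], "w") as fh:
        json.dump({
            "schema_version": SCHEMA_VERSION,
            "seed": seed,
            "config": asdict(cfg),
            "chrom_sizes_a": sizes_a,
            "chrom_sizes_b": sizes_b,
            "te_types": te_info,
            "enriched_types": list(enriched),
            "loops": [asdict(pl) for pl in planted_loops],
            "genes": genes,
            "expected_delta_tpm_effect": truth.expected_delta_tpm_effect,
            "motif_consensus": consensus,
        }, fh, indent=1, sort_keys=True)

    fixture = SyntheticFixture(
        truth=truth, paths=paths,
        query_loops=query_loops, target_loops=target_loops,
        chains_ab=chains_ab, chains_ba=chains_ba,
        query_peaks=peaks_a, target_peaks=peaks_b,
        repeats=repeats, tss=sorted(tss), pwm=pwm,
    )

    if self_check:
        index = ChainIndex(chains_ab)
        got = classify_all(query_loops, target_loops, index, flank=0)
        for pl in planted_loops:
            if got[pl.loop_id].label != pl.conservation_class:
                raise ValueError(
                    f"infeasible class for loop {pl.loop_id}: intended "
                    f"{pl.conservation_class}, realized {got[pl.loop_id].label}"
                )
    return fixture


def generate_null_te_table(
    n_types: int = 200,
    seed: int = 0,
    copies_range: tuple[int, int] = (100, 2000),
    binding_rate: float = 0.05,
    tss_max: float = 1_000_000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A genome-wide TE table with NO type/binding association, for
    permutation-test calibration.

    Copy numbers per type are log-uniform over ``copies_range`` (mirroring
    the wide abundance spread of real repeat types); every copy is bound
    independently with ``binding_rate``; TSS distances are log-uniform so
    all six shuffle bins are populated. Returns (te_types, tss_distances,
    bound) arrays.
    """
    rng = np.random.default_rng(seed)
    copies = np.exp(rng.uniform(np.log(copies_range[0]),
                                np.log(copies_range[1]),
                                size=n_types)).astype(int)
    types = np.repeat([f"T{i:03d}" for i in range(n_types)], copies)
    n = types.size
    tss = np.exp(rng.uniform(np.log(10.0), np.log(tss_max), size=n))
    bound = rng.random(n) < binding_rate
    return types, tss, bound
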