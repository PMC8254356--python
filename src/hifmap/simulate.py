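"""Synthetic dataset generator with planted regulatory structure.

Emulates the processed outputs of a CUT&RUN + ATAC-seq + RNA-seq study:
a toy genome, non-overlapping genes, open-chromatin regions biased toward
promoters, binding sites preferentially planted near transcription start
sites and inside accessible regions, and an expression table in which
genes with proximal binding (<=3 kb) are preferentially upregulated and
genes with 3-10 kb binding preferentially downregulated. Every stage is
deterministic under the seed, and the planted ground truth is emitted so
recovery can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import annotate, core
from .core import GeneAnnotation, GeneExpressionRecord, Genome, GenomicInterval, Peak
from .expression import summarize_gene_binding


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 5
    chrom_length: int = 10_000_000
    n_genes: int = 2000
    gene_length_min: int = 1000
    gene_length_max: int = 10_000
    n_peaks: int = 1500
    peak_length: int = 300
    atac_fraction: float = 0.08
    atac_region_length: int = 1000
    p_atac_promoter: float = 0.4
    p_peak_promoter: float = 0.3
    p_peak_open: float = 0.5
    p_up_given_proximal: float = 0.5
    p_down_given_mid: float = 0.4
    p_deg_baseline: float = 0.03
    lfc_effect_mean: float = 1.5
    lfc_noise_sd: float = 0.25
    motif_plant: bool = False
    with_sequence: bool = False

    def __post_init__(self):
        for name in (
            "atac_fraction", "p_atac_promoter", "p_peak_promoter", "p_peak_open",
            "p_up_given_proximal", "p_down_given_mid", "p_deg_baseline",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if self.peak_length >= self.chrom_length:
            raise ValueError("peak_length must be < chrom_length")
        if self.gene_length_min > self.gene_length_max:
            raise ValueError("gene_length_min > gene_length_max")


@dataclass
class SimDataset:
    config: SimulationConfig
    genome: Genome
    genes: list[GeneAnnotation]
    atac: list[GenomicInterval]
    peaks: list[Peak]
    expression: list[GeneExpressionRecord]
    hypoxia_genes: list[str]
    ground_truth: dict


def _stage_rngs(seed: int, n: int = 6) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_genome(cfg: SimulationConfig) -> Genome:
    """Equal-length chromosomes chr1..chrN (no sequence; see
    :func:`generate_sequence`)."""
    return Genome({f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)})


def generate_annotation(
    cfg: SimulationConfig, genome: Genome, rng: np.random.Generator
) -> tuple[list[GeneAnnotation], list[GenomicInterval]]:
    """Non-overlapping genes (slot placement) and ATAC regions.

    Genes are distributed across chromosomes proportional to length, one
    gene per equal-width slot, so packing is always collision-free when a
    slot can hold the longest gene. A fraction ``p_atac_promoter`` of ATAC
    regions is anchored over a random TSS; the rest land uniformly.
    """
    names = list(genome.chroms)
    lengths = np.array([genome.chroms[c] for c in names], dtype=np.int64)
    alloc = np.floor(cfg.n_genes * lengths / lengths.sum()).astype(int)
    while alloc.sum() < cfg.n_genes:
        alloc[int(np.argmin(alloc * lengths.max() / lengths))] += 1
    genes: list[GeneAnnotation] = []
    gid = 0
    width = len(str(cfg.n_genes))
    for chrom, clen, k in zip(names, lengths, alloc):
        if k == 0:
            continue
        slot = clen // k
        if slot <= cfg.gene_length_max:
            raise ValueError(
                f"infeasible packing: slot {slot} bp cannot hold genes up to "
                f"{cfg.gene_length_max} bp; reduce n_genes or gene length"
            )
        for j in range(k):
            glen = int(rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1))
            lo, hi = j * slot, (j + 1) * slot - glen
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(
                GeneAnnotation(f"g{gid:0{width}d}", chrom, strand, start, start + glen)
            )
    # ATAC regions: fixed length, count set by the target covered fraction
    target_bp = cfg.atac_fraction * float(lengths.sum())
    n_regions = max(1, int(round(target_bp / cfg.atac_region_length)))
    tss = [(g.chrom, g.tss) for g in genes]
    atac: list[GenomicInterval] = []
    probs = lengths / lengths.sum()
    for i in range(n_regions):
        rlen = cfg.atac_region_length
        if tss and rng.random() < cfg.p_atac_promoter:
            chrom, pos = tss[int(rng.integers(0, len(tss)))]
            start = int(pos) - int(rng.integers(0, rlen))
        else:
            ci = int(rng.choice(len(names), p=probs))
            chrom = names[ci]
            start = int(rng.integers(0, lengths[ci] - rlen + 1))
        clen = genome.length(chrom)
        start = max(0, min(start, clen - rlen))
        atac.append(GenomicInterval(chrom, start, start + rlen, name=f"atac_{i + 1}"))
    return genes, atac


def generate_peaks(
    cfg: SimulationConfig,
    genome: Genome,
    genes: list[GeneAnnotation],
    atac: list[GenomicInterval],
    rng: np.random.Generator,
) -> tuple[list[Peak], list[str]]:
    """Binding sites with planted placement classes.

    Each peak is promoter-proximal (reference point uniform within +/-3 kb
    of a random TSS) with probability ``p_peak_promoter``; otherwise
    open-chromatin (uniform inside a random ATAC region) with probability
    ``p_peak_open``; otherwise uniform genome-wide. Returns the peaks and
    the per-peak planting class.
    """
    names = list(genome.chroms)
    lengths = np.array([genome.chroms[c] for c in names], dtype=np.int64)
    probs = lengths / lengths.sum()
    plen = cfg.peak_length
    half = plen // 2
    peaks: list[Peak] = []
    classes: list[str] = []
    for i in range(cfg.n_peaks):
        u = rng.random()
        if genes and u < cfg.p_peak_promoter:
            cls = "promoter"
            g = genes[int(rng.integers(0, len(genes)))]
            # keep the reference point within the 3 kb promoter window
            # even after summit jitter (+/-20 bp)
            center = g.tss + int(rng.integers(-2980, 2981))
            chrom = g.chrom
        elif atac and u < cfg.p_peak_promoter + (1 - cfg.p_peak_promoter) * cfg.p_peak_open:
            cls = "open"
            region = atac[int(rng.integers(0, len(atac)))]
            if len(region) >= plen:
                start = int(rng.integers(region.start, region.end - plen + 1))
                center = start + half
            else:
                center = (region.start + region.end) // 2
            chrom = region.chrom
        else:
            cls = "uniform"
            ci = int(rng.choice(len(names), p=probs))
            chrom = names[ci]
            center = int(rng.integers(half, lengths[ci] - (plen - half) + 1))
        clen = genome.length(chrom)
        start = max(0, min(center - half, clen - plen))
        summit = half + int(rng.integers(-20, 21))
        summit = max(0, min(summit, plen - 1))
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, start + plen, name=f"peak_{i + 1}"),
                summit_offset=summit,
                score=float(int(rng.integers(100, 1000))),
            )
        )
        classes.append(cls)
    return peaks, classes


def generate_sequence(
    cfg: SimulationConfig,
    genome: Genome,
    peaks: list[Peak],
    rng: np.random.Generator,
    motif: str = "RCGTG",
) -> Genome:
    """I.i.d. uniform ACGT sequence; with ``motif_plant``, one consensus
    occurrence is planted at each peak summit and spontaneous occurrences
    outside peak footprints are disrupted by a single-base substitution."""
    from .motif import MotifSpec, scan_sequence

    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs: dict[str, str] = {}
    footprints: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        footprints.setdefault(p.chrom, []).append((p.interval.start, p.interval.end))
    for chrom, clen in genome.chroms.items():
        arr = rng.choice(bases, size=clen)
        seq = arr.tobytes().decode()
        if cfg.motif_plant:
            spec = MotifSpec(motif, scan_both_strands=True)
            chars = list(seq)
            fps = sorted(footprints.get(chrom, []))
            starts = np.array([f[0] for f in fps], dtype=np.int64)
            ends = np.array([f[1] for f in fps], dtype=np.int64)

            def in_footprint(lo: int, hi: int) -> bool:
                if len(starts) == 0:
                    return False
                j = np.searchsorted(starts, hi)
                return bool(np.any(ends[:j] > lo))

            for pos, strand in scan_sequence(seq, spec).positions:
                if not in_footprint(pos, pos + len(motif)):
                    # break the core CGTG by flipping its G->A (or A->C)
                    k = pos + 2
                    chars[k] = "A" if chars[k] != "A" else "C"
            for p in peaks:
                if p.chrom != chrom:
                    continue
                s = p.ref_point
                if s + 5 <= clen:
                    planted = ("A" if rng.random() < 0.5 else "G") + "CGTG"
                    chars[s : s + 5] = planted
            seq = "".join(chars)
        seqs[chrom] = seq
    return Genome(dict(genome.chroms), sequence=seqs)


def generate_expression(
    cfg: SimulationConfig,
    genes: list[GeneAnnotation],
    peaks: list[Peak],
    rng: np.random.Generator,
) -> tuple[list[GeneExpressionRecord], dict]:
    """Expression table with planted distance-dependent regulation.

    Genes whose nearest-neighbor binding minimum distance is <=3 kb are
    upregulated with probability ``p_up_given_proximal``; 3-10 kb binding
    yields downregulation with probability ``p_down_given_mid``; all other
    genes are differentially expressed (random direction) at the baseline
    rate. Planted DE genes draw log2FC ~ sign*(effect_mean + N(0, sd)) and
    p ~ Beta(0.1, 1); background genes draw log2FC ~ N(0, sd) and
    p ~ U(0, 1).
    """
    anns = annotate.assign_nearest_tss(peaks, genes) if peaks else []
    summaries = {s.gene_id: s for s in summarize_gene_binding(anns, genes)}
    records: list[GeneExpressionRecord] = []
    truth: dict[str, dict] = {}
    for g in genes:
        s = summaries[g.gene_id]
        md = s.min_abs_distance
        direction = 0
        if md <= 3000:
            if rng.random() < cfg.p_up_given_proximal:
                direction = +1
        elif md <= 10000:
            if rng.random() < cfg.p_down_given_mid:
                direction = -1
        elif rng.random() < cfg.p_deg_baseline:
            direction = +1 if rng.random() < 0.5 else -1
        if direction != 0:
            lfc = direction * abs(cfg.lfc_effect_mean + rng.normal(0, cfg.lfc_noise_sd))
            p = float(rng.beta(0.1, 1.0))
        else:
            lfc = float(rng.normal(0, cfg.lfc_noise_sd))
            p = float(rng.uniform(0, 1))
        records.append(GeneExpressionRecord(g.gene_id, float(lfc), min(1.0, max(0.0, p))))
        truth[g.gene_id] = {
            "planted_de": "up" if direction > 0 else "down" if direction < 0 else "non",
            "min_abs_distance": None if math.isinf(md) else md,
            "planted_target": direction != 0 and md <= 100_000,
        }
    return records, truth


def generate_hypoxia_list(
    truth: dict[str, dict], rng: np.random.Generator,
    p_known_given_target: float = 0.3, p_known_background: float = 0.02,
) -> list[str]:
    """A known-hypoxia gene list covering a fraction of planted targets
    plus background genes, emulating a curated database export."""
    known = []
    for gene_id in sorted(truth):
        p = p_known_given_target if truth[gene_id]["planted_target"] else p_known_background
        if rng.random() < p:
            known.append(gene_id)
    return known


def generate_dataset(cfg: SimulationConfig) -> SimDataset:
    """Run all stages with per-stage RNG streams spawned from the seed."""
    r_gene, r_peak, r_seq, r_expr, r_hyp, _ = _stage_rngs(cfg.seed)
    genome = generate_genome(cfg)
    genes, atac = generate_annotation(cfg, genome, r_gene)
    peaks, classes = generate_peaks(cfg, genome, genes, atac, r_peak)
    if cfg.with_sequence:
        genome = generate_sequence(cfg, genome, peaks, r_seq)
    expression, truth = generate_expression(cfg, genes, peaks, r_expr)
    hypoxia = generate_hypoxia_list(truth, r_hyp)
    ground_truth = {
        "peak_classes": classes,
        "genes": truth,
        "config": asdict(cfg),
    }
    return SimDataset(cfg, genome, genes, atac, peaks, expression, hypoxia, ground_truth)


def write_dataset(ds: SimDataset, outdir) -> dict[str, Path]:
    """Emit every file of the dataset; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "genes": outdir / "genes.tsv",
        "atac": outdir / "atac.bed",
        "peaks": outdir / "peaks.narrowPeak",
        "expression": outdir / "expression.tsv",
        "hypoxia": outdir / "hypoxia_genes.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    core.write_chrom_sizes(ds.genome, paths["chrom_sizes"])
    core.write_gene_table(ds.genes, paths["genes"])
    core.write_bed(ds.atac, paths["atac"])
    core.write_peaks_narrowpeak(ds.peaks, paths["peaks"])
    core.write_expression_table(ds.expression, paths["expression"])
    with open(paths["hypoxia"], "w") as fh:
        fh.write("\n".join(ds.hypoxia_genes) + ("\n" if ds.hypoxia_genes else ""))
    with open(paths["ground_truth"], "w") as fh:
        json.dump(ds.ground_truth, fh, indent=1, sort_keys=True)
    if ds.genome.sequence is not None:
        paths["fasta"] = outdir / "genome.fa"
        core.write_fasta(ds.genome.sequence, paths["fasta"])
    return paths
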