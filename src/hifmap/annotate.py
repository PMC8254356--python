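"""Peak annotation: nearest-TSS assignment, distance binning, genomic
feature classification and open-chromatin overlap flags.

Each binding site is anchored at its reference point (summit or midpoint)
and assigned to the gene whose TSS is closest on the same chromosome.
Equidistant TSSs are broken deterministically by the lexicographically
smaller gene_id. Peaks on chromosomes carrying no genes receive an
infinite-distance sentinel and are excluded from bin counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneAnnotation, GenomicInterval, Peak

log = logging.getLogger("hifmap")

DISTANCE_BINS = ("0-3kb", "3-10kb", "10-100kb", ">100kb")
FEATURES = ("promoter", "genebody", "intergenic")
PROMOTER_WINDOW = 3000


@dataclass(frozen=True)
class PeakAnnotation:
    """Per-peak annotation record.

    ``signed_distance`` is ref_point - TSS, orientation-corrected so a
    positive value means the peak lies downstream of the TSS in the
    gene's direction of transcription.
    """

    peak: Peak
    nearest_gene: Optional[str]
    signed_distance: float  # bp; +/- inf sentinel when no gene available
    abs_distance: float
    distance_bin: Optional[str]
    feature: Optional[str] = None
    open_chromatin: Optional[bool] = None


def bin_distance(abs_distance: float, edges: Sequence[int] = (3000, 10000, 100000)) -> str:
    """Map an absolute TSS distance to its bin. Edges are closed on the
    upper side (d = 3000 falls in the first bin)."""
    if abs_distance < 0:
        raise ValueError(f"negative distance {abs_distance}")
    if abs_distance <= edges[0]:
        return DISTANCE_BINS[0]
    if abs_distance <= edges[1]:
        return DISTANCE_BINS[1]
    if abs_distance <= edges[2]:
        return DISTANCE_BINS[2]
    return DISTANCE_BINS[3]


def _tss_index(genes: Sequence[GeneAnnotation]):
    """Per-chromosome sorted arrays of (tss, gene_id, strand) for nearest-
    neighbor queries; co-located TSSs keep the smallest gene_id first."""
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (
            np.array([g.tss for g in glist], dtype=np.int64),
            glist,
        )
    return index


def assign_nearest_tss(
    peaks: Sequence[Peak], genes: Sequence[GeneAnnotation]
) -> list[PeakAnnotation]:
    """Assign every peak to the gene with the nearest TSS (distance fields
    only; run :func:`classify_features` / :func:`flag_open_chromatin` to
    fill the remaining fields)."""
    if not genes:
        raise ValueError("empty gene list")
    index = _tss_index(genes)
    out: list[PeakAnnotation] = []
    n_orphans = 0
    n_ties = 0
    for peak in peaks:
        entry = index.get(peak.chrom)
        if entry is None:
            n_orphans += 1
            out.append(
                PeakAnnotation(peak, None, math.inf, math.inf, None)
            )
            continue
        tss_arr, glist = entry
        ref = peak.ref_point
        j = int(np.searchsorted(tss_arr, ref))
        # candidate TSS positions flanking the insertion point
        cands: list[GeneAnnotation] = []
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(tss_arr):
                d = abs(ref - int(tss_arr[k]))
                if best is None or d < best:
                    best = d
        for k in range(j - 1, -1, -1):
            if abs(ref - int(tss_arr[k])) == best:
                cands.append(glist[k])
            else:
                break
        for k in range(j, len(tss_arr)):
            if abs(ref - int(tss_arr[k])) == best:
                cands.append(glist[k])
            else:
                break
        if len(cands) > 1:
            n_ties += 1
        gene = min(cands, key=lambda g: g.gene_id)
        raw = ref - gene.tss
        signed = raw if gene.strand == "+" else -raw
        out.append(
            PeakAnnotation(
                peak,
                gene.gene_id,
                float(signed),
                float(abs(raw)),
                bin_distance(abs(raw)),
            )
        )
    if n_orphans:
        log.warning("%d peaks on gene-free chromosomes (infinite-distance sentinel)", n_orphans)
    if n_ties:
        log.info("%d peaks had equidistant TSS ties (broken by gene_id)", n_ties)
    return out


def classify_features(
    anns: Sequence[PeakAnnotation],
    genes: Sequence[GeneAnnotation],
    promoter_window: int = PROMOTER_WINDOW,
) -> list[PeakAnnotation]:
    """Classify each peak as promoter / genebody / intergenic.

    Promoter: reference point within ``promoter_window`` bp of any TSS
    (takes precedence). Genebody: reference point inside any gene span
    [start, end). Intergenic: neither. The classes partition the peaks.
    """
    body_trees: dict[str, IntervalTree] = {}
    for g in genes:
        body_trees.setdefault(g.chrom, IntervalTree()).addi(g.gene_start, g.gene_end)
    out = []
    for ann in anns:
        ref = ann.peak.ref_point
        if ann.abs_distance <= promoter_window:
            feature = "promoter"
        else:
            tree = body_trees.get(ann.peak.chrom)
            if tree is not None and tree.overlaps_point(ref):
                feature = "genebody"
            else:
                feature = "intergenic"
        out.append(replace(ann, feature=feature))
    return out


def flag_open_chromatin(
    peaks: Sequence[Peak],
    atac: Sequence[GenomicInterval],
    mode: str = "any",
) -> list[bool]:
    """True iff the peak overlaps >=1 bp of any open-chromatin interval
    on the same chromosome (``mode='any'``), or iff the summit/reference
    point itself falls in one (``mode='summit'``)."""
    if mode not in ("any", "summit"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for iv in atac:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    flags = []
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            flags.append(False)
        elif mode == "summit":
            flags.append(bool(tree.overlaps_point(p.ref_point)))
        else:
            flags.append(bool(tree.overlap(p.interval.start, p.interval.end)))
    return flags


def attach_open_chromatin(
    anns: Sequence[PeakAnnotation],
    atac: Sequence[GenomicInterval],
    mode: str = "any",
) -> list[PeakAnnotation]:
    flags = flag_open_chromatin([a.peak for a in anns], atac, mode=mode)
    return [replace(a, open_chromatin=f) for a, f in zip(anns, flags)]


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    atac: Optional[Sequence[GenomicInterval]] = None,
    promoter_window: int = PROMOTER_WINDOW,
    overlap_mode: str = "any",
) -> list[PeakAnnotation]:
    """Full annotation: nearest TSS, feature class and (if ATAC regions
    are supplied) open-chromatin flags."""
    anns = assign_nearest_tss(peaks, genes)
    anns = classify_features(anns, genes, promoter_window=promoter_window)
    if atac is not None:
        anns = attach_open_chromatin(anns, atac, mode=overlap_mode)
    return anns


def _count_pct(counts: dict, total: int, order: Iterable) -> pd.DataFrame:
    rows = [
        {"category": c, "count": counts.get(c, 0), "percent": round(100.0 * counts.get(c, 0) / total, 1)}
        for c in order
    ]
    return pd.DataFrame(rows)


def summarize_annotation(anns: Sequence[PeakAnnotation]) -> dict[str, pd.DataFrame]:
    """Count/percentage tables per distance bin, per feature class, per
    open-chromatin flag, and the distance x accessibility cross-tab.

    Percentages are 100*count/total rounded to one decimal. Peaks with the
    infinite-distance sentinel are excluded from distance-bin counts (and
    logged); feature/open-chromatin tables use all annotated peaks.
    """
    if not anns:
        raise ValueError("no annotations to summarize")
    binned = [a for a in anns if a.distance_bin is not None]
    n_excluded = len(anns) - len(binned)
    if n_excluded:
        log.warning("%d peaks excluded from bin counts (no gene on chromosome)", n_excluded)
    tables: dict[str, pd.DataFrame] = {}
    if binned:
        bc = pd.Series([a.distance_bin for a in binned]).value_counts().to_dict()
        tables["distance_bin"] = _count_pct(bc, len(binned), DISTANCE_BINS)
    if all(a.feature is not None for a in anns):
        fc = pd.Series([a.feature for a in anns]).value_counts().to_dict()
        tables["feature"] = _count_pct(fc, len(anns), FEATURES)
    if all(a.open_chromatin is not None for a in anns):
        oc = pd.Series([a.open_chromatin for a in anns]).value_counts().to_dict()
        tables["open_chromatin"] = _count_pct(oc, len(anns), (True, False))
        cross = {}
        for a in binned:
            key = (a.distance_bin, "open" if a.open_chromatin else "closed")
            cross[key] = cross.get(key, 0) + 1
        rows = []
        for b in DISTANCE_BINS:
            for state in ("open", "closed"):
                n = cross.get((b, state), 0)
                rows.append(
                    {
                        "distance_bin": b,
                        "chromatin": state,
                        "count": n,
                        "percent": round(100.0 * n / len(binned), 1),
                    }
                )
        tables["distance_bin_x_chromatin"] = pd.DataFrame(rows)
    return tables


def feature_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Percentages (1-decimal) for a category->count table."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty count table")
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}


def write_annotated_bed(anns: Sequence[PeakAnnotation], path) -> None:
    """BED6+4: gene_id, signed_distance, feature, open_chromatin."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\tnearest_gene\t"
            "signed_distance\tfeature\topen_chromatin\n"
        )
        for k, a in enumerate(anns):
            iv = a.peak.interval
            name = iv.name or f"peak_{k + 1}"
            score = int(a.peak.score) if a.peak.score is not None else 0
            sd = "inf" if math.isinf(a.signed_distance) else str(int(a.signed_distance))
            oc = "." if a.open_chromatin is None else str(int(a.open_chromatin))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\t"
                f"{a.nearest_gene or '.'}\t{sd}\t{a.feature or '.'}\t{oc}\n"
            )
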