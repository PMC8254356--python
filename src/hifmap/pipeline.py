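"""One-command orchestration: annotate -> null -> integrate -> motif.

Produces per-stage TSV/BED outputs plus a machine-readable summary JSON
keyed by figure-panel-shaped sections (distance distribution, feature
classes, null enrichment, accessibility, binding-DEG association,
distance-stratified association, overlap counts, target calls, motif
enrichment). Optional inputs (ATAC, FASTA, hypoxia list) disable exactly
their dependent sections.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import __version__
from . import annotate as ann_mod
from . import core, expression as expr_mod, motif as motif_mod, null as null_mod

log = logging.getLogger("hifmap")

SUMMARY_SECTIONS = (
    "fig2c", "fig2d", "fig2e", "fig2f", "fig3a",
    "fig4b", "fig4c", "fig4e", "fig4f", "fig4g", "fig4j",
    "magnitude", "targets", "motif",
)


@dataclass
class RunConfig:
    peaks: str
    chrom_sizes: str
    genes: str
    expression: str
    atac: Optional[str] = None
    fasta: Optional[str] = None
    hypoxia: Optional[str] = None
    outdir: str = "hifmap_out"
    lfc_threshold: float = 0.6
    alpha: float = 0.05
    promoter_window: int = 3000
    target_window: int = expr_mod.TARGET_WINDOW
    n_replicates: int = 100
    seed: int = 0
    overlap_mode: str = "any"
    yates: bool = False
    motif_pattern: str = "RCGTG"
    keep_shuffles: bool = False

    def __post_init__(self):
        if self.target_window < 100_000 and self.target_window < 10_000:
            raise ValueError("target_window must cover the distance bins used for target calling")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _enrichment_section(table: null_mod.EnrichmentTable) -> dict:
    return {
        "gof_chi2": table.gof_stat,
        "gof_df": table.gof_df,
        "gof_pvalue": table.gof_pvalue,
        "categories": [
            {
                "category": r.category,
                "observed": r.observed,
                "expected": r.expected,
                "rpd": r.rpd,
                "chi2": r.chi2_stat,
                "pvalue": r.pvalue,
                "pvalue_adj": r.pvalue_adj,
            }
            for r in table.results
        ],
    }


def _assoc_section(res: expr_mod.Association2x2, a, b) -> dict:
    return {
        "a_bound": a[0], "a_total": a[1], "b_bound": b[0], "b_total": b[1],
        "prop_a": res.prop_a, "prop_b": res.prop_b,
        "chi2": res.chi2_stat, "pvalue": res.pvalue,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the result bundle under
    ``cfg.outdir``; returns the summary dict (also written as JSON)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = core.read_chrom_sizes(cfg.chrom_sizes)
    peaks = core.read_peaks(cfg.peaks, genome=genome)
    genes = core.read_gene_table(cfg.genes, genome=genome)
    records = core.read_expression_table(cfg.expression)
    atac = core.read_bed_intervals(cfg.atac, genome=genome) if cfg.atac else None
    hypoxia = core.read_gene_list(cfg.hypoxia) if cfg.hypoxia else None

    # --- annotation -------------------------------------------------------
    anns = ann_mod.annotate_peaks(
        peaks, genes, atac=atac,
        promoter_window=cfg.promoter_window, overlap_mode=cfg.overlap_mode,
    )
    ann_mod.write_annotated_bed(anns, outdir / "peaks_annotated.bed")
    tables = ann_mod.summarize_annotation(anns)
    for name, df in tables.items():
        df.to_csv(outdir / f"summary_{name}.tsv", sep="\t", index=False)

    summary: dict = {
        "meta": {
            "version": __version__,
            "seed": cfg.seed,
            "n_replicates": cfg.n_replicates,
            "n_peaks": len(peaks),
            "n_genes": len(genes),
            "n_expression_records": len(records),
            "conventions": {
                "coordinates": "0-based half-open",
                "ref_point": "summit if present else midpoint",
                "bin_edges": "upper-closed (d<=3000 in first bin)",
                "rpd": "100*(observed-expected)/expected",
                "overlap_mode": cfg.overlap_mode,
                "promoter_window": cfg.promoter_window,
                "target_window": cfg.target_window,
                "lfc_threshold": cfg.lfc_threshold,
                "alpha": cfg.alpha,
            },
        }
    }
    summary["fig2c"] = tables["distance_bin"].to_dict(orient="records")
    summary["fig2e"] = tables["feature"].to_dict(orient="records")
    if atac is not None:
        summary["open_chromatin"] = tables["open_chromatin"].to_dict(orient="records")

    # --- null model -------------------------------------------------------
    shuffle_cfg = null_mod.ShuffleConfig(n_replicates=cfg.n_replicates, seed=cfg.seed)
    replicates = null_mod.shuffle_intervals(peaks, genome, shuffle_cfg)
    rep_anns = [
        ann_mod.annotate_peaks(
            rep, genes, atac=atac,
            promoter_window=cfg.promoter_window, overlap_mode=cfg.overlap_mode,
        )
        for rep in replicates
    ]
    if cfg.keep_shuffles:
        for i, rep in enumerate(replicates):
            core.write_bed([p.interval for p in rep], outdir / f"shuffle_{i + 1}.bed")
    dist_table = null_mod.category_enrichment(
        null_mod.count_distance_bins(anns),
        [null_mod.count_distance_bins(r) for r in rep_anns],
        ann_mod.DISTANCE_BINS,
    )
    feat_table = null_mod.category_enrichment(
        null_mod.count_features(anns),
        [null_mod.count_features(r) for r in rep_anns],
        ann_mod.FEATURES,
    )
    summary["fig2d"] = _enrichment_section(dist_table)
    summary["fig2f"] = _enrichment_section(feat_table)
    null_mod.enrichment_to_frame(dist_table).to_csv(
        outdir / "enrichment_distance.tsv", sep="\t", index=False
    )
    null_mod.enrichment_to_frame(feat_table).to_csv(
        outdir / "enrichment_feature.tsv", sep="\t", index=False
    )
    if atac is not None:
        joint = null_mod.joint_distance_accessibility_enrichment(anns, rep_anns)
        summary["fig3a"] = _enrichment_section(joint)
        null_mod.enrichment_to_frame(joint).to_csv(
            outdir / "enrichment_joint.tsv", sep="\t", index=False
        )
    else:
        summary["fig3a"] = None

    # --- expression integration ------------------------------------------
    degs = expr_mod.classify_deg(records, cfg.lfc_threshold, cfg.alpha)
    counts = expr_mod.deg_counts(degs)
    summaries = expr_mod.summarize_gene_binding(anns, genes)
    pairs = expr_mod.join_binding(degs, summaries)
    summary["deg_counts"] = counts

    def bound_of(group) -> tuple[int, int]:
        sel = [s for d, s in pairs if d.status in group]
        return sum(1 for s in sel if s.is_nearest_neighbor_of_peak), len(sel)

    deg_bt, non_bt = bound_of(("up", "down")), bound_of(("non",))
    assoc = {}
    for key, group in (("fig4b", deg_bt), ("fig4e", bound_of(("up",))), ("fig4g", bound_of(("down",)))):
        try:
            res = expr_mod.association_2x2(group, non_bt, yates=cfg.yates)
            assoc[key] = _assoc_section(res, group, non_bt)
        except ValueError as exc:
            assoc[key] = {"error": str(exc)}
    summary.update(assoc)

    strata = expr_mod.distance_stratified_association(degs, summaries, yates=cfg.yates)
    summary["fig4c"] = [asdict(s) for s in strata if s.comparison == "deg_vs_non"]
    summary["fig4f"] = [asdict(s) for s in strata if s.comparison in ("up_vs_non", "down_vs_non")]

    bound_lfcs = [d.log2fc for d, s in pairs if s.is_nearest_neighbor_of_peak]
    unbound_lfcs = [d.log2fc for d, s in pairs if not s.is_nearest_neighbor_of_peak]
    if bound_lfcs and unbound_lfcs:
        u, p = expr_mod.magnitude_test(bound_lfcs, unbound_lfcs)
        summary["magnitude"] = {"U": u, "pvalue": p}
    else:
        summary["magnitude"] = None

    summary["fig4j"] = expr_mod.overlap_counts(degs, summaries, cfg.target_window)
    targets = expr_mod.classify_targets(degs, summaries, hypoxia, cfg.target_window)
    summary["targets"] = expr_mod.target_counts(targets)

    # gene-level master table
    by_id = {s.gene_id: s for s in summaries}
    tcalls = {t.gene_id: t for t in targets}
    with open(outdir / "genes_master.tsv", "w") as fh:
        fh.write(
            "gene_id\tlog2FC\tpvalue\tstatus\tmin_abs_distance\tbound_3kb\t"
            "bound_3_10kb\tbound_10_100kb\tbound_100kb\thif1a_dependent\t"
            "direction\tknown_hypoxia\n"
        )
        for d in degs:
            s = by_id.get(d.gene_id)
            t = tcalls.get(d.gene_id)
            md = "inf" if s is None or math.isinf(s.min_abs_distance) else str(int(s.min_abs_distance))
            flags = (
                (s.bound_within_3kb, s.bound_3_10kb, s.bound_10_100kb, s.bound_within_100kb)
                if s is not None else (False,) * 4
            )
            fh.write(
                f"{d.gene_id}\t{d.log2fc:.6g}\t{d.pvalue:.6g}\t{d.status}\t{md}\t"
                + "\t".join(str(int(f)) for f in flags)
                + f"\t{int(t.hif1a_dependent) if t else 0}"
                + f"\t{t.direction if t else 'none'}"
                + f"\t{int(t.known_hypoxia) if t else 0}\n"
            )

    # --- motif (optional) -------------------------------------------------
    if cfg.fasta:
        sequences = core.read_fasta(cfg.fasta)
        genome_seq = core.Genome(dict(genome.chroms), sequence=sequences)
        spec = motif_mod.MotifSpec(cfg.motif_pattern)
        enr = motif_mod.motif_enrichment(peaks, replicates, genome_seq, spec)
        summary["motif"] = {
            "pattern": cfg.motif_pattern,
            "observed_per_kb": enr.observed_per_kb,
            "expected_per_kb": enr.expected_per_kb,
            "ratio": enr.ratio,
            "empirical_p": enr.empirical_p,
            "observed_matches": enr.observed_matches,
            "kb_scanned": enr.kb_scanned,
        }
    else:
        summary["motif"] = None

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def validate_summary(summary: dict) -> None:
    """Minimal schema check used by :func:`report`."""
    if "meta" not in summary:
        raise ValueError("summary lacks 'meta' section")
    for key in ("fig2c", "fig2d", "fig2e", "fig2f", "fig4j", "targets"):
        if key not in summary:
            raise ValueError(f"summary lacks required section {key!r}")


def report(summary: dict) -> str:
    """Render the summary as a markdown report (no recomputation)."""
    validate_summary(summary)
    lines = ["# hifmap run report", ""]
    meta = summary["meta"]
    lines.append(
        f"hifmap {meta['version']} | seed {meta['seed']} | "
        f"{meta['n_peaks']} peaks, {meta['n_genes']} genes, "
        f"{meta['n_replicates']} shuffle replicates"
    )
    lines.append("")

    def count_table(title, rows):
        lines.append(f"## {title}")
        lines.append("| category | count | percent |")
        lines.append("|---|---|---|")
        for r in rows:
            lines.append(f"| {r['category']} | {r['count']} | {r['percent']} |")
        lines.append("")

    count_table("Distance to nearest TSS", summary["fig2c"])
    count_table("Genomic feature classes", summary["fig2e"])

    def enrich_table(title, section):
        lines.append(f"## {title}")
        if section is None:
            lines.append("not run")
            lines.append("")
            return
        lines.append(
            f"overall GOF chi2 = {section['gof_chi2']:.3g}, "
            f"df = {section['gof_df']}, p = {section['gof_pvalue']:.3g}"
        )
        lines.append("| category | observed | expected | rpd (%) | p_adj |")
        lines.append("|---|---|---|---|---|")
        for r in section["categories"]:
            lines.append(
                f"| {r['category']} | {r['observed']} | {r['expected']:.1f} | "
                f"{r['rpd']:.1f} | {r['pvalue_adj']:.3g} |"
            )
        lines.append("")

    enrich_table("Distance enrichment vs random placement", summary["fig2d"])
    enrich_table("Feature enrichment vs random placement", summary["fig2f"])
    enrich_table("Distance x accessibility enrichment", summary.get("fig3a"))

    lines.append("## Binding-DEG association")
    for key, label in (("fig4b", "DEG vs non-DEG"), ("fig4e", "up vs non"), ("fig4g", "down vs non")):
        sec = summary.get(key)
        if not sec:
            continue
        if "error" in sec:
            lines.append(f"- {label}: not testable ({sec['error']})")
        else:
            lines.append(
                f"- {label}: {sec['a_bound']}/{sec['a_total']} "
                f"({sec['prop_a']:.1f}%) vs {sec['b_bound']}/{sec['b_total']} "
                f"({sec['prop_b']:.1f}%), chi2 = {sec['chi2']:.3g}, p = {sec['pvalue']:.3g}"
            )
    lines.append("")

    lines.append("## Distance-stratified association")
    rows = (summary.get("fig4c") or []) + (summary.get("fig4f") or [])
    if rows:
        lines.append("| comparison | stratum | group | non-DEG | p_adj | direction |")
        lines.append("|---|---|---|---|---|---|")
        for s in rows:
            lines.append(
                f"| {s['comparison']} | {s['stratum']} | "
                f"{s['a_bound']}/{s['a_total']} ({s['prop_a']:.1f}%) | "
                f"{s['b_bound']}/{s['b_total']} ({s['prop_b']:.1f}%) | "
                f"{s['pvalue_adj']:.3g} | {s['direction']} |"
            )
    else:
        lines.append("not run")
    lines.append("")

    mag = summary.get("magnitude")
    lines.append("## Fold-change magnitude (bound vs unbound)")
    lines.append(
        "not run" if mag is None else f"Mann-Whitney U = {mag['U']:.6g}, p = {mag['pvalue']:.3g}"
    )
    lines.append("")

    ov = summary["fig4j"]
    lines.append("## Overlap with binding within the target window")
    lines.append(
        f"up&bound {ov['up_bound']}, down&bound {ov['down_bound']}, "
        f"bound non-DEG {ov['bound_non_deg']}, DEG unbound {ov['deg_unbound']}"
    )
    tg = summary["targets"]
    lines.append(
        f"targets: {tg['total']} ({tg['activated']} activated + {tg['repressed']} repressed; "
        f"{tg['known_hypoxia']} known hypoxia, {tg['novel']} novel)"
    )
    lines.append("")

    lines.append("## Motif enrichment")
    mo = summary.get("motif")
    lines.append(
        "not run" if mo is None else (
            f"{mo['pattern']}: {mo['observed_per_kb']:.3g}/kb observed vs "
            f"{mo['expected_per_kb']:.3g}/kb expected, ratio {mo['ratio']:.3g}, "
            f"empirical p = {mo['empirical_p']:.3g}"
        )
    )
    lines.append("")
    return "\n".join(lines)
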