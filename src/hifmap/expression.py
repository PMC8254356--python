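"""Integration of binding annotation with differential expression.

A gene is "bound" when it is the nearest-neighbor gene of at least one
binding site (peak-to-gene mapping, not a window scan). Differentially
expressed genes (DEGs) are |log2FC| > 0.6 at p < 0.05 by default; a gene
is a HIF1a-dependent target when it is a DEG with at least one binding
site within 100 kb of its TSS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .annotate import PeakAnnotation
from .core import GeneAnnotation, GeneExpressionRecord
from .null import bonferroni_adjust

log = logging.getLogger("hifmap")

STRATA = ("0-3kb", "3-10kb", "10-100kb")  # cumulative-exclusive on min distance
TARGET_WINDOW = 100_000


@dataclass(frozen=True)
class GeneBindingSummary:
    gene_id: str
    is_nearest_neighbor_of_peak: bool
    min_abs_distance: float  # bp, +inf when unbound
    bound_within_3kb: bool
    bound_3_10kb: bool
    bound_10_100kb: bool
    bound_within_100kb: bool
    n_peaks: int = 0


@dataclass(frozen=True)
class DEGCall:
    gene_id: str
    status: str  # up / down / non
    log2fc: float
    pvalue: float


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    hif1a_dependent: bool
    direction: str  # activated / repressed / none
    known_hypoxia: bool = False


@dataclass
class Association2x2:
    chi2_stat: float
    pvalue: float
    prop_a: float  # 100 * bound/total, group A
    prop_b: float


@dataclass
class StratumAssociation:
    comparison: str
    stratum: str
    a_bound: int
    a_total: int
    b_bound: int
    b_total: int
    prop_a: float
    prop_b: float
    chi2_stat: float
    pvalue: float
    pvalue_adj: float
    direction: str  # enriched / depleted


UNBOUND = dict(
    is_nearest_neighbor_of_peak=False,
    min_abs_distance=math.inf,
    bound_within_3kb=False,
    bound_3_10kb=False,
    bound_10_100kb=False,
    bound_within_100kb=False,
    n_peaks=0,
)


def summarize_gene_binding(
    anns: Sequence[PeakAnnotation], genes: Sequence[GeneAnnotation]
) -> list[GeneBindingSummary]:
    """Reduce per-peak annotations to per-gene binding summaries.

    Stratum flags come from any assigned peak in that stratum, so a gene
    may carry both a <=3 kb and a 3-10 kb flag.
    """
    per_gene: dict[str, list[float]] = {}
    for a in anns:
        if a.nearest_gene is not None and not math.isinf(a.abs_distance):
            per_gene.setdefault(a.nearest_gene, []).append(a.abs_distance)
    out = []
    for g in genes:
        dists = per_gene.get(g.gene_id)
        if not dists:
            out.append(GeneBindingSummary(g.gene_id, **UNBOUND))
            continue
        out.append(
            GeneBindingSummary(
                gene_id=g.gene_id,
                is_nearest_neighbor_of_peak=True,
                min_abs_distance=min(dists),
                bound_within_3kb=any(d <= 3000 for d in dists),
                bound_3_10kb=any(3000 < d <= 10000 for d in dists),
                bound_10_100kb=any(10000 < d <= 100000 for d in dists),
                bound_within_100kb=min(dists) <= TARGET_WINDOW,
                n_peaks=len(dists),
            )
        )
    return out


def classify_deg(
    records: Sequence[GeneExpressionRecord],
    lfc_threshold: float = 0.6,
    alpha: float = 0.05,
) -> list[DEGCall]:
    """up: log2FC > threshold & p < alpha; down: log2FC < -threshold &
    p < alpha; non otherwise."""
    if lfc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be > 0")
    calls = []
    for r in records:
        if r.pvalue < alpha and r.log2fc > lfc_threshold:
            status = "up"
        elif r.pvalue < alpha and r.log2fc < -lfc_threshold:
            status = "down"
        else:
            status = "non"
        calls.append(DEGCall(r.gene_id, status, r.log2fc, r.pvalue))
    return calls


def deg_counts(calls: Sequence[DEGCall]) -> dict[str, int]:
    return {
        s: sum(1 for c in calls if c.status == s) for s in ("up", "down", "non")
    }


def association_2x2(
    group_a: tuple[int, int],
    group_b: tuple[int, int],
    yates: bool = False,
) -> Association2x2:
    """Pearson chi-square (df=1) on a 2x2 bound/unbound table.

    ``group_a``/``group_b`` are (bound, total). No continuity correction
    by default. Proportions reported as 100*bound/total.
    """
    (a_bound, a_total), (b_bound, b_total) = group_a, group_b
    if a_total <= 0 or b_total <= 0:
        raise ValueError("group totals must be > 0")
    if a_bound > a_total or b_bound > b_total:
        raise ValueError("bound count exceeds total")
    table = np.array(
        [[a_bound, a_total - a_bound], [b_bound, b_total - b_bound]], dtype=float
    )
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("degenerate 2x2 table: a bound/unbound column margin is zero")
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate 2x2 table: a group row margin is zero")
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return Association2x2(
        chi2_stat=float(stat),
        pvalue=float(p),
        prop_a=100.0 * a_bound / a_total,
        prop_b=100.0 * b_bound / b_total,
    )


def _stratum_of(min_dist: float) -> Optional[str]:
    if min_dist <= 3000:
        return "0-3kb"
    if min_dist <= 10000:
        return "3-10kb"
    if min_dist <= 100000:
        return "10-100kb"
    return None


def join_binding(
    degs: Sequence[DEGCall], summaries: Sequence[GeneBindingSummary]
) -> list[tuple[DEGCall, GeneBindingSummary]]:
    """Pair each expression call with its binding summary; genes absent
    from the annotation are kept as unbound (warning). A >50% mismatch
    rate raises (it usually signals mismatched annotations)."""
    by_id = {s.gene_id: s for s in summaries}
    pairs = []
    n_missing = 0
    for d in degs:
        s = by_id.get(d.gene_id)
        if s is None:
            n_missing += 1
            s = GeneBindingSummary(d.gene_id, **UNBOUND)
        pairs.append((d, s))
    if degs and n_missing / len(degs) > 0.5:
        raise ValueError(
            f"{n_missing}/{len(degs)} expression gene_ids absent from the "
            "annotation — inputs probably use different gene identifiers"
        )
    if n_missing:
        log.warning("%d expression genes absent from annotation, kept as unbound", n_missing)
    return pairs


def distance_stratified_association(
    degs: Sequence[DEGCall],
    summaries: Sequence[GeneBindingSummary],
    yates: bool = False,
) -> list[StratumAssociation]:
    """Per-stratum 2x2 association of binding with differential expression.

    Strata are cumulative-exclusive on the gene's minimum binding distance
    (<=3 kb; 3-10 kb; 10-100 kb). Three comparisons are run per stratum:
    all DEGs vs non-DEGs, upregulated vs non, downregulated vs non;
    Bonferroni is applied within each comparison across its strata.
    """
    pairs = join_binding(degs, summaries)
    strata_of = {
        d.gene_id: _stratum_of(s.min_abs_distance) for d, s in pairs
    }
    groups = {
        "deg": [d for d, _ in pairs if d.status in ("up", "down")],
        "up": [d for d, _ in pairs if d.status == "up"],
        "down": [d for d, _ in pairs if d.status == "down"],
        "non": [d for d, _ in pairs if d.status == "non"],
    }
    out: list[StratumAssociation] = []
    non = groups["non"]
    for comparison in ("deg", "up", "down"):
        grp = groups[comparison]
        if not grp or not non:
            continue  # degenerate: nothing to test
        rows = []
        for stratum in STRATA:
            a_bound = sum(1 for d in grp if strata_of[d.gene_id] == stratum)
            b_bound = sum(1 for d in non if strata_of[d.gene_id] == stratum)
            try:
                res = association_2x2(
                    (a_bound, len(grp)), (b_bound, len(non)), yates=yates
                )
                stat, p = res.chi2_stat, res.pvalue
            except ValueError:
                stat, p = float("nan"), 1.0
            rows.append((stratum, a_bound, b_bound, stat, p))
        adj = bonferroni_adjust([r[4] for r in rows])
        for (stratum, a_bound, b_bound, stat, p), pa in zip(rows, adj):
            prop_a = 100.0 * a_bound / len(grp)
            prop_b = 100.0 * b_bound / len(non)
            out.append(
                StratumAssociation(
                    comparison=f"{comparison}_vs_non",
                    stratum=stratum,
                    a_bound=a_bound,
                    a_total=len(grp),
                    b_bound=b_bound,
                    b_total=len(non),
                    prop_a=prop_a,
                    prop_b=prop_b,
                    chi2_stat=stat,
                    pvalue=p,
                    pvalue_adj=pa,
                    direction="enriched" if prop_a >= prop_b else "depleted",
                )
            )
    return out


def magnitude_test(
    bound_lfcs: Sequence[float], unbound_lfcs: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing |log2FC| magnitudes.

    Exact enumeration when both groups have n <= 8 and no cross-group
    ties; the tie-corrected normal approximation otherwise.
    """
    x = np.abs(np.asarray(bound_lfcs, dtype=float))
    y = np.abs(np.asarray(unbound_lfcs, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def classify_targets(
    degs: Sequence[DEGCall],
    summaries: Sequence[GeneBindingSummary],
    known_hypoxia: Optional[Iterable[str]] = None,
    target_window: int = TARGET_WINDOW,
) -> list[TargetCall]:
    """HIF1a-dependent target: a DEG with >=1 binding site within
    ``target_window`` bp of its TSS. Known-hypoxia matching is exact,
    case-insensitive symbol comparison."""
    known = {g.upper() for g in known_hypoxia} if known_hypoxia is not None else set()
    calls = []
    for d, s in join_binding(degs, summaries):
        bound = s.min_abs_distance <= target_window
        dependent = bound and d.status in ("up", "down")
        direction = (
            "activated" if (dependent and d.status == "up")
            else "repressed" if (dependent and d.status == "down")
            else "none"
        )
        calls.append(
            TargetCall(
                gene_id=d.gene_id,
                hif1a_dependent=dependent,
                direction=direction,
                known_hypoxia=d.gene_id.upper() in known,
            )
        )
    return calls


def target_counts(calls: Sequence[TargetCall]) -> dict[str, int]:
    activated = sum(1 for c in calls if c.direction == "activated")
    repressed = sum(1 for c in calls if c.direction == "repressed")
    known = sum(1 for c in calls if c.hif1a_dependent and c.known_hypoxia)
    return {
        "activated": activated,
        "repressed": repressed,
        "total": activated + repressed,
        "known_hypoxia": known,
        "novel": activated + repressed - known,
    }


def overlap_counts(
    degs: Sequence[DEGCall],
    summaries: Sequence[GeneBindingSummary],
    target_window: int = TARGET_WINDOW,
) -> dict[str, int]:
    """Overlap table of DEG status x binding within the target window:
    upregulated-with-binding, downregulated-with-binding, bound non-DEGs,
    and unbound DEGs."""
    pairs = join_binding(degs, summaries)
    bound = {d.gene_id: s.min_abs_distance <= target_window for d, s in pairs}
    up_bound = sum(1 for d, _ in pairs if d.status == "up" and bound[d.gene_id])
    down_bound = sum(1 for d, _ in pairs if d.status == "down" and bound[d.gene_id])
    bound_non = sum(1 for d, _ in pairs if d.status == "non" and bound[d.gene_id])
    deg_unbound = sum(
        1 for d, _ in pairs if d.status in ("up", "down") and not bound[d.gene_id]
    )
    return {
        "up_bound": up_bound,
        "down_bound": down_bound,
        "bound_non_deg": bound_non,
        "deg_unbound": deg_unbound,
    }
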