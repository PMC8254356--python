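"""Random-placement null model and enrichment statistics.

Observed binding-site annotations are compared against replicates of the
same intervals shuffled across the genome (lengths preserved, placement
uniform, chromosome drawn with probability proportional to its length).
Enrichment per category is reported as the relative percentage difference
rpd = 100 * (observed - expected) / expected, with chi-square tests and
Bonferroni correction across categories.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .annotate import DISTANCE_BINS, FEATURES, PeakAnnotation
from .core import Genome, GenomicInterval, Peak


@dataclass
class ShuffleConfig:
    n_replicates: int = 100
    seed: int = 0
    mode: str = "genome-wide"  # or "same-chromosome"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mode not in ("genome-wide", "same-chromosome"):
            raise ValueError(f"unknown shuffle mode {self.mode!r}")


@dataclass
class EnrichmentResult:
    category: str
    observed: int
    expected: float
    rpd: float
    chi2_stat: float
    pvalue: float
    pvalue_adj: float = np.nan


def shuffle_intervals(
    peaks: Sequence[Peak], genome: Genome, cfg: ShuffleConfig
) -> list[list[Peak]]:
    """Generate ``cfg.n_replicates`` random placements of the peak set.

    Every replicate preserves the number of intervals, their lengths and
    their summit offsets; shuffled intervals may overlap one another.
    """
    names = list(genome.chroms)
    lengths = np.array([genome.chroms[c] for c in names], dtype=np.int64)
    max_len = int(lengths.max())
    for p in peaks:
        if len(p.interval) > max_len:
            raise ValueError(
                f"interval of length {len(p.interval)} exceeds every chromosome"
            )
    rng = np.random.default_rng(cfg.seed)
    plens = np.array([len(p.interval) for p in peaks], dtype=np.int64)
    replicates: list[list[Peak]] = []
    for _ in range(cfg.n_replicates):
        shuffled: list[Peak] = []
        if cfg.mode == "genome-wide":
            for p, plen in zip(peaks, plens):
                fits = lengths >= plen
                probs = lengths * fits / (lengths * fits).sum()
                ci = rng.choice(len(names), p=probs)
                start = int(rng.integers(0, lengths[ci] - plen + 1))
                shuffled.append(
                    Peak(
                        GenomicInterval(names[ci], start, start + int(plen)),
                        summit_offset=p.summit_offset,
                    )
                )
        else:  # same-chromosome
            for p, plen in zip(peaks, plens):
                clen = genome.length(p.chrom)
                if plen > clen:
                    raise ValueError(
                        f"interval longer than its chromosome {p.chrom} in same-chromosome mode"
                    )
                start = int(rng.integers(0, clen - plen + 1))
                shuffled.append(
                    Peak(
                        GenomicInterval(p.chrom, start, start + int(plen)),
                        summit_offset=p.summit_offset,
                    )
                )
        replicates.append(shuffled)
    return replicates


def relative_percentage_difference(observed: float, expected: float) -> float:
    """rpd = 100 * (observed - expected) / expected."""
    if expected <= 0:
        raise ValueError(
            "expected count is 0; increase n_replicates so every category "
            "receives null mass"
        )
    return 100.0 * (observed - expected) / expected


def gof_chi_square(
    observed: Sequence[float], expected: Sequence[float]
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square with expected counts rescaled to the
    observed total; df = k - 1, upper-tail p."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.size < 2:
        raise ValueError("need >= 2 categories")
    if np.any(exp <= 0):
        raise ValueError("all expected counts must be > 0")
    if obs.sum() <= 0:
        raise ValueError("observed total must be > 0")
    exp = exp * obs.sum() / exp.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def bonferroni_adjust(pvalues: Sequence[float], m: Optional[int] = None) -> list[float]:
    """min(1, m*p) per p-value; ``m`` defaults to the number of tests."""
    pvals = list(pvalues)
    if m is None:
        m = len(pvals)
    if m < len(pvals):
        raise ValueError("m must be >= number of p-values")
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in pvals]


# ---------------------------------------------------------------------------
# Category counting and enrichment tables
# ---------------------------------------------------------------------------

def count_distance_bins(anns: Sequence[PeakAnnotation]) -> dict[str, int]:
    c = Counter(a.distance_bin for a in anns if a.distance_bin is not None)
    return {b: c.get(b, 0) for b in DISTANCE_BINS}


def count_features(anns: Sequence[PeakAnnotation]) -> dict[str, int]:
    c = Counter(a.feature for a in anns if a.feature is not None)
    return {f: c.get(f, 0) for f in FEATURES}


JOINT_CELLS = tuple(
    f"{b}:{state}" for b in DISTANCE_BINS for state in ("open", "closed")
)


def count_joint_cells(anns: Sequence[PeakAnnotation]) -> dict[str, int]:
    c: Counter = Counter()
    for a in anns:
        if a.distance_bin is None or a.open_chromatin is None:
            continue
        c[f"{a.distance_bin}:{'open' if a.open_chromatin else 'closed'}"] += 1
    return {cell: c.get(cell, 0) for cell in JOINT_CELLS}


@dataclass
class EnrichmentTable:
    """Per-category enrichment plus the overall goodness-of-fit test."""

    results: list[EnrichmentResult]
    gof_stat: float
    gof_df: int
    gof_pvalue: float
    per_replicate: list[dict[str, int]] = field(default_factory=list)


def expected_distribution(
    replicate_counts: Sequence[dict[str, int]], categories: Sequence[str]
) -> dict[str, float]:
    """Mean count per category over shuffle replicates."""
    return {
        c: float(np.mean([rc.get(c, 0) for rc in replicate_counts]))
        for c in categories
    }


def category_enrichment(
    observed_counts: dict[str, int],
    replicate_counts: Sequence[dict[str, int]],
    categories: Optional[Sequence[str]] = None,
) -> EnrichmentTable:
    """Observed-vs-null enrichment for a categorical annotation.

    Per category: rpd and a 1-df chi-square of the in/out split against
    the null proportions, Bonferroni-adjusted across categories. Overall:
    a k-1 df goodness-of-fit chi-square across all categories.
    """
    if categories is None:
        categories = list(observed_counts)
    expected = expected_distribution(replicate_counts, categories)
    # Categories with no mass under either the data or the null are not
    # testable and are dropped; null-empty categories with observed mass
    # still error (the user must raise n_replicates).
    categories = [
        c for c in categories
        if not (observed_counts.get(c, 0) == 0 and expected[c] == 0.0)
    ]
    if len(categories) < 2:
        raise ValueError("fewer than 2 categories with observed or null mass")
    for c in categories:
        if expected[c] <= 0:
            raise ValueError(
                f"category {c!r} has observed mass but zero null mass; "
                "increase n_replicates"
            )
    n_obs = sum(observed_counts.get(c, 0) for c in categories)
    n_exp = sum(expected[c] for c in categories)
    results = []
    for c in categories:
        o = observed_counts.get(c, 0)
        e = expected[c]
        rpd = relative_percentage_difference(o, e)
        # 1-df test of this category against its complement
        e_scaled = e * n_obs / n_exp
        stat, _, p = gof_chi_square([o, n_obs - o], [e_scaled, n_obs - e_scaled])
        results.append(EnrichmentResult(c, o, e, rpd, stat, p))
    adj = bonferroni_adjust([r.pvalue for r in results])
    for r, pa in zip(results, adj):
        r.pvalue_adj = pa
    gof_stat, gof_df, gof_p = gof_chi_square(
        [observed_counts.get(c, 0) for c in categories],
        [expected[c] for c in categories],
    )
    return EnrichmentTable(results, gof_stat, gof_df, gof_p, list(replicate_counts))


def joint_distance_accessibility_enrichment(
    anns: Sequence[PeakAnnotation],
    replicate_anns: Sequence[Sequence[PeakAnnotation]],
) -> EnrichmentTable:
    """Enrichment per (distance bin x open/closed chromatin) cell — 8
    cells, each tested against its null proportion, Bonferroni over 8."""
    obs = count_joint_cells(anns)
    reps = [count_joint_cells(r) for r in replicate_anns]
    return category_enrichment(obs, reps, JOINT_CELLS)


def enrichment_to_frame(table: EnrichmentTable):
    import pandas as pd

    return pd.DataFrame(
        [
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
        ]
    )
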