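"""IUPAC consensus motif scanning and enrichment.

Validates binding specificity by counting occurrences of the hypoxia
response element consensus (RCGTG by default) inside bound regions and
comparing the per-kb density against shuffled regions. Overlapping
matches are counted; both strands are scanned by default (the reverse
strand by matching the reverse-complement pattern on the forward
sequence).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .core import Genome, Peak

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")


@dataclass(frozen=True)
class MotifSpec:
    pattern: str = "RCGTG"
    scan_both_strands: bool = True

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("empty motif pattern")
        for ch in self.pattern.upper():
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC character {ch!r} in motif")


def reverse_complement(pattern: str) -> str:
    return pattern.upper().translate(_COMPLEMENT)[::-1]


def _regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping matches are all found
    body = "".join(f"[{IUPAC[ch]}]" for ch in pattern.upper())
    return re.compile(f"(?=({body}))")


@dataclass
class ScanResult:
    count: int
    positions: list[tuple[int, str]]  # (0-based position, strand)


def scan_sequence(seq: str, motif: MotifSpec) -> ScanResult:
    """Count motif occurrences in one sequence.

    Positions are 0-based starts of the matched window on the forward
    sequence; strand records which orientation matched. An N in the
    sequence never matches a non-N motif symbol.
    """
    seq = seq.upper()
    spec = MotifSpec(motif.pattern.upper(), motif.scan_both_strands)
    positions = [(m.start(), "+") for m in _regex(spec.pattern).finditer(seq)]
    if spec.scan_both_strands:
        rc = reverse_complement(spec.pattern)
        positions += [(m.start(), "-") for m in _regex(rc).finditer(seq)]
    positions.sort()
    return ScanResult(count=len(positions), positions=positions)


def _region_stats(
    peaks: Sequence[Peak], genome: Genome, motif: MotifSpec
) -> tuple[int, float]:
    """(total matches, kb scanned) over the peak intervals."""
    if genome.sequence is None:
        raise ValueError("genome has no sequence; supply a FASTA")
    total = 0
    bp = 0
    for p in peaks:
        try:
            seq = genome.sequence[p.chrom][p.interval.start : p.interval.end]
        except KeyError:
            raise ValueError(f"no sequence for chromosome {p.chrom!r}") from None
        total += scan_sequence(seq, motif).count
        bp += len(p.interval)
    return total, bp / 1000.0


@dataclass
class MotifEnrichment:
    observed_per_kb: float
    expected_per_kb: float
    ratio: float
    empirical_p: float
    observed_matches: int
    kb_scanned: float
    n_replicates: int


def motif_enrichment(
    peaks: Sequence[Peak],
    shuffles: Sequence[Sequence[Peak]],
    genome: Genome,
    motif: MotifSpec = MotifSpec(),
) -> MotifEnrichment:
    """Match density in bound regions vs shuffled regions.

    The empirical p-value is the add-one-corrected fraction of shuffle
    replicates whose matches/kb is >= the observed density.
    """
    obs_matches, obs_kb = _region_stats(peaks, genome, motif)
    obs_rate = obs_matches / obs_kb if obs_kb > 0 else 0.0
    rep_rates = []
    for rep in shuffles:
        m, kb = _region_stats(rep, genome, motif)
        rep_rates.append(m / kb if kb > 0 else 0.0)
    n_ge = sum(1 for r in rep_rates if r >= obs_rate)
    expected = sum(rep_rates) / len(rep_rates) if rep_rates else float("nan")
    return MotifEnrichment(
        observed_per_kb=obs_rate,
        expected_per_kb=expected,
        ratio=obs_rate / expected if expected > 0 else float("inf"),
        empirical_p=(1 + n_ge) / (len(rep_rates) + 1),
        observed_matches=obs_matches,
        kb_scanned=obs_kb,
        n_replicates=len(rep_rates),
    )
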