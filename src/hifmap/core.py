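"""Core data model and file I/O for the binding-site integration pipeline.

All coordinates are 0-based half-open (BED convention). GTF input (1-based,
inclusive) is converted on read. The transcription start site (TSS) of a
minus-strand gene is ``gene_end - 1`` in these coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

log = logging.getLogger("hifmap")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass
class Genome:
    """Chromosome name -> length map, optionally carrying sequence.

    ``chroms`` preserves declaration order; lengths are bp. If ``sequence``
    is present each entry must match the declared length.
    """

    chroms: dict[str, int]
    sequence: Optional[dict[str, str]] = None

    def __post_init__(self):
        for name, length in self.chroms.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.sequence is not None:
            for name, seq in self.sequence.items():
                declared = self.chroms.get(name)
                if declared is None:
                    raise ValueError(f"sequence for undeclared chromosome {name!r}")
                if len(seq) != declared:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared {declared} for {name!r}"
                    )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def length(self, chrom: str) -> int:
        return self.chroms[chrom]

    @property
    def total_length(self) -> int:
        return sum(self.chroms.values())


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A binding site. ``ref_point`` anchors all distance computations:
    the summit when a narrowPeak summit offset is available, else the
    integer midpoint floor((start+end)/2)."""

    interval: GenomicInterval
    summit_offset: Optional[int] = None
    score: Optional[float] = None

    def __post_init__(self):
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length {len(self.interval)}"
            )

    @property
    def ref_point(self) -> int:
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return (self.interval.start + self.interval.end) // 2

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-level annotation; ``tss`` is derived from strand."""

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not (0 <= self.gene_start < self.gene_end):
            raise ValueError(
                f"gene {self.gene_id}: invalid span {self.gene_start}-{self.gene_end}"
            )

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end - 1


@dataclass(frozen=True)
class GeneExpressionRecord:
    gene_id: str
    log2fc: float
    pvalue: float

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"gene {self.gene_id}: p-value {self.pvalue} outside [0, 1]")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> Genome:
    """Read a two-column (name, length) chrom.sizes file."""
    chroms: dict[str, int] = {}
    with open(path) as fh:
        lines = [ln for ln in fh]
    if not any(ln.strip() for ln in lines):
        raise ParseError(path, 0, "empty chrom.sizes file")
    for i, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(path, i, f"expected 2 columns, got {len(fields)}")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(path, i, f"non-integer length {fields[1]!r}") from None
        if length <= 0:
            raise ParseError(path, i, f"non-positive length {length} for {name!r}")
        if name in chroms:
            raise ParseError(path, i, f"duplicate chromosome {name!r}")
        chroms[name] = length
    return Genome(chroms=chroms)


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chroms.items():
            fh.write(f"{name}\t{length}\n")


def read_peaks(path, genome: Optional[Genome] = None) -> list[Peak]:
    """Read BED3/BED6 or 10-column ENCODE narrowPeak into Peaks.

    narrowPeak is detected by exactly 10 columns; its column 10 (0-based
    summit offset from start) sets the summit when >= 0, else the midpoint
    rule applies. Coordinates are validated against ``genome`` when given.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, i, f"expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, i, "non-integer coordinates") from None
            if start >= end:
                raise ParseError(path, i, f"start {start} >= end {end}")
            if genome is not None:
                if chrom not in genome:
                    raise ParseError(path, i, f"unknown chromosome {chrom!r}")
                if end > genome.length(chrom):
                    raise ParseError(
                        path, i, f"interval end {end} beyond chromosome end {genome.length(chrom)}"
                    )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(path, i, f"non-numeric score {fields[4]!r}") from None
            summit = None
            if len(fields) == 10:  # narrowPeak
                try:
                    raw = int(fields[9])
                except ValueError:
                    raise ParseError(path, i, f"non-integer summit {fields[9]!r}") from None
                if raw >= 0:
                    if raw >= end - start:
                        raise ParseError(path, i, f"summit offset {raw} outside peak")
                    summit = raw
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, name=name, strand=strand),
                    summit_offset=summit,
                    score=score,
                )
            )
    return peaks


def write_peaks_narrowpeak(peaks: Iterable[Peak], path) -> None:
    """Write peaks as 10-column narrowPeak (summit -1 when absent)."""
    with open(path, "w") as fh:
        for k, p in enumerate(peaks):
            iv = p.interval
            name = iv.name or f"peak_{k + 1}"
            score = int(p.score) if p.score is not None else 0
            summit = p.summit_offset if p.summit_offset is not None else -1
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t"
                f"{iv.strand}\t0\t-1\t-1\t{summit}\n"
            )


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            name = iv.name or f"region_{k + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed_intervals(path, genome: Optional[Genome] = None) -> list[GenomicInterval]:
    """Read a BED file as plain intervals (e.g. ATAC open-chromatin regions)."""
    return [p.interval for p in read_peaks(path, genome=genome)]


def read_gene_table(path, genome: Optional[Genome] = None) -> list[GeneAnnotation]:
    """Read genes from a simplified TSV (gene_id, chrom, strand, start, end)
    or from GTF ``gene`` features (detected by 9 tab-separated columns with
    an attribute field). GTF coordinates convert 1-based inclusive ->
    0-based half-open. Genes on chromosomes absent from ``genome`` are
    dropped with a warning."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    n_dropped = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 9 and fields[8]:
                feature = fields[2]
                if feature != "gene":
                    continue
                chrom, strand = fields[0], fields[6]
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError:
                    raise ParseError(path, i, "non-integer GTF coordinates") from None
                start, end = start1 - 1, end1
                gene_id = _gtf_attribute(fields[8], "gene_id")
                if gene_id is None:
                    raise ParseError(path, i, "GTF gene record lacks gene_id attribute")
            elif len(fields) >= 5:
                if i == 1 and fields[0].lower() in ("gene_id", "gene", "id"):
                    continue  # header row
                gene_id, chrom, strand = fields[0], fields[1], fields[2]
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError:
                    raise ParseError(path, i, "non-integer coordinates") from None
            else:
                raise ParseError(path, i, f"unrecognized gene table row ({len(fields)} columns)")
            if strand not in ("+", "-"):
                raise ParseError(path, i, f"unknown strand symbol {strand!r}")
            if gene_id in seen:
                raise ParseError(path, i, f"duplicate gene_id {gene_id!r}")
            if genome is not None and chrom not in genome:
                n_dropped += 1
                continue
            try:
                gene = GeneAnnotation(gene_id, chrom, strand, start, end)
            except ValueError as exc:
                raise ParseError(path, i, str(exc)) from None
            seen.add(gene_id)
            genes.append(gene)
    if n_dropped:
        log.warning("dropped %d genes on chromosomes absent from the genome", n_dropped)
    return genes


def _gtf_attribute(attr_field: str, key: str) -> Optional[str]:
    for part in attr_field.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key):].strip().strip('"')
    return None


def write_gene_table(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.gene_start}\t{g.gene_end}\n")


def write_gene_gtf(genes: Iterable[GeneAnnotation], path, source: str = "hifmap") -> None:
    """Write gene records as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.gene_start + 1}\t{g.gene_end}\t.\t"
                f'{g.strand}\t.\tgene_id "{g.gene_id}";\n'
            )


def read_expression_table(
    path,
    gene_id_col: str = "gene_id",
    log2fc_col: str = "log2FC",
    pvalue_col: str = "pvalue",
) -> list[GeneExpressionRecord]:
    """Read a TSV differential-expression table.

    Requires a header naming the three columns (names configurable). Rows
    with missing/empty values are dropped and counted in the log; p-values
    outside [0, 1] are errors.
    """
    records: list[GeneExpressionRecord] = []
    n_dropped = 0
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError(path, 1, "empty expression table")
        header = header_line.rstrip("\n").split("\t")
        try:
            idx = {c: header.index(c) for c in (gene_id_col, log2fc_col, pvalue_col)}
        except ValueError as exc:
            raise ParseError(path, 1, f"missing required column: {exc}") from None
        for i, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            raw = [fields[idx[c]] if idx[c] < len(fields) else "" for c in (gene_id_col, log2fc_col, pvalue_col)]
            if any(v in ("", "NA", "NaN", "nan", ".") for v in raw):
                n_dropped += 1
                continue
            gene_id = raw[0]
            try:
                log2fc, pvalue = float(raw[1]), float(raw[2])
            except ValueError:
                raise ParseError(path, i, "non-numeric log2FC or p-value") from None
            if not (0.0 <= pvalue <= 1.0):
                raise ParseError(path, i, f"p-value {pvalue} outside [0, 1]")
            records.append(GeneExpressionRecord(gene_id, log2fc, pvalue))
    if n_dropped:
        log.warning("dropped %d expression rows with missing values", n_dropped)
    return records


def write_expression_table(records: Iterable[GeneExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2FC\tpvalue\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into name -> uppercase sequence (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width] + "\n")


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; matching is case-insensitive downstream."""
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip()}
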