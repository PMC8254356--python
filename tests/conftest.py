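import numpy as np
import pytest

from hifmap.core import GeneAnnotation, Genome, GenomicInterval, Peak


@pytest.fixture
def toy_genome():
    return Genome({"chr1": 1_000_000, "chr2": 500_000})


def random_genes(rng, genome, n):
    """Random genes, non-overlapping per chromosome via slot placement."""
    names = list(genome.chroms)
    genes = []
    per = max(1, n // len(names))
    gid = 0
    for chrom in names:
        clen = genome.chroms[chrom]
        slot = clen // per
        for j in range(per):
            if gid >= n:
                break
            glen = int(rng.integers(500, min(5000, slot - 1)))
            start = int(rng.integers(j * slot, (j + 1) * slot - glen))
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(GeneAnnotation(f"g{gid:04d}", chrom, strand, start, start + glen))
    return genes


def random_peaks(rng, genome, n, length=200):
    names = list(genome.chroms)
    lengths = np.array([genome.chroms[c] for c in names])
    probs = lengths / lengths.sum()
    peaks = []
    for i in range(n):
        ci = int(rng.choice(len(names), p=probs))
        start = int(rng.integers(0, lengths[ci] - length + 1))
        summit = int(rng.integers(0, length)) if rng.random() < 0.5 else None
        peaks.append(
            Peak(
                GenomicInterval(names[ci], start, start + length, name=f"p{i}"),
                summit_offset=summit,
            )
        )
    return peaks


def random_intervals(rng, genome, n, min_len=100, max_len=2000):
    names = list(genome.chroms)
    out = []
    for i in range(n):
        chrom = names[int(rng.integers(0, len(names)))]
        clen = genome.chroms[chrom]
        ilen = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, clen - ilen + 1))
        out.append(GenomicInterval(chrom, start, start + ilen, name=f"iv{i}"))
    return out
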