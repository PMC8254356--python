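# hifmap

Integration of genome-wide transcription-factor binding sites with open
chromatin and differential gene expression, built around the analysis of
HIF1α (hypoxia-inducible factor 1α) CUT&RUN binding in a vertebrate
genome.

## The problem

A CUT&RUN (or ChIP-seq) experiment yields thousands of binding-site
intervals; an RNA-seq contrast yields per-gene log2 fold changes and
p-values; ATAC-seq yields open-chromatin regions. The questions this
package answers, for analysts working with such processed outputs:

1. **Where does the factor bind?** Each peak is anchored at its summit
   (or midpoint) and assigned to the gene with the nearest transcription
   start site (TSS). Distances are binned (0–3 kb, 3–10 kb, 10–100 kb,
   >100 kb) and peaks are classified as promoter (±3 kb of a TSS), gene
   body, or intergenic.
2. **Is that placement non-random?** Observed category counts are
   compared against a random-placement null: the same intervals shuffled
   across the genome (lengths preserved, chromosome drawn ∝ length,
   start uniform). Enrichment per category is the relative percentage
   difference rpd = 100·(O − E)/E with a goodness-of-fit χ² across
   categories (E rescaled to the observed total, df = k − 1) and
   Bonferroni correction, jointly stratified by distance bin ×
   open/closed chromatin.
3. **Does binding track regulation?** Genes are called differentially
   expressed (DEG) when |log2FC| > 0.6 at p < 0.05. Binding–DEG
   association is a Pearson χ² on the 2×2 bound/unbound table, overall
   and within cumulative-exclusive distance strata of the gene's minimum
   binding distance (≤3 kb; 3–10 kb; 10–100 kb). Fold-change magnitudes
   of bound vs unbound genes are compared by a two-sided Mann–Whitney U
   (exact for small samples). A gene is a **factor-dependent target**
   when it is a DEG with ≥1 binding site within 100 kb of its TSS;
   targets are cross-referenced against a known-hypoxia gene list.
4. **Is the consensus motif there?** Bound sequences are scanned for an
   IUPAC consensus (RCGTG, the hypoxia response element) on both strands
   and its per-kb density compared against shuffled regions with an
   add-one-corrected empirical p-value.

A fully deterministic synthetic-data generator emits toy genomes, gene
tables, ATAC regions, peaks and expression tables with planted versions
of all of these signals — including the distance-dependent regulation
pattern in which proximally bound (≤3 kb) genes are preferentially
upregulated and 3–10 kb-bound genes preferentially downregulated — so
every stage is testable end to end without downloads.

## Worked example

```bash
hifmap simulate --seed 42 -o example_data
hifmap run --peaks example_data/peaks.narrowPeak \
    --chrom-sizes example_data/genome.chrom.sizes \
    --genes example_data/genes.tsv \
    --expression example_data/expression.tsv \
    --atac example_data/atac.bed \
    --n-replicates 25 --seed 1 -o example_out
hifmap report example_out/summary.json
```

or, from Python, the scripts in `examples/` (one per capability). On a
small simulated dataset (300 genes, 250 peaks, 2×2 Mb genome, seed 42)
`examples/04_expression_integration.py` prints:

```
DEG counts: {'up': 47, 'down': 14, 'non': 239}
bound: 93.4% of DEGs vs 46.4% of non-DEGs (chi2 = 43.6, p = 4.1e-11)
  up_vs_non    0-3kb     95.7% vs  32.6%  p_adj = 4.09e-15 (enriched)
  down_vs_non  3-10kb    78.6% vs  13.4%  p_adj = 8.31e-10 (enriched)
fold-change magnitude, bound vs unbound: U = 15960, p = 6.5e-11
dependent targets (DEG + binding within 100 kb): {'activated': 45,
  'repressed': 12, 'total': 57, 'known_hypoxia': 10, 'novel': 47}
```

Reading: nearly all upregulated genes carry binding within 3 kb of their
TSS while downregulated genes are enriched for 3–10 kb binding — the
planted distance-dependent regulation recovered with Bonferroni-adjusted
significance — and 57 genes qualify as factor-dependent targets.

`hifmap run` writes, per stage: an annotated BED (nearest gene, signed
distance, feature, accessibility per peak), enrichment TSVs
(observed/expected/rpd/χ²/p/p_adj per category), a gene-level master
table, and `summary.json` holding every panel's numbers;
`hifmap report` renders that JSON as markdown without recomputing
anything.

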