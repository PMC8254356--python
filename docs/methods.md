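# Methods

This note documents the models, conventions and design decisions behind
hifmap, and what the synthetic tests do and do not demonstrate.

## Coordinate and anchoring conventions

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read (1-based inclusive → 0-based half-open). The TSS of a
minus-strand gene is `gene_end − 1`. Each peak's distance computations
are anchored at a single **reference point**: the narrowPeak summit when
column 10 is ≥ 0, otherwise the integer midpoint ⌊(start+end)/2⌋. The
summit is the better estimate of the protein–DNA contact point for
high-resolution assays like CUT&RUN; the midpoint fallback keeps plain
BED input usable. The reference point used is recorded in the annotated
output so results are auditable.

Signed distance is `ref_point − TSS`, orientation-corrected so positive
means downstream of the TSS in the gene's direction of transcription;
all binning and statistics use the absolute distance.

## Nearest-TSS assignment

Each peak is assigned to the gene with the minimal |ref − TSS| on the
same chromosome (binary search over the sorted TSS array; the brute-force
all-pairs scan exists only as a test oracle). Equidistant TSSs are
broken by the lexicographically smaller gene_id — an arbitrary but
deterministic rule; tie frequency is logged. Peaks on chromosomes with
no annotated gene get an infinite-distance sentinel, are excluded from
bin counts, and are logged. Distance bins are upper-closed: d ≤ 3000 →
0–3 kb, 3000 < d ≤ 10000 → 3–10 kb, 10000 < d ≤ 100000 → 10–100 kb,
else >100 kb. Edge handling is a convention choice (the boundary mass is
negligible at genomic scale) and is stated in the run metadata.

Feature classes partition the peaks with promoter taking precedence:
promoter if any TSS lies within 3 kb of the reference point, else gene
body if the reference point falls inside any gene span, else intergenic.
Precedence is required for the three percentages to be mutually
exclusive.

Open-chromatin overlap defaults to ≥1 bp intersection of the full peak
interval with any accessible region (`any`), the standard interval-
intersection semantics; a `summit` mode restricts to the reference point
itself.

## Random-placement null and enrichment

The null redistributes the observed intervals across the genome:
chromosome drawn with probability proportional to its length (restricted
to chromosomes that can hold the interval), start uniform on
[0, L − len]; lengths and summit offsets are preserved and shuffled
intervals may overlap each other — no exclusion or blacklist regions.
A `same-chromosome` mode re-places each interval on its own chromosome.

Expected counts are means over `n_replicates` shuffles (default 100; a
single-draw mode reproduces the one-shuffle procedure some studies use —
averaging merely stabilises E). Per category we report
rpd = 100·(O − E)/E, a 1-df χ² of the in/out split against the null
proportion, and Bonferroni adjustment across the categories tested;
across categories we report a goodness-of-fit χ² with E rescaled to the
observed total (so df = k − 1 remains valid if a replicate drops
unannotatable peaks). Categories with zero mass under both the data and
the null are untestable and are dropped; zero null mass with observed
mass is an error telling the user to raise `n_replicates`. The joint
distance × accessibility analysis applies the same machinery to the 8
(bin × open/closed) cells.

An alternative rpd reading — difference of percentages rather than of
counts — changes only the scale, not sign or significance, since both
totals are equal; the count-ratio definition is recorded in run
metadata.

## Expression integration

A gene is **bound** when it is the nearest-neighbor gene of ≥1 peak
(peak→gene mapping, not a window scan around the gene; a window variant
can be emulated by filtering the gene summaries on `min_abs_distance`).
DEG calls use strict inequalities: up ⇔ log2FC > 0.6 and p < 0.05, down
symmetric. The 2×2 association tests are Pearson χ² without continuity
correction by default (`yates=True` available); with the group sizes
this pipeline targets the conclusion is insensitive to the correction.
Distance strata are cumulative-exclusive on the gene's minimum binding
distance (≤3 kb; >3–≤10 kb; >10–≤100 kb) so the three strata partition
the bound genes; Bonferroni is applied within each comparison across its
strata. The Mann–Whitney magnitude test compares |log2FC| and uses exact
enumeration when both groups have n ≤ 8 without cross-group ties,
otherwise the tie-corrected normal approximation.

Target calling: DEG and ≥1 binding site within 100 kb of the TSS
(`target_window` configurable). Known-hypoxia matching is exact,
case-insensitive symbol comparison. Genes present in the expression
table but absent from the annotation are kept as unbound with a warning
(they can still be DEGs); a >50% identifier mismatch raises, since it
almost always means mismatched annotations rather than missing genes.

## Motif scanning

IUPAC consensus scanning (default RCGTG, the hypoxia response element)
counts overlapping matches via a regex lookahead on the forward sequence
plus the reverse-complement pattern; an N in the sequence never matches
a non-N motif symbol. Enrichment is matches/kb in bound regions vs each
shuffle replicate, with empirical p = (1 + #{replicates ≥ observed}) /
(R + 1). No PWM scoring, background Markov model, E-values, or de novo
discovery — this module validates consensus enrichment, nothing more.

## Synthetic data generator

Defaults: 5 × 10 Mb chromosomes; 2000 non-overlapping genes of 1–10 kb
(slot placement — one gene per equal-width slot, which guarantees
collision-free packing); ATAC regions of 1 kb covering 8% of the genome
with 40% anchored over a random TSS; 1500 peaks of 300 bp; planting
probabilities p_promoter = 0.3 (reference point uniform within ±3 kb of
a random TSS, shrunk by the ±20 bp summit jitter so planted peaks stay
inside the first distance bin), p_open = 0.5 for the remainder (uniform
inside a random ATAC region), else uniform genome-wide. Expression:
genes with minimum binding distance ≤3 kb are upregulated with
probability 0.5; 3–10 kb bound genes downregulated with probability 0.4;
all others differentially expressed at a 3% baseline with random
direction. Planted DE genes draw log2FC ~ sign·(1.5 + N(0, 0.25)) and
p ~ Beta(0.1, 1) (skewed to 0: ~74% fall below α = 0.05, so recovery is
deliberately imperfect); background genes draw log2FC ~ N(0, 0.25),
p ~ U(0, 1). A p-value distribution rather than a count model is enough
because the pipeline consumes only (log2FC, p). Per-stage RNG streams
are spawned from the single seed, making every emitted file
byte-identical across reruns.

The generator emulates the *structure* of processed binding /
accessibility / expression data, not its realism: no GC or mappability
bias, no correlated replicate noise, no transcript models, a gene
density ~25× that of a vertebrate genome. Passing recovery tests
therefore demonstrates that the statistics detect the planted effects at
desk scale with calibrated type-I error — not that effect sizes or
p-value magnitudes transfer to real genomes.

## Test and calibration problem sizes

Statistical checks run at sizes chosen for quick, reliable desk-scale
power: goodness-of-fit calibration uses a 2 × 2 Mb genome, 200 genes and
300 peaks, with the expected vector taken from a shared 300-replicate
shuffle (its Monte-Carlo error is an order of magnitude below the
per-seed sampling noise) and 200 single-draw observed sets;
binding-independent 2×2 calibration regenerates a 600-gene / 400-peak
layout per seed (200 seeds) so the rejection rate is unconditional;
planted-effect recovery runs the full pipeline at the generator defaults
over 20 seeds with 20 shuffle replicates each. Known limitation of the
shared-expected design: treating the replicate mean as exact slightly
inflates the χ² (≈ (1 + 1/R)); with R = 300 the effect is ~0.3% and
invisible at the calibration tolerance.

## Known limitations

- Genome-scale outputs of a real study (peak counts, printed p-values
  against a single bedtools shuffle) are not reproducible from desk-scale
  synthetic data; only directionality, calibration and the arithmetic of
  the published count tables are.
- No GC-/mappability-matched null and no blacklist support.
- Gene-level only: no exon/intron/UTR sub-classification, no enhancer
  prediction, no transcript reconstruction.
- Nearest-neighbor assignment attributes each peak to exactly one gene;
  regulatory many-to-many relationships are summarized, not modeled.
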