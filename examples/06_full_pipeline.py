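"""Run the complete pipeline from files on disk and render the report.

Equivalent shell commands:
    hifmap simulate --seed 42 -o example_data
    hifmap run --peaks example_data/peaks.narrowPeak ... -o example_out
    hifmap report example_out/summary.json
"""

from pathlib import Path

from hifmap.pipeline import RunConfig, report, run_pipeline
from hifmap.simulate import SimulationConfig, generate_dataset, write_dataset

data = Path("example_data")
write_dataset(
    generate_dataset(SimulationConfig(seed=42, n_chroms=2,
                                      chrom_length=2_000_000, n_genes=300,
                                      n_peaks=250, gene_length_min=500,
                                      gene_length_max=4000, with_sequence=True)),
    data,
)
cfg = RunConfig(
    peaks=str(data / "peaks.narrowPeak"),
    chrom_sizes=str(data / "genome.chrom.sizes"),
    genes=str(data / "genes.tsv"),
    expression=str(data / "expression.tsv"),
    atac=str(data / "atac.bed"),
    fasta=str(data / "genome.fa"),
    hypoxia=str(data / "hypoxia_genes.txt"),
    outdir="example_out",
    n_replicates=25,
    seed=1,
)
summary = run_pipeline(cfg)
print(report(summary))
# Every number in the rendered report is read from example_out/summary.json;
# the stage TSV/BED files next to it carry the per-peak and per-gene detail.
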