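"""Generate the synthetic four-condition RNAPII study and summarize its truth.

Creates the mini dataset (2 x 500 kb chromosomes, 60 planted enhancer-like
features across four stage patterns, planted motifs, mappability gaps, input
artifacts) and writes the ground-truth tables under results/. Full read BEDs
and the genome FASTA go to scratch/ (they are bulky and regenerable).
"""

from pathlib import Path

import polprime as pp
from polprime import io as pio

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    ds = pp.make_mini_dataset(seed=SEED)

    ds.feature_truth.to_csv(RESULTS / "truth_features.tsv", sep="\t", index=False)
    ds.genome_truth.to_csv(RESULTS / "truth_motifs.tsv", sep="\t", index=False)
    ds.mappability_truth.to_csv(RESULTS / "truth_mappability.tsv", sep="\t", index=False)
    ds.input_truth.to_csv(RESULTS / "truth_input_artifacts.tsv", sep="\t", index=False)

    pio.write_fasta(ds.genome, SCRATCH / "genome.fa")
    ds.layout.to_chrom_sizes(SCRATCH / "chrom.sizes")
    for cond, rs in ds.readsets.items():
        pio.write_bed_reads(rs, SCRATCH / f"reads_{cond}.bed")
    pio.write_bed_reads(ds.input_reads, SCRATCH / "reads_input.bed")

    stage_counts = ds.feature_truth["stage"].value_counts()
    motif_counts = ds.feature_truth["motif_class"].value_counts()
    print(f"seed {SEED}: planted {len(ds.feature_truth)} features over "
          f"{len(ds.layout.names)} chromosomes")
    print("stage patterns:", dict(stage_counts))
    print("planted motif classes:", dict(motif_counts))
    print("reads per condition:",
          {c: rs.total_unique_reads for c, rs in ds.readsets.items()})
    print(f"truth tables -> {RESULTS}, raw data -> {SCRATCH}")


if __name__ == "__main__":
    main()
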