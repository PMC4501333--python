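"""Plain-text genomics I/O: BED6, bedGraph, chrom-sizes and FASTA.

All coordinates are 0-based, half-open. bedGraph is the 4-column UCSC
variant. FASTA reading goes through pyfaidx for random access; writing is a
simple wrapped-line writer.
"""

from __future__ import annotations

import numpy as np
from pyfaidx import Fasta

from .genome import GenomeLayout
from .tracks import BinnedTrack, ReadSet, MASK_NAMES, VALID


def read_bed_reads(path, layout: GenomeLayout | None = None) -> ReadSet:
    """Read aligned-read intervals from BED (3+ columns; strand from col 6)."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 else "+"
            records.append((chrom, start, end, strand))
    return ReadSet.from_records(records, layout=layout)


def write_bed_reads(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reads.intervals):
            iv = reads.intervals[chrom]
            for s, e, st in zip(iv["start"], iv["end"], iv["strand"]):
                strand = "+" if st > 0 else "-"
                fh.write(f"{chrom}\t{s}\t{e}\tread\t0\t{strand}\n")


def write_bed_features(features, path, bin_size: int = 20) -> None:
    """Features as BED6: name = id, score = scaled max USHP (capped at 1000)."""
    with open(path, "w") as fh:
        for f in features:
            score = int(min(1000, round(f.max_ushp)))
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t{score}\t.\n")


def write_features_tsv(features, path, bin_size: int = 20) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tsummit\tmax_ushp\ttag_count\ttag_density\tstatus\tmerged_from\n")
        for f in features:
            fh.write(
                f"{f.id}\t{f.chrom}\t{f.start}\t{f.end}\t{f.summit_bp(bin_size)}\t"
                f"{f.max_ushp:.6g}\t{f.tag_count}\t{f.tag_density:.6g}\t{f.status}\t"
                f"{','.join(map(str, f.merged_from))}\n"
            )


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Per-bin values as 4-column bedGraph (adjacent equal bins not merged)."""
    bs = track.layout.bin_size
    with open(path, "w") as fh:
        for chrom in track.layout.names:
            L = track.layout.length(chrom)
            vals = track.values[chrom]
            for i, v in enumerate(vals):
                start = i * bs
                fh.write(f"{chrom}\t{start}\t{min(start + bs, L)}\t{v:.6g}\n")


def read_bedgraph(path, layout: GenomeLayout) -> dict:
    """Read a bedGraph into per-bin arrays (value assigned to covered bins)."""
    out = {c: np.zeros(layout.n_bins(c)) for c in layout.names}
    bs = layout.bin_size
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            if chrom not in out:
                raise KeyError(f"bedGraph chromosome {chrom!r} not in layout")
            b0 = int(start) // bs
            b1 = -(-int(end) // bs)
            out[chrom][b0:b1] = float(value)
    return out


def write_mask_bed(track: BinnedTrack, path) -> None:
    """Non-valid bins as BED with the mask flag in the name field."""
    bs = track.layout.bin_size
    with open(path, "w") as fh:
        for chrom in track.layout.names:
            L = track.layout.length(chrom)
            for i, code in enumerate(track.mask[chrom]):
                if code != VALID:
                    start = i * bs
                    fh.write(f"{chrom}\t{start}\t{min(start + bs, L)}\t{MASK_NAMES[int(code)]}\n")


def write_fasta(genome: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_fasta(path) -> Fasta:
    return Fasta(str(path))
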