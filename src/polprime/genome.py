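"""Genome coordinate layout shared by every binned track.

Coordinates are 0-based, half-open throughout the package. A layout fixes the
chromosome order, chromosome lengths and the bin width (default 20 bp) so that
tracks, slope profiles and feature calls are always comparable bin-for-bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with a fixed bin width.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Bin width in bp. The coverage signal is summarized per bin.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = 20
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_index", {n: l for n, l in chroms})

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.length(chrom) / self.bin_size)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin index containing base-pair position ``pos`` (0-based)."""
        if not 0 <= pos < self.length(chrom):
            raise ValueError(f"position {pos} outside {chrom} (length {self.length(chrom)})")
        return pos // self.bin_size

    def bin_start(self, bin_index: int) -> int:
        return bin_index * self.bin_size

    @classmethod
    def from_chrom_sizes(cls, path, bin_size: int = 20) -> "GenomeLayout":
        """Read a two-column ``chrom<TAB>length`` text file."""
        chroms = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, length = line.split()[:2]
                chroms.append((name, int(length)))
        return cls(tuple(chroms), bin_size=bin_size)

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")
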