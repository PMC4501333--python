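"""Unique-stack coverage tracks: binning, masking, interpolation, smoothing,
input blacklisting and slope scoring.

The central signal is the unique stack height profile (USHP): the per-base
pileup depth of deduplicated reads, summarized per 20 bp bin. Downstream
feature detection operates on the per-bin slope of the smoothed profile.

Processing order for a standard RNAPII track::

    bin_coverage -> normalize_rpm -> mask_low_mappability -> interpolate_masked
                 -> smooth -> blacklist_input -> slope_scores
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeLayout

# mask channel codes
VALID = 0
MASKED = 1
INTERPOLATED = 2
BLACKLISTED = 3

MASK_NAMES = {VALID: "valid", MASKED: "masked", INTERPOLATED: "interpolated", BLACKLISTED: "blacklisted"}


@dataclass
class ReadSet:
    """Deduplicated aligned-read intervals.

    Reads sharing (chrom, start, strand) are collapsed to a single unique
    stack, mirroring how uniquely aligned reads are counted.
    """

    intervals: dict  # chrom -> structured arrays: start, end (int64), strand (+1/-1 int8)
    total_unique_reads: int

    @classmethod
    def from_records(cls, records, layout: GenomeLayout | None = None,
                     dedup: bool = True) -> "ReadSet":
        """Build from an iterable of (chrom, start, end, strand) records.

        Deduplicates on (chrom, start, strand) unless ``dedup=False``.
        Validates against ``layout`` when given: unknown chromosomes and
        reads past a chromosome end are rejected.
        """
        by_chrom: dict[str, list] = {}
        for chrom, start, end, strand in records:
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"read on {chrom} has start {start} >= end {end}")
            s = 1 if strand in ("+", 1, "1") else -1
            if layout is not None:
                if chrom not in layout._index:
                    raise KeyError(f"read on unknown chromosome {chrom!r}")
                if end > layout.length(chrom):
                    raise ValueError(
                        f"read {chrom}:{start}-{end} extends beyond chromosome end "
                        f"({layout.length(chrom)})"
                    )
            by_chrom.setdefault(chrom, []).append((start, end, s))
        arrays = {}
        for chrom, recs in by_chrom.items():
            arr = np.array(recs, dtype=np.int64)
            arrays[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls.from_arrays(arrays, dedup=dedup)

    @classmethod
    def from_arrays(cls, arrays, layout: GenomeLayout | None = None,
                    dedup: bool = True) -> "ReadSet":
        """Fast constructor from per-chromosome (starts, ends, strands) arrays.

        ``strands`` is +1/-1. Deduplicates on (start, strand) and sorts by
        start, like :meth:`from_records`.
        """
        intervals = {}
        total = 0
        for chrom, (starts, ends, strands) in arrays.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            strands = np.asarray(strands, dtype=np.int64)
            if layout is not None:
                if chrom not in layout._index:
                    raise KeyError(f"read on unknown chromosome {chrom!r}")
                if len(ends) and ends.max() > layout.length(chrom):
                    raise ValueError(f"read on {chrom} beyond chromosome end")
            # dedup on (start, strand): encode strand in the low bit
            if dedup:
                key = starts * 2 + (strands > 0)
                _, idx = np.unique(key, return_index=True)
            else:
                idx = np.arange(len(starts))
            order = idx[np.argsort(starts[idx], kind="stable")]
            intervals[chrom] = {
                "start": starts[order],
                "end": ends[order],
                "strand": strands[order].astype(np.int8),
            }
            total += len(order)
        return cls(intervals=intervals, total_unique_reads=total)

    def chroms(self) -> list[str]:
        return list(self.intervals)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of unique reads overlapping [start, end)."""
        iv = self.intervals.get(chrom)
        if iv is None:
            return 0
        return int(np.count_nonzero((iv["start"] < end) & (iv["end"] > start)))


@dataclass
class BinnedTrack:
    """Per-bin USHP values with a mask channel.

    ``values`` and ``mask`` are dicts of per-chromosome numpy arrays aligned
    to ``layout``. Mask codes: 0 valid, 1 masked, 2 interpolated,
    3 blacklisted.
    """

    layout: GenomeLayout
    values: dict
    mask: dict
    normalization: str = "raw"  # "raw" | "rpm"
    library_size: int = 0

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            layout=self.layout,
            values={c: v.copy() for c, v in self.values.items()},
            mask={c: m.copy() for c, m in self.mask.items()},
            normalization=self.normalization,
            library_size=self.library_size,
        )

    def genome_mean(self, include=(VALID, INTERPOLATED)) -> float:
        """Mean value over bins whose mask code is in ``include``."""
        tot, n = 0.0, 0
        for chrom in self.layout.names:
            sel = np.isin(self.mask[chrom], include)
            tot += float(self.values[chrom][sel].sum())
            n += int(sel.sum())
        return tot / n if n else 0.0

    @classmethod
    def zeros(cls, layout: GenomeLayout, **kw) -> "BinnedTrack":
        values = {c: np.zeros(layout.n_bins(c)) for c in layout.names}
        mask = {c: np.zeros(layout.n_bins(c), dtype=np.uint8) for c in layout.names}
        return cls(layout=layout, values=values, mask=mask, **kw)


@dataclass
class SlopeTrack:
    """Per-bin USHP slope (USHP units per bp) with a defined flag."""

    layout: GenomeLayout
    slopes: dict
    defined: dict


def bin_coverage(reads: ReadSet, layout: GenomeLayout, summary: str = "mean") -> BinnedTrack:
    """Pile up unique reads per base and summarize per bin.

    The per-bin USHP is the mean per-base pileup depth within the bin
    (``summary="max"`` takes the bin maximum instead). Library size is the
    number of unique reads.
    """
    if summary not in ("mean", "max"):
        raise ValueError(f"summary must be 'mean' or 'max', got {summary!r}")
    track = BinnedTrack.zeros(layout)
    bs = layout.bin_size
    for chrom, iv in reads.intervals.items():
        if chrom not in layout._index:
            raise KeyError(f"reads on unknown chromosome {chrom!r}")
        L = layout.length(chrom)
        if len(iv["start"]) and (iv["end"].max() > L or iv["start"].min() < 0):
            bad = int(iv["end"].max())
            raise ValueError(f"read on {chrom} extends to {bad}, beyond chromosome end {L}")
        diff = np.zeros(L + 1)
        np.add.at(diff, iv["start"], 1.0)
        np.add.at(diff, iv["end"], -1.0)
        pileup = np.cumsum(diff[:-1])
        nb = layout.n_bins(chrom)
        pad = nb * bs - L
        if pad:
            pileup = np.concatenate([pileup, np.full(pad, np.nan)])
        grid = pileup.reshape(nb, bs)
        if summary == "mean":
            track.values[chrom] = np.nanmean(grid, axis=1)
        else:
            track.values[chrom] = np.nanmax(grid, axis=1)
    track.library_size = reads.total_unique_reads
    return track


def normalize_rpm(track: BinnedTrack) -> BinnedTrack:
    """Scale values to reads-per-million: value × 10^6 / library_size."""
    if track.normalization == "rpm":
        raise ValueError("track is already RPM-normalized")
    if track.library_size <= 0:
        raise ValueError("library_size must be positive to normalize")
    out = track.copy()
    factor = 1e6 / track.library_size
    for chrom in out.values:
        out.values[chrom] *= factor
    out.normalization = "rpm"
    return out


def mask_low_mappability(
    track: BinnedTrack,
    mappability: dict,
    threshold: float = 0.5,
    max_signal: float = 0.0,
) -> BinnedTrack:
    """Flag bins with poor alignability and no coverage as masked.

    A bin is masked when its uniqueness score is below ``threshold`` *and*
    its signal is at or below ``max_signal`` (regions of no sequence
    coverage caused by poor mappability, not genuine enrichment).
    """
    out = track.copy()
    for chrom in out.layout.names:
        m = np.asarray(mappability[chrom], dtype=float)
        if m.shape != out.values[chrom].shape:
            raise ValueError(f"mappability for {chrom} has {m.shape[0]} bins, layout expects {out.values[chrom].shape[0]}")
        low = (m < threshold) & (out.values[chrom] <= max_signal) & (out.mask[chrom] == VALID)
        out.mask[chrom][low] = MASKED
    return out


def interpolate_masked(
    track: BinnedTrack,
    scan_distance: int = 3,
    enrichment_fold: float = 2.0,
) -> BinnedTrack:
    """Fill masked gaps that sit inside enriched signal.

    Each maximal run of masked bins is assigned the mean of the nearest
    valid upstream and downstream bins, provided both exist within
    ``scan_distance`` bins of the run edges and at least one of them carries
    signal ≥ ``enrichment_fold`` × the genome-wide mean of valid bins.
    Isolated masked deserts (no valid flank in range) stay masked.
    """
    out = track.copy()
    floor = enrichment_fold * out.genome_mean(include=(VALID,))
    for chrom in out.layout.names:
        mask = out.mask[chrom]
        vals = out.values[chrom]
        n = len(mask)
        i = 0
        while i < n:
            if mask[i] != MASKED:
                i += 1
                continue
            j = i
            while j < n and mask[j] == MASKED:
                j += 1
            # nearest valid bins flanking the run [i, j)
            up = None
            for k in range(i - 1, max(i - 1 - scan_distance, -1), -1):
                if mask[k] == VALID:
                    up = k
                    break
                if mask[k] != MASKED:
                    break
            down = None
            for k in range(j, min(j + scan_distance, n)):
                if mask[k] == VALID:
                    down = k
                    break
                if mask[k] != MASKED:
                    break
            if up is not None and down is not None:
                if max(vals[up], vals[down]) >= floor:
                    fill = 0.5 * (vals[up] + vals[down])
                    vals[i:j] = fill
                    mask[i:j] = INTERPOLATED
            i = j
    return out


def smooth(track: BinnedTrack) -> BinnedTrack:
    """Moving average of a 3-bin (60 bp) window centered on each bin.

    Only valid and interpolated bins contribute; at chromosome ends the
    average runs over the available neighbors rather than zero-padding.
    Masked and blacklisted bins keep their values and flags.
    """
    out = track.copy()
    for chrom in out.layout.names:
        vals = out.values[chrom]
        mask = out.mask[chrom]
        ok = np.isin(mask, (VALID, INTERPOLATED)).astype(float)
        v = vals * ok
        # 3-bin windowed sums of signal and of contributing-bin counts
        ssum = np.convolve(v, np.ones(3), mode="same")
        scnt = np.convolve(ok, np.ones(3), mode="same")
        sm = np.divide(ssum, scnt, out=np.zeros_like(ssum), where=scnt > 0)
        keep = ok.astype(bool)
        vals[keep] = sm[keep]
    return out


def blacklist_input(track: BinnedTrack, input_track: BinnedTrack, fold: float = 10.0) -> BinnedTrack:
    """Flag bins where the input (no-ChIP) track is anomalously deep.

    Bins whose input signal exceeds ``fold`` × the genome-wide input mean
    are blacklisted and excluded from feature detection. Interpreted as
    region removal: the purpose is to drop false-positive peaks over
    artifact regions, not to subtract a background level.
    """
    if input_track.layout != track.layout:
        raise ValueError("input track layout does not match")
    if input_track.normalization != track.normalization:
        raise ValueError("track and input must share a normalization (RPM vs raw)")
    out = track.copy()
    mean = input_track.genome_mean(include=(VALID, INTERPOLATED))
    cut = fold * mean
    for chrom in out.layout.names:
        hot = input_track.values[chrom] > cut
        out.mask[chrom][hot] = BLACKLISTED
    return out


def slope_scores(track: BinnedTrack, offset_bins: int = 3, divisor_bp: float = 100.0) -> SlopeTrack:
    """Per-bin slope: (value 60 bp downstream − value 60 bp upstream) / 100.

    The slope at bin *i* uses the smoothed USHP at bins *i±3*. It is
    undefined within 3 bins of a chromosome end and wherever the ±3-bin
    support window touches a masked (uninterpolated) or blacklisted bin.
    """
    slopes = {}
    defined = {}
    for chrom in track.layout.names:
        vals = track.values[chrom]
        mask = track.mask[chrom]
        n = len(vals)
        s = np.zeros(n)
        d = np.zeros(n, dtype=bool)
        if n > 2 * offset_bins:
            sl = (vals[2 * offset_bins:] - vals[: n - 2 * offset_bins]) / divisor_bp
            s[offset_bins : n - offset_bins] = sl
            bad = ~np.isin(mask, (VALID, INTERPOLATED))
            # window touches a bad bin if any of i-3 .. i+3 is bad
            w = 2 * offset_bins + 1
            touch = np.convolve(bad.astype(int), np.ones(w, dtype=int), mode="same") > 0
            d[offset_bins : n - offset_bins] = ~touch[offset_bins : n - offset_bins]
        slopes[chrom] = s
        defined[chrom] = d
    return SlopeTrack(layout=track.layout, slopes=slopes, defined=defined)


def process_track(
    reads: ReadSet,
    layout: GenomeLayout,
    mappability: dict | None = None,
    input_track: BinnedTrack | None = None,
    rpm: bool = True,
    mappability_threshold: float = 0.5,
    input_fold: float = 10.0,
    do_smooth: bool = True,
) -> BinnedTrack:
    """Standard track pipeline: bin, normalize, mask, interpolate, smooth, blacklist."""
    track = bin_coverage(reads, layout)
    if rpm:
        track = normalize_rpm(track)
    if mappability is not None:
        track = mask_low_mappability(track, mappability, threshold=mappability_threshold)
        track = interpolate_masked(track)
    if do_smooth:
        track = smooth(track)
    if input_track is not None:
        track = blacklist_input(track, input_track, fold=input_fold)
    return track
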