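"""Slope-run RNAPII feature detection.

A feature is a rising-slope region paired with the nearest downstream
falling-slope region. Candidate features are then (1) merged with neighbors
when the peak-to-trough ratio shows they are poorly resolved multiplets of a
single element, (2) filtered against the local RNAPII background, and
(3) filtered on absolute tag support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeLayout
from .tracks import BinnedTrack, ReadSet, SlopeTrack, VALID, INTERPOLATED, slope_scores


@dataclass
class DetectionConfig:
    """Thresholds of the feature-detection algorithm.

    slope_threshold is in USHP units per bp and has no published value.
    The default (None) resolves per track to genome_mean_USHP / 100 — one
    genome-mean of signal change across the slope's 100 bp divisor — a
    scale-free rule calibrated once on the packaged synthetic data (see
    docs). All other defaults are the published constants.
    """

    slope_threshold: float | None = None
    pairing_max_gap: int = 400        # bp between rise end and fall start
    merge_ratio: float = 2.5          # peak-to-trough ratio below which neighbors merge
    neighbor_cluster_gap: int = 2000  # bp between feature centers grouped into one domain
    background_flank: int = 1000      # bp domain expansion for local background
    enrichment_fold: float = 3.5      # max USHP vs local background mean
    min_tags: int = 20                # per-feature unique tag count
    min_density: float = 14.5         # tags per bp (alternative to min_tags)

    def __post_init__(self) -> None:
        for name in ("pairing_max_gap", "merge_ratio",
                     "neighbor_cluster_gap", "background_flank",
                     "enrichment_fold", "min_tags", "min_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.slope_threshold is not None and self.slope_threshold <= 0:
            raise ValueError("slope_threshold must be positive")

    def resolved(self, track: "BinnedTrack") -> "DetectionConfig":
        """Fill the automatic slope threshold from the track's genome mean."""
        if self.slope_threshold is not None:
            return self
        mean = track.genome_mean()
        if mean <= 0:
            return replace(self, slope_threshold=np.inf)
        return replace(self, slope_threshold=mean / 100.0)


@dataclass
class SlopeRun:
    chrom: str
    start_bin: int  # half-open bin range
    end_bin: int
    sign: int  # +1 rising, -1 falling
    extremum_slope: float


@dataclass
class RNAPIIFeature:
    chrom: str
    start: int  # bp, half-open
    end: int
    summit_bin: int = -1
    max_ushp: float = 0.0
    tag_count: int = 0
    tag_density: float = 0.0
    merged_from: list = field(default_factory=list)
    status: str = "candidate"
    id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)

    def summit_bp(self, bin_size: int = 20) -> int:
        """Summit position in bp (center of the summit bin)."""
        return self.summit_bin * bin_size + bin_size // 2


def find_slope_runs(slopes: SlopeTrack, config: DetectionConfig) -> list[SlopeRun]:
    """Maximal runs of consecutive defined bins beyond ±slope_threshold."""
    thr = config.slope_threshold
    if thr is None or thr <= 0:
        raise ValueError("slope_threshold must be a positive number (use "
                         "DetectionConfig.resolved(track) for the automatic rule)")
    runs: list[SlopeRun] = []
    for chrom in slopes.layout.names:
        s = slopes.slopes[chrom]
        d = slopes.defined[chrom]
        state = np.zeros(len(s), dtype=np.int8)
        state[d & (s > thr)] = 1
        state[d & (s < -thr)] = -1
        # boundaries of constant nonzero runs
        idx = np.flatnonzero(np.diff(np.concatenate([[0], state, [0]])))
        for a, b in zip(idx[:-1], idx[1:]):
            sign = int(state[a])
            if sign == 0:
                continue
            seg = s[a:b]
            ext = float(seg.max()) if sign > 0 else float(seg.min())
            runs.append(SlopeRun(chrom, int(a), int(b), sign, ext))
    return runs


def pair_runs(runs: list[SlopeRun], config: DetectionConfig, layout: GenomeLayout) -> list[RNAPIIFeature]:
    """Join each rising run to the nearest downstream falling run.

    The gap is measured in bp from the 3' end of the rising run to the 5'
    start of the falling run and must not exceed ``pairing_max_gap``. Each
    falling run is consumed at most once; unpaired runs are discarded.
    """
    bs = layout.bin_size
    features: list[RNAPIIFeature] = []
    by_chrom: dict[str, list[SlopeRun]] = {}
    for r in runs:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: (r.start_bin, r.end_bin))
        pos = [r for r in rs if r.sign > 0]
        neg = [r for r in rs if r.sign < 0]
        used = [False] * len(neg)
        j0 = 0
        for p in pos:
            p_end_bp = p.end_bin * bs
            best = None
            for j in range(j0, len(neg)):
                if used[j]:
                    continue
                n_start_bp = neg[j].start_bin * bs
                if neg[j].start_bin < p.end_bin:
                    continue
                gap = n_start_bp - p_end_bp
                if gap > config.pairing_max_gap:
                    break
                best = j
                break  # sorted: first eligible is the nearest downstream
            if best is not None:
                used[best] = True
                n = neg[best]
                features.append(RNAPIIFeature(
                    chrom=chrom,
                    start=p.start_bin * bs,
                    end=min(n.end_bin * bs, layout.length(chrom)),
                ))
    features.sort(key=lambda f: (f.chrom, f.start, f.end))
    for i, f in enumerate(features):
        f.id = f"{f.chrom}:{f.start}-{f.end}"
    return features


def annotate_signal(features: list[RNAPIIFeature], track: BinnedTrack) -> None:
    """Set summit bin and maximum smoothed USHP from the track (in place)."""
    bs = track.layout.bin_size
    for f in features:
        b0 = f.start // bs
        b1 = max(b0 + 1, -(-f.end // bs))
        vals = track.values[f.chrom][b0:b1]
        k = int(np.argmax(vals))
        f.summit_bin = b0 + k
        f.max_ushp = float(vals[k])


def annotate_tags(features: list[RNAPIIFeature], reads: ReadSet) -> None:
    """Set unique tag count and tag density per feature (in place)."""
    for f in features:
        f.tag_count = reads.count_in(f.chrom, f.start, f.end)
        f.tag_density = f.tag_count / f.length if f.length else 0.0


def merge_multiplets(features: list[RNAPIIFeature], track: BinnedTrack, config: DetectionConfig) -> list[RNAPIIFeature]:
    """Merge adjacent features with a peak-to-trough ratio below merge_ratio.

    Ratio = min(max_left, max_right) / trough, with the trough the minimum
    smoothed USHP between the two summits. A zero trough never merges.
    Left-to-right passes repeat until no pair merges (fixpoint).
    """
    feats = [replace(f, merged_from=list(f.merged_from) or [f.id]) for f in features]
    annotate_signal(feats, track)
    feats.sort(key=lambda f: (f.chrom, f.start, f.end))
    changed = True
    while changed:
        changed = False
        out: list[RNAPIIFeature] = []
        i = 0
        while i < len(feats):
            f = feats[i]
            if i + 1 < len(feats) and feats[i + 1].chrom == f.chrom:
                g = feats[i + 1]
                lo, hi = min(f.summit_bin, g.summit_bin), max(f.summit_bin, g.summit_bin)
                between = track.values[f.chrom][lo + 1 : hi]
                if between.size == 0:
                    between = track.values[f.chrom][lo : hi + 1]
                trough = float(between.min())
                ratio = np.inf if trough <= 0 else min(f.max_ushp, g.max_ushp) / trough
                if ratio < config.merge_ratio:
                    merged = RNAPIIFeature(
                        chrom=f.chrom, start=f.start, end=max(f.end, g.end),
                        merged_from=f.merged_from + g.merged_from,
                        id=f"{f.chrom}:{f.start}-{max(f.end, g.end)}",
                    )
                    annotate_signal([merged], track)
                    feats[i + 1] = merged
                    changed = True
                    i += 1
                    continue
            out.append(f)
            i += 1
        feats = out
    return feats


def local_background_filter(features: list[RNAPIIFeature], track: BinnedTrack, config: DetectionConfig) -> list[RNAPIIFeature]:
    """Require the feature maximum to clear the local background.

    Features whose centers lie within ``neighbor_cluster_gap`` are grouped
    into a domain; the domain is expanded by ``background_flank`` on each
    side; the background is the mean smoothed USHP over valid/interpolated
    domain bins not covered by any feature. A feature passes iff
    max_ushp ≥ enrichment_fold × background mean.
    """
    bs = track.layout.bin_size
    feats = sorted(features, key=lambda f: (f.chrom, f.start, f.end))
    out: list[RNAPIIFeature] = []
    by_chrom: dict[str, list[RNAPIIFeature]] = {}
    for f in feats:
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom, fs in by_chrom.items():
        nb = track.layout.n_bins(chrom)
        # bins covered by any feature on this chromosome
        peak_bins = np.zeros(nb, dtype=bool)
        for f in fs:
            peak_bins[f.start // bs : -(-f.end // bs)] = True
        usable = np.isin(track.mask[chrom], (VALID, INTERPOLATED))
        # chain features into domains by center distance
        groups: list[list[RNAPIIFeature]] = []
        for f in fs:
            if groups and f.center - groups[-1][-1].center <= config.neighbor_cluster_gap:
                groups[-1].append(f)
            else:
                groups.append([f])
        for grp in groups:
            d0 = max(0, min(f.start for f in grp) - config.background_flank)
            d1 = min(track.layout.length(chrom), max(f.end for f in grp) + config.background_flank)
            b0, b1 = d0 // bs, -(-d1 // bs)
            sel = ~peak_bins[b0:b1] & usable[b0:b1]
            vals = track.values[chrom][b0:b1][sel]
            if vals.size == 0:
                warnings.warn(
                    f"no non-peak bins in background domain {chrom}:{d0}-{d1}; "
                    "features accepted with undefined background"
                )
                bg = 0.0
            else:
                bg = float(vals.mean())
            for f in grp:
                g = replace(f, merged_from=list(f.merged_from))
                if f.max_ushp >= config.enrichment_fold * bg:
                    g.status = "candidate"
                    out.append(g)
                else:
                    g.status = "background_filtered"
                    out.append(g)
    out.sort(key=lambda f: (f.chrom, f.start, f.end))
    return out


def signal_threshold_filter(features: list[RNAPIIFeature], config: DetectionConfig) -> list[RNAPIIFeature]:
    """Accept features with ≥ min_tags unique tags OR tag density ≥ min_density."""
    out = []
    for f in features:
        g = replace(f, merged_from=list(f.merged_from))
        if g.status == "candidate":
            if g.tag_count >= config.min_tags or g.tag_density >= config.min_density:
                g.status = "accepted"
            else:
                g.status = "signal_filtered"
        out.append(g)
    return out


def detect_track(track: BinnedTrack, reads: ReadSet, config: DetectionConfig | None = None) -> list[RNAPIIFeature]:
    """Full single-track detection; returns all features with final statuses.

    ``track`` must already be masked/interpolated/smoothed (see
    :func:`polprime.tracks.process_track`).
    """
    config = (config or DetectionConfig()).resolved(track)
    slopes = slope_scores(track)
    runs = find_slope_runs(slopes, config)
    feats = pair_runs(runs, config, track.layout)
    feats = merge_multiplets(feats, track, config)
    feats = local_background_filter(feats, track, config)
    annotate_tags(feats, reads)
    feats = signal_threshold_filter(feats, config)
    return feats


@dataclass
class FeatureSet:
    """Per-track accepted features plus their coordinate-merged union."""

    per_track: dict
    union: list  # of RNAPIIFeature with merged_from = contributing track labels


def union_features(per_track: dict) -> list[RNAPIIFeature]:
    """Coordinate-merge accepted features across tracks, keeping provenance."""
    items = []
    for label, feats in per_track.items():
        for f in feats:
            if f.status == "accepted":
                items.append((f.chrom, f.start, f.end, label, f))
    items.sort(key=lambda t: (t[0], t[1], t[2]))
    union: list[RNAPIIFeature] = []
    for chrom, start, end, label, f in items:
        if union and union[-1].chrom == chrom and start < union[-1].end:
            u = union[-1]
            u.end = max(u.end, end)
            if label not in u.merged_from:
                u.merged_from.append(label)
            if f.max_ushp > u.max_ushp:
                u.max_ushp = f.max_ushp
                u.summit_bin = f.summit_bin
            u.id = f"{u.chrom}:{u.start}-{u.end}"
        else:
            union.append(RNAPIIFeature(
                chrom=chrom, start=start, end=end, summit_bin=f.summit_bin,
                max_ushp=f.max_ushp, merged_from=[label], status="accepted",
                id=f"{chrom}:{start}-{end}",
            ))
    return union


def detect(per_condition: dict, config: DetectionConfig | None = None) -> FeatureSet:
    """Detect features per condition and build the union set.

    ``per_condition`` maps a condition label to ``(processed_track, reads)``.
    """
    config = config or DetectionConfig()
    per_track = {label: detect_track(track, reads, config) for label, (track, reads) in per_condition.items()}
    accepted = {label: [f for f in feats if f.status == "accepted"] for label, feats in per_track.items()}
    return FeatureSet(per_track=per_track, union=union_features(accepted))
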