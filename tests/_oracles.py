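"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over the stated rules, with no
shared code paths with the package (beyond reading its data containers).
"""

from __future__ import annotations

import itertools
import math


def pileup_oracle(reads, chrom_length):
    """Per-base pileup from (start, end) pairs by explicit iteration."""
    depth = [0] * chrom_length
    for start, end in reads:
        for pos in range(start, end):
            depth[pos] += 1
    return depth


def binned_mean_oracle(depth, bin_size):
    """Per-bin mean of a per-base depth list (last bin may be partial)."""
    out = []
    for b0 in range(0, len(depth), bin_size):
        chunk = depth[b0 : b0 + bin_size]
        out.append(sum(chunk) / len(chunk))
    return out


def smooth_oracle(values):
    """3-bin moving average, averaging only available neighbors at the ends."""
    n = len(values)
    out = []
    for i in range(n):
        window = [values[j] for j in range(max(0, i - 1), min(n, i + 2))]
        out.append(sum(window) / len(window))
    return out


def hypergeom_tail_enumeration(k, n, K, N):
    """P(X >= k) by enumerating all C(N, n) draws from N items, K marked."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def overlap_count_oracle(feature, reads):
    """O(n) interval-overlap count: reads (start, end) hitting [fs, fe)."""
    fs, fe = feature
    return sum(1 for s, e in reads if s < fe and e > fs)


# ---------------------------------------------------------------------------
# Brute-force re-statement of the full feature-detection rule set.
# Operates on a processed BinnedTrack + ReadSet, entirely with Python loops.

VALID, MASKED, INTERPOLATED, BLACKLISTED = 0, 1, 2, 3


def detect_oracle(track, reads, config):
    """All features with final statuses, per the detection rules.

    config must have a concrete slope_threshold (resolve it first).
    """
    bs = track.layout.bin_size
    all_feats = []
    for chrom in track.layout.names:
        vals = list(track.values[chrom])
        mask = list(track.mask[chrom])
        L = track.layout.length(chrom)
        n = len(vals)

        # slopes
        slope = [0.0] * n
        defined = [False] * n
        for i in range(3, n - 3):
            slope[i] = (vals[i + 3] - vals[i - 3]) / 100.0
            ok = True
            for j in range(i - 3, i + 4):
                if mask[j] in (MASKED, BLACKLISTED):
                    ok = False
            defined[i] = ok

        # maximal threshold runs
        runs = []  # (start_bin, end_bin, sign)
        i = 0
        while i < n:
            if defined[i] and slope[i] > config.slope_threshold:
                sign = 1
            elif defined[i] and slope[i] < -config.slope_threshold:
                sign = -1
            else:
                i += 1
                continue
            j = i
            while j < n and defined[j] and (
                (sign > 0 and slope[j] > config.slope_threshold)
                or (sign < 0 and slope[j] < -config.slope_threshold)
            ):
                j += 1
            runs.append((i, j, sign))
            i = j

        # pair each rising run with nearest downstream falling run
        pos_runs = [r for r in runs if r[2] > 0]
        neg_runs = [r for r in runs if r[2] < 0]
        consumed = set()
        feats = []  # dicts
        for ps, pe, _ in pos_runs:
            for idx, (ns, ne, _) in enumerate(neg_runs):
                if idx in consumed or ns < pe:
                    continue
                gap = ns * bs - pe * bs
                if gap > config.pairing_max_gap:
                    break
                consumed.add(idx)
                feats.append({"start": ps * bs, "end": min(ne * bs, L)})
                break
        feats.sort(key=lambda f: (f["start"], f["end"]))

        def annotate(f):
            b0 = f["start"] // bs
            b1 = max(b0 + 1, math.ceil(f["end"] / bs))
            best, arg = None, b0
            for b in range(b0, b1):
                if best is None or vals[b] > best:
                    best, arg = vals[b], b
            f["summit"], f["max"] = arg, best

        for f in feats:
            annotate(f)

        # merge poorly resolved multiplets to fixpoint, left to right
        changed = True
        while changed:
            changed = False
            out = []
            i = 0
            while i < len(feats):
                f = feats[i]
                if i + 1 < len(feats):
                    g = feats[i + 1]
                    lo, hi = min(f["summit"], g["summit"]), max(f["summit"], g["summit"])
                    between = vals[lo + 1 : hi] or vals[lo : hi + 1]
                    trough = min(between)
                    if trough > 0 and min(f["max"], g["max"]) / trough < config.merge_ratio:
                        merged = {"start": f["start"], "end": max(f["end"], g["end"])}
                        annotate(merged)
                        feats[i + 1] = merged
                        changed = True
                        i += 1
                        continue
                out.append(f)
                i += 1
            feats = out

        # local background: chain features into domains by center distance
        peak_bins = set()
        for f in feats:
            for b in range(f["start"] // bs, math.ceil(f["end"] / bs)):
                peak_bins.add(b)
        groups = []
        for f in feats:
            center = (f["start"] + f["end"]) / 2
            if groups and center - (groups[-1][-1]["start"] + groups[-1][-1]["end"]) / 2 <= config.neighbor_cluster_gap:
                groups[-1].append(f)
            else:
                groups.append([f])
        for grp in groups:
            d0 = max(0, min(f["start"] for f in grp) - config.background_flank)
            d1 = min(L, max(f["end"] for f in grp) + config.background_flank)
            bg_vals = []
            for b in range(d0 // bs, math.ceil(d1 / bs)):
                if b not in peak_bins and mask[b] in (VALID, INTERPOLATED):
                    bg_vals.append(vals[b])
            bg = sum(bg_vals) / len(bg_vals) if bg_vals else 0.0
            for f in grp:
                f["status"] = ("candidate" if f["max"] >= config.enrichment_fold * bg
                               else "background_filtered")

        # tag support
        read_list = []
        iv = reads.intervals.get(chrom)
        if iv is not None:
            read_list = list(zip((int(x) for x in iv["start"]), (int(x) for x in iv["end"])))
        for f in feats:
            tags = overlap_count_oracle((f["start"], f["end"]), read_list)
            density = tags / (f["end"] - f["start"])
            if f["status"] == "candidate":
                f["status"] = ("accepted" if tags >= config.min_tags or density >= config.min_density
                               else "signal_filtered")
            f["chrom"] = chrom
        all_feats.extend(feats)
    return sorted(
        [(f["chrom"], f["start"], f["end"], f["status"]) for f in all_feats]
    )
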