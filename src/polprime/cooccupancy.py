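"""Peak-set overlap, hypergeometric co-occupancy enrichment, anchored density
matrices, and in vitro cistromics (IVC) titration analysis.

The enrichment question: given N RNAPII features of which K overlap a
factor's peaks genome-wide, is a cluster of n features with k overlaps
enriched? Answered with the upper-tail hypergeometric probability.

The IVC analysis classifies binding sites across an ascending protein
titration by reads-per-million (RPM) thresholds: detected at ≥ 1 RPM,
co-bound when ≥ 0.5 RPM at every concentration, gained when detected only
at the top of the titration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class PeakSet:
    """Sorted peaks with summits and RPM strengths."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    summits: np.ndarray
    strengths: np.ndarray
    label: str = ""

    @classmethod
    def from_records(cls, records, label: str = "") -> "PeakSet":
        """records: iterable of (chrom, start, end, summit, strength)."""
        recs = sorted(records, key=lambda r: (r[0], int(r[1]), int(r[2])))
        if any(float(r[4]) < 0 for r in recs):
            raise ValueError("peak strengths must be non-negative")
        return cls(
            chroms=np.array([r[0] for r in recs], dtype=object),
            starts=np.array([int(r[1]) for r in recs]),
            ends=np.array([int(r[2]) for r in recs]),
            summits=np.array([int(r[3]) for r in recs]),
            strengths=np.array([float(r[4]) for r in recs]),
            label=label,
        )

    def __len__(self) -> int:
        return len(self.starts)


def overlap_fraction(a: PeakSet, b: PeakSet, window: int = 200,
                     mode: str = "summit") -> tuple[float, np.ndarray]:
    """Fraction of a's peaks co-localized with b.

    mode="summit": an a-peak counts when its summit lies within ``window``
    bp of some b summit (order-sensitive by design). mode="any": intervals
    simply overlap. Returns (fraction, per-peak boolean flags over a).
    """
    flags = np.zeros(len(a), dtype=bool)
    for chrom in np.unique(a.chroms):
        ia = np.flatnonzero(a.chroms == chrom)
        ib = np.flatnonzero(b.chroms == chrom)
        if ib.size == 0:
            continue
        if mode == "summit":
            bs = np.sort(b.summits[ib])
            pos = a.summits[ia]
            j = np.searchsorted(bs, pos)
            near = np.zeros(len(ia), dtype=bool)
            for off in (0, -1):
                k = np.clip(j + off, 0, len(bs) - 1)
                near |= np.abs(bs[k] - pos) <= window
            flags[ia] = near
        elif mode == "any":
            starts_b = b.starts[ib]
            ends_b = b.ends[ib]
            for t, i in enumerate(ia):
                flags[i] = bool(np.any((starts_b < a.ends[i]) & (ends_b > a.starts[i])))
        else:
            raise ValueError(f"unknown overlap mode {mode!r}")
    frac = float(flags.mean()) if len(a) else 0.0
    return frac, flags


@dataclass
class EnrichmentResult:
    cluster: str
    overlap_count: int   # k
    cluster_size: int    # n
    genome_wide_overlaps: int  # K
    population: int      # N
    p_value: float


def hypergeom_enrichment(k: int, n: int, K: int, N: int, cluster: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric probability P(X ≥ k).

    X ~ Hypergeometric(N population, K marked, n drawn).
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(cluster, k, n, K, N, min(1.0, max(0.0, p)))


def cluster_enrichment(cluster_labels: pd.Series, overlap_flags: pd.Series,
                       correct: bool = False) -> pd.DataFrame:
    """Per-cluster co-occupancy enrichment vs the genome-wide rate.

    ``cluster_labels`` and ``overlap_flags`` are aligned per-feature series.
    Raw upper-tail p-values by default; Benjamini–Hochberg adjusted column
    added when ``correct``.
    """
    labels = cluster_labels.reindex(overlap_flags.index)
    N = len(labels)
    K = int(overlap_flags.sum())
    rows = []
    for cl, idx in labels.groupby(labels).groups.items():
        n = len(idx)
        k = int(overlap_flags.loc[idx].sum())
        r = hypergeom_enrichment(k, n, K, N, cluster=str(cl))
        rows.append({"cluster": r.cluster, "k": r.overlap_count, "n": r.cluster_size,
                     "K": r.genome_wide_overlaps, "N": r.population, "p_value": r.p_value})
    df = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    if correct and len(df):
        df["p_adj_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


@dataclass
class DensityMatrix:
    values: np.ndarray       # anchors × position bins
    flank: int
    bin: int
    flagged: np.ndarray      # rows padded at a chromosome end

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def density_matrix(anchors, track, flank: int = 2000, bin: int = 20,
                   cap: float | None = None) -> DensityMatrix:
    """Signal sampled in fixed bins across [summit−flank, summit+flank).

    ``anchors`` is a list of (chrom, summit_bp); rows follow the supplied
    order (no re-sorting — the caller controls ordering for heat maps).
    Rows reaching past a chromosome end are padded with NaN and flagged.
    ``cap`` saturates values for display scaling.
    """
    if 2 * flank % bin:
        raise ValueError("2*flank must be a multiple of bin")
    ncol = 2 * flank // bin
    bs = track.layout.bin_size
    if bin % bs:
        raise ValueError(f"sampling bin {bin} must be a multiple of track bin {bs}")
    step = bin // bs
    out = np.full((len(anchors), ncol), np.nan)
    flagged = np.zeros(len(anchors), dtype=bool)
    for i, (chrom, summit) in enumerate(anchors):
        nb = track.layout.n_bins(chrom)
        c = summit // bs
        b0 = c - flank // bs
        b1 = c + flank // bs
        lo, hi = max(b0, 0), min(b1, nb)
        if lo != b0 or hi != b1:
            flagged[i] = True
        vals = track.values[chrom][lo:hi]
        row = np.full(b1 - b0, np.nan)
        row[lo - b0 : hi - b0] = vals
        out[i] = np.nanmean(row.reshape(ncol, step), axis=1) if step > 1 else row
    if cap is not None:
        out = np.minimum(out, cap)
    return DensityMatrix(values=out, flank=flank, bin=bin, flagged=flagged)


@dataclass
class TitrationSeries:
    """Shared sites scored (RPM) across an ascending protein titration."""

    concentrations: list          # ordered labels or numeric concentrations
    site_ids: list
    rpm: np.ndarray               # sites × concentrations
    detect_threshold: float = 1.0
    cobound_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.rpm = np.asarray(self.rpm, dtype=float)
        if len(self.concentrations) < 2:
            raise ValueError("a titration needs at least 2 concentrations")
        conc = [float(c) for c in self.concentrations]
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly ascending")
        if self.rpm.shape != (len(self.site_ids), len(self.concentrations)):
            raise ValueError("rpm shape does not match sites × concentrations")


def titration_analysis(series: TitrationSeries) -> pd.DataFrame:
    """Classify each site across the titration and count detections.

    Per site: detected at a concentration iff RPM ≥ detect_threshold (1);
    co-bound iff RPM ≥ cobound_threshold (0.5) at *every* concentration;
    gained iff below detect_threshold at all lower concentrations and at or
    above it at the top concentration. Returns a per-site frame; counts per
    concentration are in ``frame.attrs["detected_counts"]``.
    """
    det = series.rpm >= series.detect_threshold
    cobound = (series.rpm >= series.cobound_threshold).all(axis=1)
    gained = (~det[:, :-1]).all(axis=1) & det[:, -1]
    cls = np.where(cobound, "co_bound", np.where(gained, "gained", "other"))
    df = pd.DataFrame({
        "site": series.site_ids,
        "classification": cls,
        **{f"detected_{c}": det[:, j] for j, c in enumerate(series.concentrations)},
    })
    df.attrs["detected_counts"] = {c: int(det[:, j].sum()) for j, c in enumerate(series.concentrations)}
    return df


def rank_extremes(peaks: PeakSet, n: int = 1000) -> tuple[PeakSet, PeakSet]:
    """Strongest-n and weakest-n peaks by strength; ties broken by coordinate."""
    if n > len(peaks):
        raise ValueError(f"n={n} exceeds peak count {len(peaks)}")
    order = np.lexsort((np.arange(len(peaks)), -peaks.strengths))
    strongest = order[:n]
    order_w = np.lexsort((np.arange(len(peaks)), peaks.strengths))
    weakest = order_w[:n]

    def subset(idx, label):
        idx = np.sort(idx)
        return PeakSet(peaks.chroms[idx], peaks.starts[idx], peaks.ends[idx],
                       peaks.summits[idx], peaks.strengths[idx], label=label)

    return subset(strongest, f"{peaks.label}_strongest{n}"), subset(weakest, f"{peaks.label}_weakest{n}")
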