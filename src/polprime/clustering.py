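"""Condition-response quantification and clustering of RNAPII features.

Tag counts per feature are measured across the four experimental tracks
(LD, LD+DMI, HD, HD+DMI), library-size normalized, assigned twofold
up/no-change/down attributes per pairwise comparison, grouped into stage
classes, k-means clustered, and expressed as log2 fold changes relative to
the per-feature mean for heat maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

CONDITIONS = ("LD", "LD_DMI", "HD", "HD_DMI")

UP, NC, DOWN = "up", "nc", "down"


@dataclass
class ConditionMatrix:
    """Features × conditions normalized tag counts."""

    feature_ids: list
    conditions: tuple
    counts: np.ndarray  # shape (n_features, n_conditions)
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.feature_ids), len(self.conditions)):
            raise ValueError("counts shape does not match ids × conditions")
        if (self.counts < 0).any():
            raise ValueError("tag counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=list(self.conditions))


def count_feature_tags(features, readsets: dict, scale_to: float = 1e6, conditions=CONDITIONS) -> ConditionMatrix:
    """Per-feature tag counts across condition read sets, library-scaled.

    Counts are unique reads overlapping the feature interval, multiplied by
    ``scale_to / library_size`` (RPM-style common scale).
    """
    missing = [c for c in conditions if c not in readsets]
    if missing:
        raise KeyError(f"missing condition read sets: {missing}")
    ids = [f.id for f in features]
    counts = np.zeros((len(features), len(conditions)))
    for j, cond in enumerate(conditions):
        rs = readsets[cond]
        if rs.total_unique_reads <= 0:
            raise ValueError(f"condition {cond} has an empty read set")
        factor = scale_to / rs.total_unique_reads
        for i, f in enumerate(features):
            counts[i, j] = rs.count_in(f.chrom, f.start, f.end) * factor
    return ConditionMatrix(feature_ids=ids, conditions=tuple(conditions), counts=counts)


def pairwise_comparisons(conditions=CONDITIONS) -> list[tuple[str, str]]:
    """All 6 ordered pairs (a, b) with a before b in the condition order."""
    return [(conditions[i], conditions[j])
            for i in range(len(conditions)) for j in range(i + 1, len(conditions))]


def assign_attributes(matrix: ConditionMatrix, fold: float = 2.0) -> pd.DataFrame:
    """Twofold up / no-change / down attribute per pairwise comparison.

    For pair (a, b): up if (b+pc)/(a+pc) ≥ fold, down if ≤ 1/fold, else nc.
    Returns a DataFrame indexed by feature id with one column per pair
    ("a_vs_b").
    """
    pc = matrix.pseudocount
    if pc <= 0:
        raise ValueError("pseudocount must be positive")
    cols = {}
    cidx = {c: i for i, c in enumerate(matrix.conditions)}
    for a, b in pairwise_comparisons(matrix.conditions):
        ratio = (matrix.counts[:, cidx[b]] + pc) / (matrix.counts[:, cidx[a]] + pc)
        attr = np.where(ratio >= fold, UP, np.where(ratio <= 1.0 / fold, DOWN, NC))
        cols[f"{a}_vs_{b}"] = attr
    return pd.DataFrame(cols, index=matrix.feature_ids)


# Stage groups: how a feature responds to density (LD vs HD) and to the
# adipogenic cocktail at high density (HD vs HD+DMI). The mapping is the
# editable two-level logic: DMI induction trumps, then density direction.
STAGE_UNCOMMITTED = "uncommitted"
STAGE_HD_PRIMED = "HD_primed"
STAGE_DMI_INDUCED = "DMI_induced"
STAGE_AMBIGUOUS = "ambiguous"

DEFAULT_STAGE_RULES = (
    # (density attr LD_vs_HD, DMI attr HD_vs_HD_DMI) -> stage
    ((None, UP), STAGE_DMI_INDUCED),
    ((UP, None), STAGE_HD_PRIMED),
    ((DOWN, None), STAGE_UNCOMMITTED),
)


def group_stage(attributes: pd.DataFrame, rules=DEFAULT_STAGE_RULES) -> pd.Series:
    """Map attribute vectors to stage groups.

    Rules are checked in order against (LD_vs_HD, HD_vs_HD_DMI); ``None``
    is a wildcard. Features matching no rule are ambiguous. The default
    table: DMI-responsive at HD → DMI_induced; density-up → HD_primed;
    density-down → uncommitted.
    """
    density = attributes["LD_vs_HD"]
    dmi = attributes["HD_vs_HD_DMI"]
    out = pd.Series(STAGE_AMBIGUOUS, index=attributes.index, dtype=object, name="stage")
    assigned = pd.Series(False, index=attributes.index)
    for (want_density, want_dmi), stage in rules:
        sel = ~assigned
        if want_density is not None:
            sel &= density == want_density
        if want_dmi is not None:
            sel &= dmi == want_dmi
        out[sel] = stage
        assigned |= sel
    return out


@dataclass
class ClusterAssignment:
    labels: pd.Series  # feature id -> 1..k
    k: int
    seed: int
    inertia: float


def log2_heatmap(matrix: ConditionMatrix) -> pd.DataFrame:
    """log2((count + pc) / (row mean + pc)) per feature × condition."""
    pc = matrix.pseudocount
    row_mean = matrix.counts.mean(axis=1, keepdims=True)
    vals = np.log2((matrix.counts + pc) / (row_mean + pc))
    return pd.DataFrame(vals, index=matrix.feature_ids, columns=list(matrix.conditions))


def kmeans_cluster(matrix: ConditionMatrix, k: int, seed: int = 0,
                   max_iter: int = 300, tol: float = 1e-6) -> ClusterAssignment:
    """k-means (k-means++ init, fixed seed) on log2 fold-change rows."""
    X = log2_heatmap(matrix).to_numpy()
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of features ({X.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed,
                max_iter=max_iter, tol=tol)
    raw = km.fit_predict(X)
    labels = pd.Series(raw + 1, index=matrix.feature_ids, name="cluster")
    return ClusterAssignment(labels=labels, k=k, seed=seed, inertia=float(km.inertia_))


def write_cdt(heatmap: pd.DataFrame, path) -> None:
    """Clustered-data-table text export (TreeView-compatible layout)."""
    with open(path, "w") as fh:
        fh.write("UID\tNAME\tGWEIGHT\t" + "\t".join(heatmap.columns) + "\n")
        fh.write("EWEIGHT\t\t\t" + "\t".join("1" for _ in heatmap.columns) + "\n")
        for uid, row in heatmap.iterrows():
            fh.write(f"{uid}\t{uid}\t1\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
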