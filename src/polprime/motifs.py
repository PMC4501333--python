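"""IUPAC consensus motif scanning and motif-window selection.

The screen distinguishes the hybrid C/EBP|ATF4 8-mer (TTKCATCA) — a C/EBP
half-site fused to an AP-1-like half-site, bound by the C/EBPβ-ATF4
heterodimer — from the palindromic canonical C/EBP motif (TTGCNNAA) bound by
C/EBP homodimers. Scanning is consensus-string based (both strands), not
PWM-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC consensus string with a name."""

    iupac: str
    name: str

    def __post_init__(self) -> None:
        pat = self.iupac.upper()
        if not pat:
            raise ValueError("empty motif pattern")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters in pattern: {sorted(bad)}")
        object.__setattr__(self, "iupac", pat)

    def __len__(self) -> int:
        return len(self.iupac)

    def regex(self) -> re.Pattern:
        return re.compile("".join(f"[{IUPAC[c]}]" for c in self.iupac))

    def regex_rc(self) -> re.Pattern:
        rc = reverse_complement(self.iupac)
        return re.compile("".join(f"[{IUPAC[c]}]" for c in rc))

    def match_probability(self) -> float:
        """Per-position single-strand match probability on uniform i.i.d. DNA."""
        p = 1.0
        for c in self.iupac:
            p *= len(IUPAC[c]) / 4.0
        return p


HYBRID = MotifPattern("TTKCATCA", "hybrid")
CANONICAL = MotifPattern("TTGCNNAA", "canonical")
HETERODIMER = MotifPattern("TTRSATCA", "heterodimer")

BUILTIN_PATTERNS = {p.name: p for p in (HYBRID, CANONICAL, HETERODIMER)}


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int  # 0-based position of the match's left edge on the + strand
    strand: str
    matched_sequence: str
    pattern: str


def scan_motif(sequence: str, pattern: MotifPattern, chrom: str = "",
               both_strands: bool = True) -> list[MotifHit]:
    """All matches of the consensus on the forward strand and, by default,
    of its reverse complement (reported on the − strand at the same left
    coordinate).

    An N in the sequence (unknown base) matches no pattern position, so
    runs of Ns can never produce hits.
    Self-complementary hits whose + and − spans coincide are reported once
    on the + strand.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid sequence letters: {sorted(bad)}")
    hits = []
    fwd_starts = set()
    rx = pattern.regex()
    for m in _finditer_overlapping(rx, seq):
        hits.append(MotifHit(chrom, m, "+", seq[m:m + len(pattern)], pattern.name))
        fwd_starts.add(m)
    if both_strands:
        rrx = pattern.regex_rc()
        for m in _finditer_overlapping(rrx, seq):
            if m in fwd_starts:
                continue  # palindromic span already reported on +
            hits.append(MotifHit(chrom, m, "-", seq[m:m + len(pattern)], pattern.name))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _finditer_overlapping(rx: re.Pattern, seq: str) -> list[int]:
    out = []
    pos = 0
    while True:
        m = rx.search(seq, pos)
        if m is None:
            return out
        out.append(m.start())
        pos = m.start() + 1


def classify_region(sequence: str, patterns=(HYBRID, CANONICAL)) -> str:
    """Classify by presence of each pattern: hybrid_only / canonical_only /
    both / none (pattern names generalize for other pairs)."""
    present = [p.name for p in patterns if scan_motif(sequence, p)]
    if len(present) == len(patterns) and len(patterns) > 1:
        return "both"
    if not present:
        return "none"
    return f"{present[0]}_only" if len(patterns) > 1 else present[0]


def motif_distance(a: str, b: str) -> int:
    """Hamming distance between two concrete, equal-length DNA strings."""
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    for s in (a, b):
        bad = set(s) - set("ACGT")
        if bad:
            raise ValueError(f"non-concrete bases: {sorted(bad)}")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Motif-mining window selection


@dataclass
class MotifWindow:
    feature_id: str
    chrom: str
    start: int
    end: int
    source: str  # expanded_to_min | natural | merged

    @property
    def length(self) -> int:
        return self.end - self.start


def select_window(feature, track, min_size: int = 400, max_size: int = 600,
                  percentile: float = 75.0) -> MotifWindow | None:
    """Window around a feature's top-quartile USHP bins, 400–600 bp.

    Bins within the feature at or above the within-feature 75th percentile
    (nearest-rank) define a span; spans longer than ``max_size`` exclude the
    feature (returns None); shorter spans are symmetrically expanded to
    ``min_size``, clipped at chromosome ends.
    """
    bs = track.layout.bin_size
    b0 = feature.start // bs
    b1 = max(b0 + 1, -(-feature.end // bs))
    vals = track.values[feature.chrom][b0:b1]
    if vals.size < 1:
        raise ValueError(f"feature {feature.id} shorter than one bin")
    cut = _nearest_rank_percentile(vals, percentile)
    top = np.flatnonzero(vals >= cut)
    span_start = (b0 + int(top[0])) * bs
    span_end = (b0 + int(top[-1]) + 1) * bs
    span = span_end - span_start
    if span > max_size:
        return None
    if span >= min_size:
        return MotifWindow(feature.id, feature.chrom, span_start, span_end, "natural")
    mid = (span_start + span_end) // 2
    half = min_size // 2
    L = track.layout.length(feature.chrom)
    start = max(0, mid - half)
    end = min(L, start + min_size)
    start = max(0, end - min_size)
    return MotifWindow(feature.id, feature.chrom, start, end, "expanded_to_min")


def _nearest_rank_percentile(vals: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: value at rank ceil(q/100 * n) of sorted vals."""
    srt = np.sort(vals)
    rank = max(1, int(np.ceil(q / 100.0 * len(srt))))
    return float(srt[rank - 1])


def merge_windows(windows: list[MotifWindow]) -> list[MotifWindow]:
    """Merge overlapping windows across features into single intervals."""
    ws = sorted(windows, key=lambda w: (w.chrom, w.start, w.end))
    out: list[MotifWindow] = []
    for w in ws:
        if out and out[-1].chrom == w.chrom and w.start < out[-1].end:
            prev = out[-1]
            out[-1] = MotifWindow(f"{prev.feature_id}+{w.feature_id}", w.chrom,
                                  prev.start, max(prev.end, w.end), "merged")
        else:
            out.append(w)
    return out


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def cluster_motif_frequency(windows_by_group: dict, genome: dict, pattern: MotifPattern,
                            level: float = 0.95):
    """Fraction of each group's windows containing ≥1 hit, with exact CI.

    ``genome`` maps chromosome name to sequence (string or pyfaidx record).
    Returns a dict group -> (fraction, n, (ci_lo, ci_hi)); empty groups map
    to None.
    """
    out = {}
    for group, windows in windows_by_group.items():
        if not windows:
            out[group] = None
            continue
        k = 0
        for w in windows:
            seq = str(genome[w.chrom][w.start:w.end])
            if len(seq) < w.end - w.start:
                raise ValueError(f"window {w.chrom}:{w.start}-{w.end} beyond chromosome end")
            if scan_motif(seq, pattern, chrom=w.chrom):
                k += 1
        n = len(windows)
        out[group] = (k / n, n, exact_binomial_ci(k, n, level))
    return out
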