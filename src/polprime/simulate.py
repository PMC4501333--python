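"""Synthetic data with full ground truth for the RNAPII pipeline.

The generator emulates the structure of a four-condition RNAPII ChIP-seq
experiment (LD, LD+DMI, HD, HD+DMI): a random genome with planted motif
instances, a uniqueness/mappability track with planted gaps, per-condition
stranded read sets with planted enhancer peaks whose intensities follow a
stage pattern, an input (no-ChIP) track with planted artifact regions, and
an in vitro titration series driven by a simple occupancy law.

Everything is a pure function of (spec, seed); randomness comes from
numpy's PCG64 generator so outputs are byte-identical across runs.
The titration occupancy model c/(c+Kd) is generator machinery for testing
the classification logic, not a fitted binding model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .tracks import ReadSet
from .clustering import CONDITIONS
from .cooccupancy import TitrationSeries
from .motifs import IUPAC, MotifPattern, reverse_complement, HYBRID, CANONICAL

STAGE_MULTIPLIERS = {
    # per-condition peak enrichment multipliers (LD, LD+DMI, HD, HD+DMI)
    "uncommitted": (8.0, 8.0, 1.0, 1.0),
    "HD_primed": (1.0, 1.0, 8.0, 8.0),
    "DMI_induced": (1.0, 1.0, 1.0, 8.0),
    "ambiguous": (8.0, 8.0, 8.0, 8.0),
}


@dataclass
class PlantedFeature:
    chrom: str
    center: int
    width: int
    multipliers: tuple  # (LD, LD_DMI, HD, HD_DMI)
    stage: str
    motif_class: str = "none"  # hybrid | canonical | none

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.center + self.width // 2


@dataclass
class ReadSimConfig:
    background_rate: float = 0.1   # reads per bp (both strands combined)
    read_length: int = 36
    distribution: str = "poisson"  # poisson | nb
    dispersion: float = 0.3        # NB dispersion (1/size), used when distribution="nb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if self.distribution == "nb" and self.dispersion <= 0:
            raise ValueError("dispersion must be positive for negative binomial")


@dataclass
class SyntheticGenomeSpec:
    lengths: dict            # chrom -> bp
    gc: float = 0.41
    plants: list = field(default_factory=list)  # (chrom, position, iupac_or_concrete, strand)
    seed: int = 0


def _concretize(iupac: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in iupac.upper())


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[dict, pd.DataFrame]:
    """Random genome at the stated GC with motif instances written verbatim.

    Returns (chrom -> sequence string, truth table with one row per plant:
    chrom, start, strand, instance, pattern). Overlapping plants raise.
    """
    rng = np.random.default_rng([spec.seed, 0xC0FFEE])
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    genome = {}
    for chrom, L in spec.lengths.items():
        genome[chrom] = np.frombuffer(b"ACGT", dtype="S1")[
            rng.choice(4, size=L, p=p)
        ].tobytes().decode()
    rows = []
    occupied: dict[str, list] = {c: [] for c in spec.lengths}
    for chrom, pos, pattern, strand in spec.plants:
        inst = _concretize(pattern, rng)
        seq = inst if strand == "+" else reverse_complement(inst)
        end = pos + len(seq)
        if pos < 0 or end > spec.lengths[chrom]:
            raise ValueError(f"plant at {chrom}:{pos} outside chromosome")
        for a, b in occupied[chrom]:
            if pos < b and end > a:
                raise ValueError(f"overlapping plants at {chrom}:{pos}")
        occupied[chrom].append((pos, end))
        g = genome[chrom]
        genome[chrom] = g[:pos] + seq + g[end:]
        rows.append({"chrom": chrom, "start": pos, "strand": strand,
                     "instance": inst, "pattern": pattern})
    truth = pd.DataFrame(rows, columns=["chrom", "start", "strand", "instance", "pattern"])
    return genome, truth


def generate_mappability(layout: GenomeLayout, gaps: list) -> tuple[dict, pd.DataFrame]:
    """Uniqueness score 1.0 everywhere except planted zero-score gaps.

    ``gaps``: (chrom, start_bin, n_bins) records; overlapping gaps merge
    silently. Returns (per-bin score arrays, truth table of gap bins).
    """
    scores = {c: np.ones(layout.n_bins(c)) for c in layout.names}
    rows = []
    for chrom, start_bin, n_bins in gaps:
        nb = layout.n_bins(chrom)
        if not (0 <= start_bin and start_bin + n_bins <= nb):
            raise ValueError(f"gap outside {chrom}")
        scores[chrom][start_bin : start_bin + n_bins] = 0.0
        rows.append({"chrom": chrom, "start_bin": start_bin, "end_bin": start_bin + n_bins})
    return scores, pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin"])


def _draw_count(rng: np.random.Generator, mean: float, config: ReadSimConfig) -> int:
    if mean <= 0:
        return 0
    if config.distribution == "poisson":
        return int(rng.poisson(mean))
    size = 1.0 / config.dispersion
    return int(rng.negative_binomial(size, size / (size + mean)))


def simulate_tracks(
    features: list[PlantedFeature],
    config: ReadSimConfig,
    layout: GenomeLayout,
    conditions=CONDITIONS,
) -> tuple[dict, pd.DataFrame]:
    """Per-condition read sets with planted peaks, plus the truth table.

    Background read starts are uniform at ``background_rate`` reads/bp; each
    planted feature adds ``multiplier × background_rate × width`` reads in
    expectation, positioned with a triangular density over the feature width
    (unimodal peaks). The truth table records per-condition *expected* tag
    counts (background + peak), so attribute logic can be checked without
    sampling noise.
    """
    rl = config.read_length
    readsets = {}
    for j, cond in enumerate(conditions):
        rng = np.random.default_rng([config.seed, 17, j])
        per_chrom = {chrom: [] for chrom, _ in layout.chromosomes}
        for chrom, L in layout.chromosomes:
            n_bg = _draw_count(rng, config.background_rate * L, config)
            starts = rng.integers(0, max(1, L - rl), size=n_bg)
            strands = rng.integers(0, 2, size=n_bg) * 2 - 1
            per_chrom[chrom].append((starts, strands))
        for f in features:
            mean = f.multipliers[j] * config.background_rate * f.width
            n_pk = _draw_count(rng, mean, config)
            mids = rng.triangular(f.center - f.width / 2, f.center, f.center + f.width / 2, size=n_pk)
            L = layout.length(f.chrom)
            starts = np.clip((mids - rl / 2).astype(np.int64), 0, max(0, L - rl))
            strands = rng.integers(0, 2, size=n_pk) * 2 - 1
            per_chrom[f.chrom].append((starts, strands))
        arrays = {}
        for chrom, parts in per_chrom.items():
            starts = np.concatenate([p[0] for p in parts])
            strands = np.concatenate([p[1] for p in parts])
            arrays[chrom] = (starts, starts + rl, strands)
        readsets[cond] = ReadSet.from_arrays(arrays, layout=layout)
    rows = []
    for i, f in enumerate(features):
        expected = {
            cond: config.background_rate * f.width * (1.0 + f.multipliers[j])
            for j, cond in enumerate(conditions)
        }
        rows.append({
            "feature": f"planted_{i}", "chrom": f.chrom, "start": f.start, "end": f.end,
            "center": f.center, "width": f.width, "stage": f.stage,
            "motif_class": f.motif_class,
            **{f"mult_{c}": f.multipliers[j] for j, c in enumerate(conditions)},
            **{f"expected_{c}": expected[c] for c in conditions},
        })
    return readsets, pd.DataFrame(rows)


def simulate_input(
    layout: GenomeLayout,
    config: ReadSimConfig,
    artifacts: list = (),
    rate: float | None = None,
) -> tuple[ReadSet, pd.DataFrame]:
    """Input (no-ChIP) reads: uniform background plus planted artifact spikes.

    ``artifacts``: (chrom, start, end, fold) regions with fold × background
    read density, emulating collapsed-repeat sequencing pileups.
    """
    rng = np.random.default_rng([config.seed, 23])
    rl = config.read_length
    rate = config.background_rate if rate is None else rate
    per_chrom = {chrom: [] for chrom, _ in layout.chromosomes}
    for chrom, L in layout.chromosomes:
        n_bg = _draw_count(rng, rate * L, config)
        starts = rng.integers(0, max(1, L - rl), size=n_bg)
        strands = rng.integers(0, 2, size=n_bg) * 2 - 1
        per_chrom[chrom].append((starts, strands))
    rows = []
    for chrom, start, end, fold in artifacts:
        n = _draw_count(rng, (fold - 1) * rate * (end - start), config)
        starts = rng.integers(start, max(start + 1, end - rl), size=n)
        strands = rng.integers(0, 2, size=n) * 2 - 1
        per_chrom[chrom].append((starts, strands))
        rows.append({"chrom": chrom, "start": start, "end": end, "fold": fold})
    arrays = {}
    for chrom, parts in per_chrom.items():
        starts = np.concatenate([p[0] for p in parts]) if parts else np.array([], dtype=np.int64)
        strands = np.concatenate([p[1] for p in parts]) if parts else np.array([], dtype=np.int64)
        ends = np.minimum(starts + rl, layout.length(chrom))
        arrays[chrom] = (starts, ends, strands)
    reads = ReadSet.from_arrays(arrays, layout=layout)
    return reads, pd.DataFrame(rows, columns=["chrom", "start", "end", "fold"])


def make_ivc_series(
    kds: list,
    concentrations: list,
    depth_rpm: float = 3.0,
    counts_per_rpm: float = 20.0,
    seed: int = 0,
    noisy: bool = True,
) -> tuple[TitrationSeries, pd.DataFrame]:
    """Saturation-binding titration series with known per-site affinities.

    Expected strength at a site with dissociation constant Kd under free
    protein concentration c is ``depth_rpm × c / (c + Kd)``; observed RPM is
    Poisson-sampled at ``counts_per_rpm`` counts per RPM unit. The truth
    table records Kd, noise-free RPM and the classification implied by the
    noise-free values.
    """
    kds = np.asarray(kds, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if (kds <= 0).any() or (conc <= 0).any():
        raise ValueError("Kds and concentrations must be positive")
    rng = np.random.default_rng([seed, 31])
    expected = depth_rpm * conc[None, :] / (conc[None, :] + kds[:, None])
    if noisy:
        rpm = rng.poisson(expected * counts_per_rpm) / counts_per_rpm
    else:
        rpm = expected.copy()
    site_ids = [f"site_{i}" for i in range(len(kds))]
    series = TitrationSeries(concentrations=list(conc), site_ids=site_ids, rpm=rpm)
    det = expected >= series.detect_threshold
    cobound = (expected >= series.cobound_threshold).all(axis=1)
    gained = (~det[:, :-1]).all(axis=1) & det[:, -1]
    truth = pd.DataFrame({
        "site": site_ids,
        "kd": kds,
        "expected_class": np.where(cobound, "co_bound", np.where(gained, "gained", "other")),
        **{f"expected_rpm_{c:g}": expected[:, j] for j, c in enumerate(conc)},
    })
    return series, truth


def filter_unmappable(reads: ReadSet, layout: GenomeLayout, mappability: dict,
                      threshold: float = 0.5) -> ReadSet:
    """Drop reads whose start falls in a low-uniqueness bin.

    Emulates the upstream alignment step: reads from unmappable positions
    never appear among uniquely aligned reads.
    """
    intervals = {}
    total = 0
    bs = layout.bin_size
    for chrom, iv in reads.intervals.items():
        keep = mappability[chrom][iv["start"] // bs] >= threshold
        intervals[chrom] = {k: v[keep] for k, v in iv.items()}
        total += int(keep.sum())
    return ReadSet(intervals=intervals, total_unique_reads=total)


@dataclass
class SyntheticDataset:
    """A complete simulated study: genome, mappability, reads and truth."""

    layout: GenomeLayout
    genome: dict
    genome_truth: pd.DataFrame
    mappability: dict
    mappability_truth: pd.DataFrame
    readsets: dict            # condition -> ReadSet
    input_reads: ReadSet
    input_truth: pd.DataFrame
    feature_truth: pd.DataFrame
    planted: list             # of PlantedFeature
    seed: int


def make_mini_dataset(
    seed: int = 0,
    n_per_stage: int = 15,
    chrom_lengths: dict | None = None,
    feature_width: int = 600,
    background_rate: float = 0.1,
    read_length: int = 36,
    min_spacing: int = 8000,
    mappability_gaps: int = 6,
    input_artifacts: int = 2,
    motif_fraction: dict | None = None,
) -> SyntheticDataset:
    """The packaged mini study: 2 × 500 kb chromosomes, 60 planted features.

    Features are spread over four stage patterns (8× peak enrichment in the
    active conditions; ~30× coverage inside peaks at the default rates).
    Motif instances are planted at feature centers: hybrid in HD-primed
    features, canonical in DMI-induced and (at lower frequency) uncommitted
    features, following ``motif_fraction`` per stage.
    """
    chrom_lengths = chrom_lengths or {"chrS1": 500_000, "chrS2": 500_000}
    motif_fraction = motif_fraction or {
        "uncommitted": ("canonical", 0.3),
        "HD_primed": ("hybrid", 0.7),
        "DMI_induced": ("canonical", 0.7),
        "ambiguous": ("none", 0.0),
    }
    layout = GenomeLayout(tuple(chrom_lengths.items()), bin_size=20)
    rng = np.random.default_rng([seed, 7])
    chroms = list(chrom_lengths)

    # feature placement: round-robin over chromosomes, jittered regular grid
    stages = [s for s in STAGE_MULTIPLIERS for _ in range(n_per_stage)]
    rng.shuffle(stages)
    n = len(stages)
    planted: list[PlantedFeature] = []
    per_chrom = -(-n // len(chroms))
    idx = 0
    for chrom in chroms:
        L = chrom_lengths[chrom]
        lo, hi = 10_000, L - 10_000
        step = (hi - lo) // per_chrom
        if step < min_spacing:
            raise ValueError("chromosomes too short for requested feature count/spacing")
        for slot in range(per_chrom):
            if idx >= n:
                break
            center = lo + slot * step + step // 2 + int(rng.integers(-step // 6, step // 6 + 1))
            stage = stages[idx]
            pattern, frac = motif_fraction[stage]
            motif_class = pattern if (pattern != "none" and rng.random() < frac) else "none"
            planted.append(PlantedFeature(
                chrom=chrom, center=center, width=feature_width,
                multipliers=STAGE_MULTIPLIERS[stage], stage=stage,
                motif_class=motif_class,
            ))
            idx += 1
    planted.sort(key=lambda f: (f.chrom, f.center))

    plants = []
    for f in planted:
        if f.motif_class == "hybrid":
            plants.append((f.chrom, f.center - 4, HYBRID.iupac, "+" if rng.random() < 0.5 else "-"))
        elif f.motif_class == "canonical":
            plants.append((f.chrom, f.center - 4, CANONICAL.iupac, "+" if rng.random() < 0.5 else "-"))
    gspec = SyntheticGenomeSpec(lengths=chrom_lengths, gc=0.41, plants=plants, seed=seed)
    genome, genome_truth = generate_genome(gspec)

    # mappability gaps: half inside randomly chosen peaks, half in background
    gaps = []
    gap_feats = rng.choice(len(planted), size=min(mappability_gaps // 2, len(planted)), replace=False)
    for i in gap_feats:
        f = planted[i]
        gaps.append((f.chrom, (f.center + 100) // layout.bin_size, 3))
    for _ in range(mappability_gaps - len(gaps)):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start_bin = int(rng.integers(100, layout.n_bins(chrom) - 100))
        gaps.append((chrom, start_bin, int(rng.integers(2, 6))))
    mapp, mapp_truth = generate_mappability(layout, gaps)

    rcfg = ReadSimConfig(background_rate=background_rate, read_length=read_length, seed=seed)
    readsets, feature_truth = simulate_tracks(planted, rcfg, layout)
    # unmappable positions yield no uniquely aligned reads
    readsets = {c: filter_unmappable(rs, layout, mapp) for c, rs in readsets.items()}

    centers = {c: np.array([f.center for f in planted if f.chrom == c]) for c in chroms}
    artifacts = []
    while len(artifacts) < input_artifacts:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(20_000, chrom_lengths[chrom] - 20_000))
        if np.abs(centers[chrom] - start).min() < 5000:
            continue  # keep sequencing artifacts clear of planted enhancers
        artifacts.append((chrom, start, start + 1000, 50.0))
    input_cfg = ReadSimConfig(background_rate=background_rate / 2, read_length=read_length, seed=seed + 1)
    input_reads, input_truth = simulate_input(layout, input_cfg, artifacts=artifacts)

    return SyntheticDataset(
        layout=layout, genome=genome, genome_truth=genome_truth,
        mappability=mapp, mappability_truth=mapp_truth,
        readsets=readsets, input_reads=input_reads, input_truth=input_truth,
        feature_truth=feature_truth, planted=planted, seed=seed,
    )
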