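"""End-to-end pipeline: tracks → detect → cluster → motifs → co-occupancy.

``run_pipeline`` executes the stages on a synthetic dataset (or one loaded
from files), writes the stage outputs as plain-text tables under a run
directory, and records a machine-readable manifest with parameter values,
seeds and per-output checksums so that reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (CONDITIONS, assign_attributes, count_feature_tags,
                         group_stage, kmeans_cluster, log2_heatmap, write_cdt)
from .features import DetectionConfig, detect
from .genome import GenomeLayout
from .io import write_bed_features, write_features_tsv
from .motifs import (BUILTIN_PATTERNS, cluster_motif_frequency, merge_windows,
                     select_window)
from .simulate import SyntheticDataset, make_mini_dataset
from .tracks import process_track


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published constants."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    k: int = 19
    seed: int = 0
    pseudocount: float = 1.0
    fold: float = 2.0
    motif_patterns: tuple = ("hybrid", "canonical")
    overlap_window: int = 200
    ivc_detect_threshold: float = 1.0
    ivc_cobound_threshold: float = 0.5
    mappability_threshold: float = 0.5
    input_fold: float = 10.0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["motif_patterns"] = list(self.motif_patterns)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        det = d.pop("detection", None)
        cfg = cls(**d)
        if det is not None:
            det_known = {f.name for f in dataclasses.fields(DetectionConfig)}
            bad = set(det) - det_known
            if bad:
                raise ValueError(f"unknown detection config keys: {sorted(bad)}")
            cfg.detection = DetectionConfig(**det)
        if isinstance(cfg.motif_patterns, list):
            cfg.motif_patterns = tuple(cfg.motif_patterns)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(dataset: SyntheticDataset, config: PipelineConfig, outdir) -> dict:
    """Run all stages on a dataset and write outputs + manifest to ``outdir``.

    Returns the manifest dict. Raises with the failing stage's name on any
    stage error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "rng": "numpy PCG64",
        "parameters": json.loads(json.dumps(asdict(config), default=str)),
        "stages": [],
        "outputs": {},
    }
    written: list[Path] = []

    def _stage(name):
        manifest["stages"].append(name)

    try:
        stage = "tracks"
        input_track = process_track(dataset.input_reads, dataset.layout)
        tracks = {
            cond: process_track(
                dataset.readsets[cond], dataset.layout,
                mappability=dataset.mappability, input_track=input_track,
                mappability_threshold=config.mappability_threshold,
                input_fold=config.input_fold,
            )
            for cond in CONDITIONS
        }
        _stage(stage)

        stage = "detect"
        fs = detect({c: (tracks[c], dataset.readsets[c]) for c in CONDITIONS},
                    config.detection)
        for cond, feats in fs.per_track.items():
            p = outdir / f"features_{cond}.tsv"
            write_features_tsv(feats, p, dataset.layout.bin_size)
            written.append(p)
        p = outdir / "features_union.bed"
        write_bed_features(fs.union, p)
        written.append(p)
        _stage(stage)

        stage = "cluster"
        matrix = count_feature_tags(fs.union, dataset.readsets)
        matrix.pseudocount = config.pseudocount
        attrs = assign_attributes(matrix, fold=config.fold)
        stages_ser = group_stage(attrs)
        k = min(config.k, len(fs.union))
        clusters = kmeans_cluster(matrix, k=k, seed=config.seed)
        heat = log2_heatmap(matrix)
        for name, obj in [("counts", matrix.to_frame()), ("attributes", attrs),
                          ("stage_groups", stages_ser.to_frame()),
                          ("clusters", clusters.labels.to_frame()), ("heatmap", heat)]:
            p = outdir / f"{name}.tsv"
            obj.to_csv(p, sep="\t", float_format="%.6g")
            written.append(p)
        p = outdir / "heatmap.cdt"
        write_cdt(heat, p)
        written.append(p)
        _stage(stage)

        stage = "motifs"
        ref = tracks["HD"]
        windows = []
        for f in fs.union:
            w = select_window(f, ref)
            if w is not None:
                windows.append(w)
        windows = merge_windows(windows)
        win_by_feature = {w.feature_id.split("+")[0]: w for w in windows}
        by_group: dict[str, list] = {}
        for f in fs.union:
            w = win_by_feature.get(f.id)
            if w is None:
                continue
            by_group.setdefault(stages_ser.get(f.id, "ambiguous"), []).append(w)
        freq_rows = []
        for pname in config.motif_patterns:
            pattern = BUILTIN_PATTERNS[pname]
            freqs = cluster_motif_frequency(by_group, dataset.genome, pattern)
            for group, res in sorted(freqs.items()):
                if res is None:
                    continue
                frac, nwin, (lo, hi) = res
                freq_rows.append({"pattern": pname, "group": group, "fraction": frac,
                                  "n_windows": nwin, "ci_lo": lo, "ci_hi": hi})
        p = outdir / "motif_frequency.tsv"
        pd.DataFrame(freq_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)
        _stage(stage)

        stage = "cooccupancy"
        # summary table: per stage group, feature counts (overlap analyses
        # against TF cistromes run through the cooccupancy module API)
        counts = stages_ser.value_counts().rename_axis("stage").to_frame("n_features")
        p = outdir / "stage_counts.tsv"
        counts.to_csv(p, sep="\t")
        written.append(p)
        _stage(stage)
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["outputs"] = {str(p.name): _sha256(p) for p in written if p.exists()}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest["outputs"] = {str(p.name): _sha256(p) for p in written}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_mini(seed: int = 0, outdir=None, config: PipelineConfig | None = None) -> dict:
    """Generate the packaged mini dataset and run the full pipeline on it."""
    config = config or PipelineConfig(seed=seed)
    dataset = make_mini_dataset(seed=seed)
    if outdir is None:
        import tempfile
        outdir = tempfile.mkdtemp(prefix="polprime_run_")
    return run_pipeline(dataset, config, outdir)
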