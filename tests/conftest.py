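from __future__ import annotations

import numpy as np
import pytest

import polprime as pp


@pytest.fixture(scope="session")
def mini():
    """The packaged mini study: 2 × 500 kb, 60 planted features (seed 1)."""
    return pp.make_mini_dataset(seed=1)


@pytest.fixture(scope="session")
def mini_tracks(mini):
    input_track = pp.process_track(mini.input_reads, mini.layout)
    return {
        cond: pp.process_track(
            mini.readsets[cond], mini.layout,
            mappability=mini.mappability, input_track=input_track,
        )
        for cond in pp.CONDITIONS
    }


@pytest.fixture(scope="session")
def mini_detection(mini, mini_tracks):
    return pp.detect({c: (mini_tracks[c], mini.readsets[c]) for c in pp.CONDITIONS})


def make_track(values, layout=None, bin_size=20, **kw):
    """BinnedTrack from an explicit per-bin value array (single chromosome)."""
    values = np.asarray(values, dtype=float)
    layout = layout or pp.GenomeLayout((("chrT", len(values) * bin_size),), bin_size=bin_size)
    (chrom,) = layout.names
    return pp.BinnedTrack(
        layout=layout,
        values={chrom: values},
        mask={chrom: np.zeros(len(values), dtype=np.uint8)},
        **kw,
    )


def triangle(n_bins, center, half_width, height, base=0.0):
    """Per-bin triangular peak profile for noise-free detector fixtures."""
    vals = np.full(n_bins, base)
    for i in range(n_bins):
        d = abs(i - center)
        if d <= half_width:
            vals[i] = max(vals[i], base + height * (1 - d / half_width))
    return vals


def random_fixture(seed, with_mappability=False):
    """Small random read fixture (≤ 10 kb) with 0–3 planted peaks.

    Returns (track, reads, layout) with the track fully processed.
    """
    rng = np.random.default_rng([seed, 99])
    L = int(rng.integers(4000, 10001))
    layout = pp.GenomeLayout((("chrF", L),), bin_size=20)
    rl = 36
    n_bg = rng.poisson(0.3 * L)
    starts = rng.integers(0, L - rl, size=n_bg)
    strands = rng.integers(0, 2, size=n_bg) * 2 - 1
    parts = [(starts, strands)]
    for _ in range(int(rng.integers(0, 4))):
        center = int(rng.integers(800, L - 800))
        width = int(rng.integers(300, 700))
        enrich = float(rng.uniform(2.0, 10.0))
        n_pk = rng.poisson(enrich * 0.3 * width)
        mids = rng.triangular(center - width / 2, center, center + width / 2, size=n_pk)
        ps = np.clip((mids - rl / 2).astype(np.int64), 0, L - rl)
        parts.append((ps, rng.integers(0, 2, size=n_pk) * 2 - 1))
    allstarts = np.concatenate([p[0] for p in parts])
    allstrands = np.concatenate([p[1] for p in parts])
    reads = pp.ReadSet.from_arrays({"chrF": (allstarts, allstarts + rl, allstrands)}, layout=layout)
    mapp = None
    if with_mappability:
        scores = np.ones(layout.n_bins("chrF"))
        g0 = int(rng.integers(50, layout.n_bins("chrF") - 50))
        scores[g0 : g0 + int(rng.integers(1, 5))] = 0.0
        mapp = {"chrF": scores}
        reads = pp.filter_unmappable(reads, layout, mapp)
    track = pp.process_track(reads, layout, mappability=mapp)
    return track, reads, layout
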