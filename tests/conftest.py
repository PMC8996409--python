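"""Shared fixtures and per-base bitmap oracles for interval algebra."""

from __future__ import annotations

import numpy as np
import pytest

from laddyn.genome import GenomeLayout, IntervalSet


# --------------------------------------------------------------------- #
# bitmap oracle: sets of intervals as boolean per-base arrays


def to_bitmap(iset: IntervalSet) -> dict[str, np.ndarray]:
    out = {}
    for chrom in iset.layout.chrom_names:
        bits = np.zeros(iset.layout.length(chrom), dtype=bool)
        for s, e in iset.segments_on(chrom):
            bits[s:e] = True
        out[chrom] = bits
    return out


def from_bitmap(bits: dict[str, np.ndarray], layout: GenomeLayout) -> IntervalSet:
    intervals = []
    for chrom, arr in bits.items():
        padded = np.concatenate([[False], arr, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        intervals.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return IntervalSet.from_intervals(intervals, layout)


def random_interval_set(
    rng: np.random.Generator, layout: GenomeLayout, max_segments: int = 8
) -> IntervalSet:
    intervals = []
    for chrom in layout.chrom_names:
        length = layout.length(chrom)
        for _ in range(int(rng.integers(0, max_segments + 1))):
            s = int(rng.integers(0, length))
            e = int(rng.integers(s + 1, min(length, s + max(2, length // 4)) + 1))
            intervals.append((chrom, s, e))
    return IntervalSet.from_intervals(intervals, layout)


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (10_000, 6_000))


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seed fixed)."""
    from laddyn.simulate import SimulationConfig, simulate_study

    return simulate_study(SimulationConfig(seed=20))


@pytest.fixture(scope="session")
def noiseless_study():
    """Zero-jitter, noise-free study for exact closure checks."""
    from laddyn.simulate import SimulationConfig, simulate_study

    cfg = SimulationConfig(
        seed=21,
        replicate_jitter_sd_bp=0.0,
        nb_dispersion=None,
        lmnb1_shared_sd=0.0,
        lmnb1_rep_sd=0.0,
        h3k9me3_sd=0.0,
        ptm_noise_sd=0.0,
    )
    return simulate_study(cfg)
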