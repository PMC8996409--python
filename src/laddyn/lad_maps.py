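"""Per-time-point LAD maps, constitutive LADs, and replicate QC.

The final LAD map at each time point is the union of the replicate LAD
calls; constitutive LADs (cLADs) are the base-exact intersection of the
per-time-point maps across the whole time course. Replicate concordance is
assessed as the Pearson correlation of binned lamin B1 log2(ChIP/input)
ratios (default 100-kb bins), optionally restricted to bins intersecting
the mapped LADs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import GenomeLayout, IntervalSet
from .signal import BinnedTrack

__all__ = [
    "LADTimeline",
    "merge_replicates",
    "constitutive_lads",
    "binned_correlation",
]


@dataclass
class LADTimeline:
    """Ordered time-point labels and the (replicate-merged) LAD map at each."""

    time_points: list[str]
    lads_per_tp: dict[str, IntervalSet]
    layout: GenomeLayout = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.time_points)) != len(self.time_points):
            raise ValueError("time-point labels must be unique")
        if set(self.time_points) != set(self.lads_per_tp):
            raise ValueError("time_points and lads_per_tp keys disagree")
        layouts = {id(s.layout): s.layout for s in self.lads_per_tp.values()}
        it = iter(self.lads_per_tp.values())
        first = next(it).layout
        for s in it:
            if s.layout != first:
                raise ValueError("all time points must share one genome layout")
        self.layout = first

    def __getitem__(self, tp: str) -> IntervalSet:
        return self.lads_per_tp[tp]

    def union_all(self) -> IntervalSet:
        """Union of LAD locations over the whole time course."""
        out = IntervalSet.empty(self.layout)
        for tp in self.time_points:
            out = out.union(self.lads_per_tp[tp])
        return out


def merge_replicates(rep_sets: Sequence[IntervalSet]) -> IntervalSet:
    """Final LADs at a time point: the union of the replicate LAD calls."""
    if not rep_sets:
        raise ValueError("need at least one replicate LAD set")
    out = rep_sets[0]
    for s in rep_sets[1:]:
        out = out.union(s)
    return out


def constitutive_lads(timeline: LADTimeline) -> IntervalSet:
    """cLADs: base-exact intersection of LAD maps over all time points."""
    if len(timeline.time_points) < 2:
        raise ValueError("constitutive LADs require at least two time points")
    tps = timeline.time_points
    out = timeline[tps[0]]
    for tp in tps[1:]:
        out = out.intersect(timeline[tp])
    return out


def binned_correlation(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    bin_bp: int = 100_000,
    restrict_to: IntervalSet | None = None,
) -> float:
    """Pearson r between two tracks re-binned to ``bin_bp``.

    Both tracks are re-binned by coverage-weighted mean; bins where either
    track has no data are dropped. With ``restrict_to`` set (e.g. the
    merged LADs), only bins intersecting those regions by >= 1 bp enter the
    correlation — the within-LAD concordance variant.
    """
    if track_a.layout != track_b.layout:
        raise ValueError("tracks are on different layouts")
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    a = track_a.rebin(bin_bp)
    b = track_b.rebin(bin_bp)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for chrom in a.layout.chrom_names:
        va, vb = a.values[chrom], b.values[chrom]
        keep = ~np.isnan(va) & ~np.isnan(vb)
        if restrict_to is not None:
            arr = restrict_to.segments_on(chrom)
            in_regions = np.zeros(len(va), dtype=bool)
            for s, e in arr:
                in_regions[s // bin_bp : (e - 1) // bin_bp + 1] = True
            keep &= in_regions
        xs.append(va[keep])
        ys.append(vb[keep])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 2:
        raise ValueError("fewer than 2 usable bins for correlation")
    r, _ = stats.pearsonr(x, y)
    return float(r)
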