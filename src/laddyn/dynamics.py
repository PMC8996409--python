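"""Classification of LAD changes between two time points.

Between an earlier and a later LAD map the genome partitions into six
disjoint categories: bases in LADs at both time points (common), bases
gained as entirely new stand-alone LADs, bases gained as extensions of
pre-existing LADs (gained edges), the symmetric lost stand-alone LADs and
lost edges, and everything else (i-LAD). "Stand-alone" means the contiguous
LAD containing the changed bases overlaps the other time point's LAD map by
zero bp (configurable minimum-overlap threshold for sensitivity analysis);
any >= 1 bp touch makes the change an edge change.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeLayout, IntervalSet, write_bed

__all__ = ["ChangeCategory", "ChangePartition", "classify_changes", "category_summary"]


class ChangeCategory(str, Enum):
    COMMON = "common"
    GAINED_LAD = "gained_lad"
    LOST_LAD = "lost_lad"
    GAINED_EDGE = "gained_edge"
    LOST_EDGE = "lost_edge"
    ILAD = "ilad"


#: The five LAD-related categories (everything except i-LAD).
LAD_CATEGORIES = (
    ChangeCategory.COMMON,
    ChangeCategory.GAINED_LAD,
    ChangeCategory.LOST_LAD,
    ChangeCategory.GAINED_EDGE,
    ChangeCategory.LOST_EDGE,
)


@dataclass
class ChangePartition:
    """Disjoint, exhaustive labelling of the genome between two time points."""

    regions: dict[ChangeCategory, IntervalSet]
    t_from: str
    t_to: str
    layout: GenomeLayout

    def __post_init__(self) -> None:
        missing = set(ChangeCategory) - set(self.regions)
        if missing:
            raise ValueError(f"partition missing categories: {missing}")

    def __getitem__(self, cat: ChangeCategory) -> IntervalSet:
        return self.regions[cat]

    def validate(self) -> None:
        """Check pairwise disjointness and exhaustive genome coverage."""
        cats = list(ChangeCategory)
        for i, a in enumerate(cats):
            for b in cats[i + 1 :]:
                bp = self.regions[a].overlap_bp(self.regions[b])
                if bp != 0:
                    raise AssertionError(f"categories {a} and {b} overlap by {bp} bp")
        total = sum(self.regions[c].total_bp for c in cats)
        if total != self.layout.total_bp:
            raise AssertionError(
                f"partition covers {total} bp of a {self.layout.total_bp} bp genome"
            )

    def write_beds(self, outdir: str | Path) -> dict[ChangeCategory, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for cat in ChangeCategory:
            p = outdir / f"{self.t_from}_{self.t_to}_{cat.value}.bed"
            write_bed(self.regions[cat], p, name=cat.value)
            paths[cat] = p
        return paths


def _standalone_segments(
    contiguous: IntervalSet, other: IntervalSet, min_overlap_bp: int
) -> IntervalSet:
    """Segments of ``contiguous`` overlapping ``other`` by <= min_overlap_bp."""
    keep = []
    for iv in contiguous:
        single = IntervalSet(
            contiguous.layout,
            {iv.chrom: np.array([[iv.start, iv.end]])},
            _normalized=True,
        )
        if single.overlap_bp(other) <= min_overlap_bp:
            keep.append(iv)
    return IntervalSet.from_intervals(keep, contiguous.layout)


def classify_changes(
    lads_from: IntervalSet,
    lads_to: IntervalSet,
    layout: GenomeLayout,
    min_overlap_bp: int = 0,
) -> ChangePartition:
    """Partition the genome into the six change categories.

    A gained base belongs to a stand-alone gained LAD iff the contiguous
    destination LAD containing it overlaps the source map by at most
    ``min_overlap_bp`` (default 0: any touch makes it an edge extension);
    symmetrically for losses. A destination LAD bridging two source LADs
    contributes its interior new bases to gained edges, consistent with the
    zero-overlap rule.
    """
    if lads_from.layout != layout or lads_to.layout != layout:
        raise ValueError("LAD sets are not on the supplied genome layout")
    common = lads_from.intersect(lads_to)
    gained_all = lads_to.subtract(lads_from)
    lost_all = lads_from.subtract(lads_to)

    standalone_to = _standalone_segments(lads_to, lads_from, min_overlap_bp)
    standalone_from = _standalone_segments(lads_from, lads_to, min_overlap_bp)

    gained_lad = gained_all.intersect(standalone_to)
    gained_edge = gained_all.subtract(standalone_to)
    lost_lad = lost_all.intersect(standalone_from)
    lost_edge = lost_all.subtract(standalone_from)
    ilad = lads_from.union(lads_to).complement()

    return ChangePartition(
        regions={
            ChangeCategory.COMMON: common,
            ChangeCategory.GAINED_LAD: gained_lad,
            ChangeCategory.LOST_LAD: lost_lad,
            ChangeCategory.GAINED_EDGE: gained_edge,
            ChangeCategory.LOST_EDGE: lost_edge,
            ChangeCategory.ILAD: ilad,
        },
        t_from="from",
        t_to="to",
        layout=layout,
    )


def category_summary(partition: ChangePartition) -> pd.DataFrame:
    """Per-category coverage (mb), segment counts, and segment-size quartiles."""
    rows = []
    for cat in ChangeCategory:
        iset = partition[cat]
        lengths = iset.segment_lengths()
        if len(lengths):
            q25, med, q75 = np.percentile(lengths, [25, 50, 75])
        else:
            q25 = med = q75 = float("nan")
        rows.append(
            {
                "category": cat.value,
                "mb": iset.total_bp / 1e6,
                "n_segments": iset.n_segments,
                "size_q25_bp": q25,
                "size_median_bp": med,
                "size_q75_bp": q75,
            }
        )
    return pd.DataFrame(rows)
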