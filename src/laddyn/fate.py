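"""Ten-class LAD fate: early change category x late LAD/i-LAD outcome.

Each of the five LAD-related change categories between the first two time
points (common, gained/lost stand-alone LAD, gained/lost edge) is split by
whether its bases end up inside or outside the LAD map at the final time
point, yielding ten classes ("Common>LAD", "Common>i-LAD", ...). Two
granularities are supported: base-exact ("split", the default, conserving
bp) and per-contiguous-segment majority vote ("majority", conserving
segment counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import LAD_CATEGORIES, ChangeCategory, ChangePartition
from .genome import IntervalSet, write_bed

__all__ = [
    "CLASS_LABELS",
    "class_label",
    "split_by_outcome",
    "LADClassMap",
    "build_lad_classes",
    "flow_table",
]

_CATEGORY_DISPLAY = {
    ChangeCategory.COMMON: "Common",
    ChangeCategory.GAINED_LAD: "Gained LAD",
    ChangeCategory.LOST_LAD: "Lost LAD",
    ChangeCategory.GAINED_EDGE: "Gained edge",
    ChangeCategory.LOST_EDGE: "Lost edge",
}

_OUTCOMES = ("LAD", "i-LAD")


def class_label(category: ChangeCategory, outcome: str) -> str:
    """Fixed class-label string, e.g. ``"Gained LAD>i-LAD"``."""
    if outcome not in _OUTCOMES:
        raise ValueError(f"outcome must be one of {_OUTCOMES}")
    return f"{_CATEGORY_DISPLAY[category]}>{outcome}"


#: The ten fixed class labels, in stable order.
CLASS_LABELS = tuple(
    class_label(cat, out) for cat in LAD_CATEGORIES for out in _OUTCOMES
)


def split_by_outcome(
    region_set: IntervalSet,
    lads_final: IntervalSet,
    mode: str = "split",
    frac_threshold: float = 0.5,
) -> tuple[IntervalSet, IntervalSet]:
    """Split a region set by its LAD vs i-LAD status at the final time point.

    ``split``: base-exact (in_lad = region ∩ final LADs; in_ilad = the
    rest). ``majority``: each contiguous segment goes wholly to LAD when
    its overlap fraction with the final LAD map is >= ``frac_threshold``.
    """
    if mode not in ("split", "majority"):
        raise ValueError(f"unknown mode {mode!r}; expected 'split' or 'majority'")
    if not (0 < frac_threshold <= 1):
        raise ValueError("frac_threshold must be in (0, 1]")
    if mode == "split":
        in_lad = region_set.intersect(lads_final)
        in_ilad = region_set.subtract(lads_final)
        return in_lad, in_ilad
    lad_ivs, ilad_ivs = [], []
    for iv in region_set:
        single = IntervalSet(
            region_set.layout,
            {iv.chrom: np.array([[iv.start, iv.end]])},
            _normalized=True,
        )
        frac = single.overlap_bp(lads_final) / iv.length
        (lad_ivs if frac >= frac_threshold else ilad_ivs).append(iv)
    return (
        IntervalSet.from_intervals(lad_ivs, region_set.layout),
        IntervalSet.from_intervals(ilad_ivs, region_set.layout),
    )


@dataclass
class LADClassMap:
    """The ten-class fate partition of the LAD-related genome."""

    classes: dict[str, IntervalSet]
    mode: str

    def __post_init__(self) -> None:
        if set(self.classes) != set(CLASS_LABELS):
            raise ValueError("class map must contain exactly the ten fixed labels")

    def __getitem__(self, label: str) -> IntervalSet:
        return self.classes[label]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"class": lbl, "mb": self.classes[lbl].total_bp / 1e6,
                 "n_segments": self.classes[lbl].n_segments}
                for lbl in CLASS_LABELS
            ]
        )

    def write_beds(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for lbl in CLASS_LABELS:
            fname = lbl.replace(">", "_to_").replace(" ", "_").replace("-", "") + ".bed"
            p = outdir / fname
            write_bed(self.classes[lbl], p, name=lbl)
            paths[lbl] = p
        return paths


def build_lad_classes(
    partition: ChangePartition,
    lads_final: IntervalSet,
    mode: str = "split",
    frac_threshold: float = 0.5,
) -> LADClassMap:
    """Split each early change category by its final LAD/i-LAD outcome."""
    classes: dict[str, IntervalSet] = {}
    for cat in LAD_CATEGORIES:
        in_lad, in_ilad = split_by_outcome(
            partition[cat], lads_final, mode=mode, frac_threshold=frac_threshold
        )
        classes[class_label(cat, "LAD")] = in_lad
        classes[class_label(cat, "i-LAD")] = in_ilad
    return LADClassMap(classes=classes, mode=mode)


def flow_table(partition: ChangePartition, lads_final: IntervalSet) -> pd.DataFrame:
    """(category, outcome, mb) rows for alluvial-style fate flows (bp-exact)."""
    rows = []
    for cat in LAD_CATEGORIES:
        in_lad, in_ilad = split_by_outcome(partition[cat], lads_final, mode="split")
        rows.append({"category": cat.value, "outcome": "LAD", "mb": in_lad.total_bp / 1e6})
        rows.append(
            {"category": cat.value, "outcome": "i-LAD", "mb": in_ilad.total_bp / 1e6}
        )
    return pd.DataFrame(rows)
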