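"""Binned signal tracks and signal summaries.

A :class:`BinnedTrack` holds one value per fixed-size genomic bin (e.g.
log2(ChIP/input) lamin B1 ratios in 1-kb bins, or library-size-normalized
histone-PTM read counts), with NaN marking bins without data. On top of it:
per-region enrichment means, strand-oriented TSS metaprofiles, and the
H3K4me1 sub-domain partition of constitutive LADs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout, IntervalSet

__all__ = [
    "BinnedTrack",
    "read_bedgraph",
    "average_tracks",
    "region_mean_signal",
    "MetaProfile",
    "tss_metaprofile",
    "subdomain_partition",
]


@dataclass
class BinnedTrack:
    """Per-chromosome arrays of bin values; NaN = no data.

    Array length for chromosome c is ``ceil(length(c) / bin_bp)``; the last
    bin may be truncated by the chromosome end, which the coverage-weighted
    operations account for.
    """

    layout: GenomeLayout
    bin_bp: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_bp <= 0:
            raise ValueError("bin_bp must be positive")
        for chrom in self.layout.chrom_names:
            n = math.ceil(self.layout.length(chrom) / self.bin_bp)
            if chrom not in self.values:
                self.values[chrom] = np.full(n, np.nan)
            elif len(self.values[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(self.values[chrom])}"
                )

    @classmethod
    def empty(cls, layout: GenomeLayout, bin_bp: int) -> "BinnedTrack":
        return cls(layout, bin_bp, {})

    @classmethod
    def constant(cls, layout: GenomeLayout, bin_bp: int, value: float) -> "BinnedTrack":
        track = cls.empty(layout, bin_bp)
        for arr in track.values.values():
            arr[:] = value
        return track

    def _bin_widths(self, chrom: str) -> np.ndarray:
        """Effective width (bp) of each bin, accounting for the truncated last bin."""
        length = self.layout.length(chrom)
        n = len(self.values[chrom])
        widths = np.full(n, self.bin_bp, dtype=np.int64)
        widths[-1] = length - (n - 1) * self.bin_bp
        return widths

    def rebin(self, bin_bp: int) -> "BinnedTrack":
        """Re-bin by coverage-weighted mean of unmasked source bins."""
        if bin_bp == self.bin_bp:
            return self
        out = BinnedTrack.empty(self.layout, bin_bp)
        for chrom in self.layout.chrom_names:
            src = self.values[chrom]
            widths = self._bin_widths(chrom)
            starts = np.arange(len(src), dtype=np.int64) * self.bin_bp
            ends = starts + widths
            ok = ~np.isnan(src)
            if not ok.any():
                continue
            n_new = len(out.values[chrom])
            wsum = np.zeros(n_new)
            vsum = np.zeros(n_new)
            s, e, v = starts[ok], ends[ok], src[ok]
            first = s // bin_bp
            last = (e - 1) // bin_bp
            # source bins may straddle several destination bins
            for i in range(len(s)):
                for j in range(int(first[i]), int(last[i]) + 1):
                    lo = max(int(s[i]), j * bin_bp)
                    hi = min(int(e[i]), (j + 1) * bin_bp)
                    w = hi - lo
                    wsum[j] += w
                    vsum[j] += w * v[i]
            vals = np.full(n_new, np.nan)
            nz = wsum > 0
            vals[nz] = vsum[nz] / wsum[nz]
            out.values[chrom] = vals
        return out

    def to_bedgraph(self, path: str | Path) -> None:
        """Write unmasked bins as a 4-column bedGraph (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom in self.layout.chrom_names:
                arr = self.values[chrom]
                widths = self._bin_widths(chrom)
                for i, v in enumerate(arr):
                    if np.isnan(v):
                        continue
                    start = i * self.bin_bp
                    fh.write(f"{chrom}\t{start}\t{start + widths[i]}\t{v:.6g}\n")


def read_bedgraph(path: str | Path, layout: GenomeLayout, bin_bp: int) -> BinnedTrack:
    """Read a 4-column bedGraph into a BinnedTrack at ``bin_bp`` resolution.

    Record values are distributed to bins by coverage-weighted mean; bases
    never covered by a record stay NaN.
    """
    track = BinnedTrack.empty(layout, bin_bp)
    wsum = {c: np.zeros(len(track.values[c])) for c in layout.chrom_names}
    vsum = {c: np.zeros(len(track.values[c])) for c in layout.chrom_names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in layout:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= layout.length(chrom)):
                raise ValueError(f"{path}:{lineno}: invalid interval")
            first, last = start // bin_bp, (end - 1) // bin_bp
            for j in range(first, last + 1):
                lo = max(start, j * bin_bp)
                hi = min(end, (j + 1) * bin_bp)
                wsum[chrom][j] += hi - lo
                vsum[chrom][j] += (hi - lo) * value
    for chrom in layout.chrom_names:
        nz = wsum[chrom] > 0
        arr = np.full(len(track.values[chrom]), np.nan)
        arr[nz] = vsum[chrom][nz] / wsum[chrom][nz]
        track.values[chrom] = arr
    return track


def average_tracks(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Per-bin mean across tracks; a bin masked in any input stays masked.

    This is the "all time points confounded" average used for pooled
    enrichment summaries.
    """
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.layout != first.layout or t.bin_bp != first.bin_bp:
            raise ValueError("tracks must share layout and bin size")
    out = BinnedTrack.empty(first.layout, first.bin_bp)
    for chrom in first.layout.chrom_names:
        stack = np.vstack([t.values[chrom] for t in tracks])
        out.values[chrom] = stack.mean(axis=0)  # NaN propagates
    return out


def region_mean_signal(
    track: BinnedTrack, regions: IntervalSet
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Coverage-weighted mean signal per region, plus a pooled summary.

    Returns a per-region table (chrom, start, end, mean_signal; NaN when a
    region has no unmasked bins) and summary statistics over the non-missing
    region means.
    """
    if regions.layout != track.layout:
        raise ValueError("track and regions are on different layouts")
    if not regions:
        raise ValueError("empty region set")
    rows = []
    b = track.bin_bp
    for iv in regions:
        arr = track.values[iv.chrom]
        first, last = iv.start // b, (iv.end - 1) // b
        idx = np.arange(first, last + 1)
        lo = np.maximum(iv.start, idx * b)
        hi = np.minimum(iv.end, (idx + 1) * b)
        w = (hi - lo).astype(float)
        v = arr[idx]
        ok = ~np.isnan(v)
        mean = float(np.sum(w[ok] * v[ok]) / np.sum(w[ok])) if ok.any() else np.nan
        rows.append((iv.chrom, iv.start, iv.end, mean))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_signal"])
    vals = table["mean_signal"].dropna().to_numpy()
    if len(vals):
        summary = {
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "q25": float(np.percentile(vals, 25)),
            "q75": float(np.percentile(vals, 75)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": int(len(vals)),
        }
    else:
        summary = {k: float("nan") for k in ("mean", "median", "q25", "q75", "min", "max")}
        summary["n"] = 0
    return table, summary


@dataclass
class MetaProfile:
    """Mean signal by strand-oriented offset from an anchor (e.g. TSS)."""

    offsets: np.ndarray  # bp, bin centers, symmetric around 0
    mean_signal: np.ndarray
    n_anchors: int
    n_dropped: int  # anchors whose window ran off a chromosome end

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset_bp": self.offsets, "mean_signal": self.mean_signal}
        )


def _window_profile(
    track: BinnedTrack, chrom: str, left: int, half_window_bp: int, profile_bin_bp: int
) -> np.ndarray:
    """Coverage-weighted means over profile bins of [left, left + 2*half_window)."""
    n_bins = 2 * half_window_bp // profile_bin_bp
    arr = track.values[chrom]
    b = track.bin_bp
    out = np.empty(n_bins)
    for k in range(n_bins):
        s = left + k * profile_bin_bp
        e = s + profile_bin_bp
        idx = np.arange(s // b, (e - 1) // b + 1)
        lo = np.maximum(s, idx * b)
        hi = np.minimum(e, (idx + 1) * b)
        w = (hi - lo).astype(float)
        v = arr[idx]
        ok = ~np.isnan(v)
        out[k] = np.sum(w[ok] * v[ok]) / np.sum(w[ok]) if ok.any() else np.nan
    return out


def tss_metaprofile(
    track: BinnedTrack,
    genes: Iterable,
    half_window_bp: int = 3000,
    profile_bin_bp: int = 50,
) -> MetaProfile:
    """Aggregate signal around transcription start sites, strand-oriented.

    Minus-strand windows are flipped so that positive offsets always point
    into the gene body. Anchors whose window would be truncated by a
    chromosome end are dropped (and counted).
    """
    if half_window_bp % profile_bin_bp != 0:
        raise ValueError("half_window_bp must be a multiple of profile_bin_bp")
    n_bins = 2 * half_window_bp // profile_bin_bp
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    n_used = 0
    n_dropped = 0
    for gene in genes:
        tss = gene.tss
        left = tss - half_window_bp
        right = tss + half_window_bp
        if left < 0 or right > track.layout.length(gene.chrom):
            n_dropped += 1
            continue
        prof = _window_profile(track, gene.chrom, left, half_window_bp, profile_bin_bp)
        if gene.strand == "-":
            prof = prof[::-1]
        ok = ~np.isnan(prof)
        acc[ok] += prof[ok]
        cnt[ok] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable anchors (all windows truncated or no genes)")
    mean = np.full(n_bins, np.nan)
    nz = cnt > 0
    mean[nz] = acc[nz] / cnt[nz]
    offsets = (
        -half_window_bp + profile_bin_bp * np.arange(n_bins) + profile_bin_bp / 2.0
    )
    return MetaProfile(offsets, mean, n_anchors=n_used, n_dropped=n_dropped)


def subdomain_partition(
    clads: IntervalSet, peak_sets: Sequence[IntervalSet]
) -> tuple[IntervalSet, IntervalSet]:
    """Split cLADs into H3K4me1 and non-H3K4me1 sub-domains.

    The merged peak footprint is the union of the per-time-point peak sets;
    a cLAD base belongs to the H3K4me1 sub-domain iff it is inside that
    footprint at >= 1 time point. The two parts partition the cLADs exactly.
    """
    footprint = IntervalSet.empty(clads.layout)
    for ps in peak_sets:
        footprint = footprint.union(ps)
    inside = clads.intersect(footprint)
    outside = clads.subtract(footprint)
    return inside, outside
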