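"""Binned tracks, region means, TSS metaprofiles, sub-domain partition."""

from __future__ import annotations

import numpy as np
import pytest

from laddyn.annotation import GeneRecord
from laddyn.genome import GenomeLayout, IntervalSet, merge
from laddyn.signal import (
    BinnedTrack,
    average_tracks,
    read_bedgraph,
    region_mean_signal,
    subdomain_partition,
    tss_metaprofile,
)


@pytest.fixture
def layout():
    return GenomeLayout(("chr1",), (100_000,))


class TestBinnedTrack:
    def test_bedgraph_roundtrip(self, layout, tmp_path):
        rng = np.random.default_rng(0)
        track = BinnedTrack.empty(layout, 1_000)
        track.values["chr1"][:] = np.round(rng.normal(size=100), 4)
        p = tmp_path / "t.bedgraph"
        track.to_bedgraph(p)
        back = read_bedgraph(p, layout, 1_000)
        assert back.values["chr1"] == pytest.approx(track.values["chr1"], rel=1e-4)

    def test_bedgraph_partial_coverage_leaves_nan(self, layout, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t1000\t2.0\nchr1\t5000\t6000\t-1.0\n")
        track = read_bedgraph(p, layout, 1_000)
        assert track.values["chr1"][0] == 2.0
        assert track.values["chr1"][5] == -1.0
        assert np.isnan(track.values["chr1"][1])

    def test_bedgraph_weighted_binning(self, layout, tmp_path):
        # value 4 over 250 bp and value 0 over 750 bp of the first 1-kb bin
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t250\t4.0\nchr1\t250\t1000\t0.0\n")
        track = read_bedgraph(p, layout, 1_000)
        assert track.values["chr1"][0] == pytest.approx(1.0)

    def test_rebin_coverage_weighted(self, layout):
        track = BinnedTrack.empty(layout, 1_000)
        track.values["chr1"][:2] = [1.0, 3.0]
        re = track.rebin(2_000)
        assert re.values["chr1"][0] == pytest.approx(2.0)
        assert np.isnan(re.values["chr1"][1])

    def test_average_tracks_propagates_mask(self, layout):
        a = BinnedTrack.empty(layout, 1_000)
        b = BinnedTrack.empty(layout, 1_000)
        a.values["chr1"][:2] = [1.0, 1.0]
        b.values["chr1"][0] = 3.0
        avg = average_tracks([a, b])
        assert avg.values["chr1"][0] == 2.0
        assert np.isnan(avg.values["chr1"][1])  # masked in one input


class TestRegionMeanSignal:
    def test_constant_track(self, layout):
        track = BinnedTrack.constant(layout, 1_000, 0.7)
        regions = merge([("chr1", 100, 5_000), ("chr1", 60_000, 61_000)], layout)
        table, summary = region_mean_signal(track, regions)
        assert table["mean_signal"].to_numpy() == pytest.approx([0.7, 0.7])
        assert summary["mean"] == pytest.approx(0.7)

    def test_weighted_mean_matches_per_bp_oracle(self, layout):
        track = BinnedTrack.empty(layout, 1_000)
        track.values["chr1"][:3] = [1.0, 5.0, 9.0]
        # region covers 500 bp of bin0, all of bin1, 200 bp of bin2
        regions = merge([("chr1", 500, 2_200)], layout)
        table, _ = region_mean_signal(track, regions)
        oracle = (500 * 1.0 + 1_000 * 5.0 + 200 * 9.0) / 1_700
        assert table["mean_signal"].iloc[0] == pytest.approx(oracle)

    def test_region_without_data_is_missing(self, layout):
        track = BinnedTrack.empty(layout, 1_000)
        track.values["chr1"][0] = 1.0
        regions = merge([("chr1", 0, 1_000), ("chr1", 50_000, 51_000)], layout)
        table, summary = region_mean_signal(track, regions)
        assert np.isnan(table["mean_signal"].iloc[1])
        assert summary["n"] == 1

    def test_empty_regions_rejected(self, layout):
        track = BinnedTrack.constant(layout, 1_000, 0.0)
        with pytest.raises(ValueError):
            region_mean_signal(track, IntervalSet.empty(layout))

    def test_planted_group_gap_recovered(self):
        """LAD-high/i-LAD-low planted track: group means recover the gap."""
        n_bins = 10_000
        layout = GenomeLayout(("chr1",), (n_bins * 1_000,))
        rng = np.random.default_rng(17)
        lads = merge(
            [("chr1", s, s + 1_000_000) for s in range(0, n_bins * 1_000, 2_000_000)],
            layout,
        )
        track = BinnedTrack.empty(layout, 1_000)
        centers = np.arange(n_bins) * 1_000 + 500
        in_lad = np.zeros(n_bins, dtype=bool)
        for s, e in lads.segments_on("chr1"):
            in_lad |= (centers >= s) & (centers < e)
        track.values["chr1"] = np.where(in_lad, 0.5, -0.3) + rng.normal(0, 0.2, n_bins)
        _, lad_summary = region_mean_signal(track, lads)
        _, ilad_summary = region_mean_signal(track, lads.complement())
        assert lad_summary["mean"] - ilad_summary["mean"] == pytest.approx(0.8, abs=0.02)


class TestTssMetaprofile:
    def test_constant_track_flat_profile(self, layout):
        track = BinnedTrack.constant(layout, 50, 1.5)
        genes = [GeneRecord("g", "chr1", 50_000, 60_000, "+")]
        prof = tss_metaprofile(track, genes, 3_000, 50)
        assert prof.mean_signal == pytest.approx(np.full(120, 1.5))
        assert prof.n_anchors == 1
        # offsets symmetric around zero
        assert prof.offsets[0] == -prof.offsets[-1]

    def test_peak_at_plus_100_plus_strand(self, layout):
        track = BinnedTrack.empty(layout, 50)
        track.values["chr1"][:] = 0.0
        tss = 50_000
        track.values["chr1"][(tss + 100) // 50] = 10.0  # delta at TSS+100
        genes = [GeneRecord("g", "chr1", tss, 60_000, "+")]
        prof = tss_metaprofile(track, genes, 3_000, 50)
        peak_offset = prof.offsets[np.nanargmax(prof.mean_signal)]
        # the delta lands in the profile bin covering [+100, +150)
        assert peak_offset == pytest.approx(125)

    def test_peak_flips_on_minus_strand(self, layout):
        track = BinnedTrack.empty(layout, 50)
        track.values["chr1"][:] = 0.0
        tss = 50_000 - 1  # minus-strand gene ending at 50,000
        track.values["chr1"][(tss + 100) // 50] = 10.0
        genes = [GeneRecord("g", "chr1", 40_000, 50_000, "-")]
        prof = tss_metaprofile(track, genes, 3_000, 50)
        peak_offset = prof.offsets[np.nanargmax(prof.mean_signal)]
        assert -150 <= peak_offset <= -75

    def test_truncated_anchors_dropped_and_counted(self, layout):
        track = BinnedTrack.constant(layout, 50, 1.0)
        genes = [
            GeneRecord("edge", "chr1", 1_000, 5_000, "+"),  # window below 0
            GeneRecord("ok", "chr1", 50_000, 60_000, "+"),
        ]
        prof = tss_metaprofile(track, genes, 3_000, 50)
        assert prof.n_anchors == 1
        assert prof.n_dropped == 1

    def test_no_usable_anchors_rejected(self, layout):
        track = BinnedTrack.constant(layout, 50, 1.0)
        genes = [GeneRecord("edge", "chr1", 100, 5_000, "+")]
        with pytest.raises(ValueError, match="anchors"):
            tss_metaprofile(track, genes, 3_000, 50)

    def test_window_must_be_multiple_of_bin(self, layout):
        track = BinnedTrack.constant(layout, 50, 1.0)
        genes = [GeneRecord("g", "chr1", 50_000, 60_000, "+")]
        with pytest.raises(ValueError, match="multiple"):
            tss_metaprofile(track, genes, 3_001, 50)


class TestSubdomainPartition:
    def test_no_peaks_everything_non_h3k4me1(self, layout):
        clads = merge([("chr1", 0, 10_000)], layout)
        inside, outside = subdomain_partition(clads, [IntervalSet.empty(layout)])
        assert not inside
        assert outside == clads

    def test_full_peak_coverage(self, layout):
        clads = merge([("chr1", 0, 10_000)], layout)
        peaks = merge([("chr1", 0, 50_000)], layout)
        inside, outside = subdomain_partition(clads, [peaks])
        assert inside == clads
        assert not outside

    def test_toy_partition_and_conservation(self, layout):
        clads = merge([("chr1", 0, 1_000)], layout)
        peaks_t04 = merge([("chr1", 200, 300)], layout)
        inside, outside = subdomain_partition(
            clads, [IntervalSet.empty(layout), peaks_t04]
        )
        assert [(i.start, i.end) for i in inside] == [(200, 300)]
        assert [(i.start, i.end) for i in outside] == [(0, 200), (300, 1_000)]
        assert inside.total_bp + outside.total_bp == clads.total_bp
        assert inside.overlap_bp(outside) == 0
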