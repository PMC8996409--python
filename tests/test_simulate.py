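"""Synthetic-study generator: determinism, closure, and planted structure."""

from __future__ import annotations

import filecmp

import numpy as np
import pandas as pd
import pytest

from laddyn.annotation import (
    ILAD_LABEL,
    MULTI_CLASS,
    assign_genes,
    enhancer_status,
    flag_expressed,
)
from laddyn.dynamics import ChangeCategory, classify_changes
from laddyn.fate import CLASS_LABELS, build_lad_classes
from laddyn.genome import read_bed, read_chrom_sizes
from laddyn.lad_maps import binned_correlation, constitutive_lads
from laddyn.signal import read_bedgraph, region_mean_signal
from laddyn.simulate import (
    SimulationConfig,
    SyntheticTruth,
    simulate_lad_timeline,
    simulate_study,
    write_study,
)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_clads=6, n_gained_lads=3, n_lost_lads=2,
                               n_gained_edges=2, n_lost_edges=2, n_ilad_genes=20)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_study(simulate_study(cfg), d1)
        write_study(simulate_study(cfg), d2)
        for p1 in sorted(d1.rglob("*")):
            if p1.is_file():
                p2 = d2 / p1.relative_to(d1)
                assert filecmp.cmp(p1, p2, shallow=False), p1.name

    def test_different_seeds_differ(self):
        a, _, _ = simulate_lad_timeline(SimulationConfig(seed=1))
        b, _, _ = simulate_lad_timeline(SimulationConfig(seed=2))
        assert a["T00"] != b["T00"]


class TestPlantedTimeline:
    def test_zero_jitter_replicates_equal_truth(self, noiseless_study):
        b = noiseless_study
        for tp in b.timeline.time_points:
            for rep in b.replicate_calls[tp]:
                assert rep == b.timeline[tp]

    def test_classification_recovers_planted_categories(self, noiseless_study):
        b = noiseless_study
        part = classify_changes(b.timeline["T00"], b.timeline["T24"], b.layout)
        for cat in ChangeCategory:
            assert part[cat] == b.truth.category_regions[cat]

    def test_fate_recovers_planted_classes(self, noiseless_study):
        b = noiseless_study
        part = classify_changes(b.timeline["T00"], b.timeline["T24"], b.layout)
        classes = build_lad_classes(part, b.timeline["T72"], mode="split")
        for lbl in CLASS_LABELS:
            assert classes[lbl] == b.truth.class_regions[lbl]

    def test_category_regions_partition_genome(self, default_study):
        total = sum(
            s.total_bp for s in default_study.truth.category_regions.values()
        )
        assert total == default_study.layout.total_bp

    def test_genome_too_small_raises(self):
        cfg = SimulationConfig(seed=0, chrom_length_bp=1_000_000)
        with pytest.raises(ValueError, match="too small"):
            simulate_lad_timeline(cfg)

    def test_jittered_recovery_stays_high(self, default_study):
        b = default_study
        mt = b.merged_timeline()
        part = classify_changes(mt["T00"], mt["T24"], b.layout)
        agree = sum(
            part[c].overlap_bp(b.truth.category_regions[c]) for c in ChangeCategory
        )
        assert agree / b.layout.total_bp >= 0.95


class TestGenesAndExpression:
    def test_gene_assignment_recovers_truth(self, noiseless_study):
        b = noiseless_study
        part = classify_changes(b.timeline["T00"], b.timeline["T24"], b.layout)
        classes = build_lad_classes(part, b.timeline["T72"], mode="split")
        assign = assign_genes(b.genes, classes)["assignment"]
        truth = b.truth.genes.set_index("gene_id")["truth_class"]
        assert (assign == truth.reindex(assign.index)).all()

    def test_multiclass_genes_planted_and_detected(self, noiseless_study):
        truth = noiseless_study.truth.genes
        assert (truth["truth_class"] == MULTI_CLASS).sum() >= 1

    def test_escapers_pass_expressed_threshold(self, noiseless_study):
        b = noiseless_study
        flags = flag_expressed(b.expression)
        escapers = b.truth.genes.loc[b.truth.genes["escaper"], "gene_id"]
        assert flags.loc[escapers].all()

    def test_silent_lad_genes_never_reach_threshold(self, noiseless_study):
        b = noiseless_study
        genes = b.truth.genes
        silent = genes.loc[
            ~genes["expressed"] & (genes["truth_class"] != ILAD_LABEL),
            "gene_id",
        ]
        assert not flag_expressed(b.expression).loc[silent].any()

    def test_wave_gene_zscore_peaks_at_scripted_time_point(self, noiseless_study):
        from laddyn.annotation import expression_zscores

        b = noiseless_study
        z = expression_zscores(b.expression)
        genes = b.truth.genes
        up_waves = genes[(genes["de"]) & (genes["de_direction"] == 1)]
        hits = 0
        for g in up_waves.itertuples(index=False):
            peak_idx = int(np.argmax(z.loc[g.gene_id].to_numpy()))
            hits += peak_idx == g.peak_tp_index
        assert hits == len(up_waves)

    def test_de_flags_match_planted(self, noiseless_study):
        b = noiseless_study
        truth_de = b.truth.genes.set_index("gene_id")["de"]
        assert (b.expression.de_flags == truth_de.reindex(
            b.expression.de_flags.index)).all()


class TestEnhancers:
    def test_statuses_consistent_with_timeline(self, noiseless_study):
        b = noiseless_study
        clads = constitutive_lads(b.timeline)
        for rec, row in zip(
            b.enhancers, b.truth.enhancers.itertuples(index=False)
        ):
            status, _ = enhancer_status(rec, b.timeline, clads)
            assert status == row.status

    def test_mean_absolute_distance_near_configured(self, default_study):
        d = default_study.truth.enhancers["signed_distance_bp"]
        cfg = default_study.config
        # co-partition clamping shortens some distances; the mean stays in range
        assert 0.3 * cfg.enhancer_distance_mean_bp <= d.abs().mean() \
            <= 1.7 * cfg.enhancer_distance_mean_bp

    def test_every_enhancer_targets_a_de_gene(self, default_study):
        b = default_study
        de_ids = set(b.truth.genes.loc[b.truth.genes["de"], "gene_id"])
        for rec in b.enhancers:
            assert set(rec.target_gene_ids) <= de_ids


class TestTracks:
    def test_zero_noise_recovers_planted_means(self, noiseless_study):
        b = noiseless_study
        cfg = b.config
        lads = b.timeline["T00"]
        track = b.tracks["lmnb1"]["T00"][0]
        # away from escaper dips the LAD mean is exactly mu_lad
        dipless = lads.subtract(
            b.truth.category_regions[ChangeCategory.ILAD]
        )
        _, summary = region_mean_signal(track, lads)
        assert abs(summary["mean"] - cfg.lmnb1_mu_lad) < 0.05  # dips pull it down

    def test_escaper_tss_bins_lower_than_flanks(self, noiseless_study):
        b = noiseless_study
        track = b.tracks["lmnb1"]["T00"][0]
        cfg = b.config
        esc = b.truth.genes[b.truth.genes["escaper"]]
        for g in esc.head(5).itertuples(index=False):
            tss = g.start if g.strand == "+" else g.end - 1
            dip_bin = tss // cfg.track_bin_bp
            flank_bin = (tss + 3 * cfg.dip_halfwidth_bp) // cfg.track_bin_bp
            vals = track.values[g.chrom]
            assert vals[dip_bin] < vals[flank_bin]

    def test_replicate_tracks_highly_correlated(self, default_study):
        b = default_study
        r1, r2 = b.tracks["lmnb1"]["T00"]
        assert binned_correlation(r1, r2, 100_000) > 0.9


class TestRoundTrip:
    def test_emitted_files_roundtrip_through_readers(self, tmp_path, noiseless_study):
        b = noiseless_study
        paths = write_study(b, tmp_path)
        layout = read_chrom_sizes(paths["chrom_sizes"])
        assert layout == b.layout
        for tp in b.timeline.time_points:
            for r, p in enumerate(paths["lads"][tp]):
                assert read_bed(p, layout) == b.replicate_calls[tp][r]
        track = read_bedgraph(
            paths["tracks"]["h3k9me3"]["T00"], layout, b.config.track_bin_bp
        )
        orig = b.tracks["h3k9me3"]["T00"]
        for chrom in layout.chrom_names:
            assert track.values[chrom] == pytest.approx(
                orig.values[chrom], rel=1e-4, abs=1e-4
            )

    def test_truth_json_roundtrip(self, tmp_path, noiseless_study):
        b = noiseless_study
        p = tmp_path / "truth.json"
        b.truth.to_json(p)
        back = SyntheticTruth.from_json(p)
        assert back.config == b.config
        for cat, iset in b.truth.category_regions.items():
            assert back.category_regions[cat] == iset
        pd.testing.assert_frame_equal(back.genes, b.truth.genes)
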