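"""Gene/enhancer assignment rules, expression statistics, exact tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from laddyn.annotation import (
    ILAD_LABEL,
    MULTI_CLASS,
    EnhancerRecord,
    ExpressionMatrix,
    GeneRecord,
    assign_genes,
    category_foldchange_test,
    coverage_fisher,
    enhancer_gene_distance,
    enhancer_partition,
    enhancer_status,
    expression_zscores,
    fisher_2x2,
    flag_expressed,
    group_welch_test,
    read_genes_bed6,
)
from laddyn.dynamics import classify_changes
from laddyn.fate import CLASS_LABELS, build_lad_classes
from laddyn.genome import GenomeLayout, IntervalSet, merge
from laddyn.lad_maps import LADTimeline


@pytest.fixture
def layout():
    return GenomeLayout(("chr1",), (1_000_000,))


@pytest.fixture
def toy_classes(layout):
    """Common>LAD on [100, 200); Gained edge>LAD on [200, 300) (in bp*1000)."""
    lads_from = merge([("chr1", 100_000, 200_000)], layout)
    lads_to = merge([("chr1", 100_000, 300_000)], layout)
    partition = classify_changes(lads_from, lads_to, layout)
    return build_lad_classes(partition, lads_to)


class TestAssignGenes:
    def test_gene_inside_single_class(self, layout, toy_classes):
        genes = [GeneRecord("g1", "chr1", 120_000, 180_000, "+")]
        out = assign_genes(genes, toy_classes)
        assert out.loc["g1", "assignment"] == "Common>LAD"

    def test_gene_spanning_two_classes_removed(self, layout, toy_classes):
        genes = [GeneRecord("g2", "chr1", 190_000, 260_000, "+")]
        out = assign_genes(genes, toy_classes)
        assert out.loc["g2", "assignment"] == MULTI_CLASS

    def test_gene_outside_all_classes_is_ilad(self, layout, toy_classes):
        genes = [GeneRecord("g3", "chr1", 500_000, 510_000, "-")]
        out = assign_genes(genes, toy_classes)
        assert out.loc["g3", "assignment"] == ILAD_LABEL

    def test_one_bp_touch_suffices(self, layout, toy_classes):
        genes = [GeneRecord("g4", "chr1", 99_000, 100_001, "+")]
        out = assign_genes(genes, toy_classes)
        assert out.loc["g4", "assignment"] == "Common>LAD"

    def test_duplicate_gene_ids_rejected(self, layout, toy_classes):
        genes = [
            GeneRecord("g", "chr1", 0, 10, "+"),
            GeneRecord("g", "chr1", 20, 30, "+"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            assign_genes(genes, toy_classes)

    def test_counts_are_exhaustive(self, layout, toy_classes):
        rng = np.random.default_rng(1)
        genes = [
            GeneRecord(
                f"g{i}", "chr1", s := int(rng.integers(0, 900_000)),
                s + int(rng.integers(1_000, 80_000)), "+",
            )
            for i in range(60)
        ]
        out = assign_genes(genes, toy_classes)
        assert len(out) == 60


class TestExpression:
    def _expr(self, rows, tps=("T00", "T24", "T72"), de=None):
        counts = pd.DataFrame(rows).T
        counts.columns = tps
        de = de or {}
        return ExpressionMatrix(
            counts, pd.Series({g: de.get(g, False) for g in counts.index})
        )

    def test_expressed_threshold_at_any_time_point(self):
        expr = self._expr({"a": [0, 3, 20], "b": [0, 0, 0], "c": [14.9, 14.9, 14.9]})
        flags = flag_expressed(expr)
        assert bool(flags["a"]) is True  # 20 >= 15
        assert bool(flags["b"]) is False
        assert bool(flags["c"]) is False  # strict threshold at 15

    def test_zscore_closed_form(self):
        expr = self._expr({"a": [10, 20, 30], "b": [7, 7, 7]})
        z = expression_zscores(expr)
        assert z.loc["a"].to_numpy() == pytest.approx(
            [-math.sqrt(3 / 2), 0.0, math.sqrt(3 / 2)]
        )  # population sd: [-1.2247, 0, 1.2247]
        assert (z.loc["b"] == 0).all()
        assert z.sum(axis=1).to_numpy() == pytest.approx([0, 0])

    def test_foldchange_arithmetic_and_t_test(self):
        expr = self._expr(
            {f"g{i}": [10, 40, 40] for i in range(10)},
            de={f"g{i}": True for i in range(10)},
        )
        assign = pd.Series({f"g{i}": "Common>LAD" for i in range(10)}, name="assignment")
        out = category_foldchange_test(expr, assign, "T00", "T24").set_index("class")
        assert out.loc["Common>LAD", "mean_log2fc"] == pytest.approx(
            math.log2(41 / 11)
        )
        # zero variance within the class: t-test omitted
        assert math.isnan(out.loc["Common>LAD", "p_one_sample_t"])

    def test_symmetric_foldchanges_not_significant(self):
        rows = {f"u{i}": [10, 20, 20] for i in range(5)}
        rows.update({f"d{i}": [20, 10, 10] for i in range(5)})
        expr = self._expr(rows, de={g: True for g in rows})
        assign = pd.Series({g: "Common>LAD" for g in rows}, name="assignment")
        out = category_foldchange_test(expr, assign, "T00", "T24").set_index("class")
        assert out.loc["Common>LAD", "mean_log2fc"] == pytest.approx(0.0)
        assert out.loc["Common>LAD", "p_one_sample_t"] == pytest.approx(1.0)

    def test_small_classes_report_nan_p(self):
        expr = self._expr({"a": [10, 40, 40], "b": [10, 30, 30]},
                          de={"a": True, "b": True})
        assign = pd.Series({"a": "Lost LAD>LAD", "b": "Lost LAD>LAD"}, name="assignment")
        out = category_foldchange_test(expr, assign, "T00", "T24").set_index("class")
        assert math.isnan(out.loc["Lost LAD>LAD", "p_one_sample_t"])

    def test_replicates_averaged_from_tsv(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text(
            "gene_id\tT00_rep1\tT00_rep2\tT24_rep1\tT24_rep2\tde\n"
            "g1\t10\t20\t30\t50\tTrue\n"
        )
        expr = ExpressionMatrix.from_tsv(p)
        assert expr.counts.loc["g1", "T00"] == 15
        assert expr.counts.loc["g1", "T24"] == 40
        assert bool(expr.de_flags["g1"])


class TestEnhancers:
    def test_signed_distance_plus_strand(self):
        gene = GeneRecord("g", "chr1", 10_000, 30_000, "+")
        enh = EnhancerRecord("e", "chr1", 11_000, 12_000, ("g",))
        assert enhancer_gene_distance(enh, gene) == 1_500  # downstream

    def test_signed_distance_minus_strand_flips(self):
        gene = GeneRecord("g", "chr1", 0, 10_001, "-")  # tss = 10,000
        enh = EnhancerRecord("e", "chr1", 11_000, 12_000, ("g",))
        assert enhancer_gene_distance(enh, gene) == -1_500  # upstream

    def test_enhancer_centered_on_tss(self):
        gene = GeneRecord("g", "chr1", 10_000, 30_000, "+")
        enh = EnhancerRecord("e", "chr1", 9_500, 10_500, ("g",))
        assert enhancer_gene_distance(enh, gene) == 0

    def test_trans_pair_rejected(self):
        layout = GenomeLayout(("chr1", "chr2"), (100_000, 100_000))
        gene = GeneRecord("g", "chr1", 10_000, 30_000, "+")
        enh = EnhancerRecord("e", "chr2", 11_000, 12_000, ("g",))
        with pytest.raises(ValueError, match="different chromosomes"):
            enhancer_gene_distance(enh, gene)

    def _timeline(self, layout):
        # cLAD [100k,200k); T24-only vLAD [400k,450k)
        t00 = merge([("chr1", 100_000, 200_000)], layout)
        t24 = merge([("chr1", 100_000, 200_000), ("chr1", 400_000, 450_000)], layout)
        t72 = merge([("chr1", 100_000, 200_000)], layout)
        return LADTimeline(["T00", "T24", "T72"], {"T00": t00, "T24": t24, "T72": t72})

    def test_status_clad_at_all_time_points(self, layout):
        tl = self._timeline(layout)
        from laddyn.lad_maps import constitutive_lads

        clads = constitutive_lads(tl)
        enh = EnhancerRecord("e", "chr1", 150_000, 151_000, ("g",))
        status, in_lad = enhancer_status(enh, tl, clads)
        assert status == "cLAD"
        assert all(in_lad.values())

    def test_status_vlad_when_gained_at_one_time_point(self, layout):
        tl = self._timeline(layout)
        from laddyn.lad_maps import constitutive_lads

        clads = constitutive_lads(tl)
        enh = EnhancerRecord("e", "chr1", 410_000, 411_000, ("g",))
        status, in_lad = enhancer_status(enh, tl, clads)
        assert status == "vLAD"
        assert in_lad == {"T00": False, "T24": True, "T72": False}

    def test_status_ilad_constant(self, layout):
        tl = self._timeline(layout)
        from laddyn.lad_maps import constitutive_lads

        clads = constitutive_lads(tl)
        enh = EnhancerRecord("e", "chr1", 700_000, 701_000, ("g",))
        status, in_lad = enhancer_status(enh, tl, clads)
        assert status == "i-LAD"
        assert not any(in_lad.values())

    def test_partition_drops_enhancers_without_targets(self, layout):
        tl = self._timeline(layout)
        lads_from, lads_to = tl["T00"], tl["T24"]
        classes = build_lad_classes(
            classify_changes(lads_from, lads_to, layout), tl["T72"]
        )
        genes = [GeneRecord("g1", "chr1", 150_000, 160_000, "+")]
        assign = assign_genes(genes, classes)
        enhancers = [
            EnhancerRecord("e1", "chr1", 150_500, 151_500, ("g1",)),
            EnhancerRecord("e2", "chr1", 700_000, 701_000, ("missing",)),
        ]
        per_enh, props = enhancer_partition(enhancers, tl, classes, assign)
        assert set(per_enh["enhancer_id"]) == {"e1"}
        row = props.set_index(["target_gene_class", "time_point"])
        assert row.loc[("Common>LAD", "T00"), "frac_in_lad"] == 1.0


def _fisher_two_tailed_oracle(a, b, c, d):
    """Exhaustive enumeration over tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    obs = math.comb(r1, a) * math.comb(r2, c) / math.comb(n, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        if p <= obs * (1 + 1e-9):
            total += p
    return total


class TestFisher:
    def test_balanced_table(self):
        res = fisher_2x2([[5, 5], [5, 5]])
        assert res["odds_ratio"] == 1.0
        assert res["p_two_tailed"] == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        res = fisher_2x2([[10, 0], [0, 10]])
        assert res["p_two_tailed"] == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2([[0, 0], [5, 5]])

    def test_haldane_correction_on_zero_cell(self):
        res = fisher_2x2([[10, 0], [5, 5]])
        assert res["odds_ratio"] == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 11, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = fisher_2x2([[a, b], [c, d]])
            oracle = _fisher_two_tailed_oracle(int(a), int(b), int(c), int(d))
            assert res["p_two_tailed"] == pytest.approx(oracle, rel=1e-6)

    def test_coverage_fisher_uses_units(self):
        res = coverage_fisher(5_000_000, 20_000_000, 1_000_000, 20_000_000)
        assert res["unit_bp"] == 100_000
        exact = fisher_2x2([[50, 150], [10, 190]])
        assert res["p_two_tailed"] == pytest.approx(exact["p_two_tailed"])


class TestWelch:
    def test_identical_two_groups_p_is_one(self):
        p = group_welch_test([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert p == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        assert group_welch_test([a, b]) < 1e-10

    def test_three_group_welch_anova_detects_shift(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 30) for m in (0, 0, 2)]
        assert group_welch_test(groups) < 1e-4

    def test_welch_anova_calibrated_under_null(self):
        """Rejection rate at alpha = 0.05 within the 99% binomial CI."""
        rng = np.random.default_rng(5)
        n_reps = 400
        rej = 0
        for _ in range(n_reps):
            groups = [rng.normal(0, s, 15) for s in (1.0, 2.0, 0.5)]
            rej += group_welch_test(groups) <= 0.05
        rate = rej / n_reps
        half = 2.576 * math.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            group_welch_test([[1.0]])
        with pytest.raises(ValueError):
            group_welch_test([[1.0, 1.0], [2.0, 2.0]])


def test_read_genes_bed6(tmp_path, layout):
    p = tmp_path / "genes.bed"
    p.write_text("chr1\t100\t500\tgeneA\t0\t+\nchr1\t900\t2000\tgeneB\t0\t-\n")
    genes = read_genes_bed6(p, layout)
    assert [g.gene_id for g in genes] == ["geneA", "geneB"]
    assert genes[0].tss == 100
    assert genes[1].tss == 1_999
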