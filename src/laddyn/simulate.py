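"""Synthetic study generator with planted ground truth.

Emulates a multi-chromosome genome carrying planted constitutive LADs,
stand-alone LAD gains/losses and edge extensions/shortenings between the
first two mapped time points, each with a scripted LAD vs i-LAD outcome at
the final time point; replicate LAD calls with boundary jitter; LAD-elevated
lamin B1 / H3K9me3 signal with local "escaper" dips at the TSS of
differentially expressed LAD genes; promoter/enhancer histone-PTM peaks; an
8-time-point expression matrix with DE waves; and enhancers linked to their
target genes at short signed distances. Every emitted file round-trips
through the package readers, and the planted labels are stored in a
:class:`SyntheticTruth` against which pipeline recovery is scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    MULTI_CLASS,
    ILAD_LABEL,
    EnhancerRecord,
    ExpressionMatrix,
    GeneRecord,
    enhancer_status,
)
from .dynamics import ChangeCategory
from .fate import class_label
from .genome import GenomeLayout, IntervalSet, write_bed, write_chrom_sizes
from .lad_maps import LADTimeline, constitutive_lads
from .signal import BinnedTrack

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "StudyBundle",
    "simulate_lad_timeline",
    "simulate_expression",
    "simulate_enhancers",
    "simulate_tracks",
    "simulate_study",
    "write_study",
]

PTM_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    Sizes follow log-normal distributions (median 500 kb for constitutive
    LADs, 150 kb for variable elements — variable LADs are smaller than
    common ones); replicate boundary jitter defaults to 5 kb sd; enhancer
    distances average 24 kb in absolute value with 42% placed downstream.
    """

    seed: int = 0
    n_chrom: int = 3
    chrom_length_bp: int = 30_000_000

    # planted LAD elements
    n_clads: int = 18
    n_gained_lads: int = 8
    n_lost_lads: int = 5
    n_gained_edges: int = 8
    n_lost_edges: int = 5
    clad_size_median_bp: int = 500_000
    vlad_size_median_bp: int = 150_000
    size_log_sd: float = 0.4
    min_spacing_bp: int = 10_000
    # probability that a planted element is in a LAD at the final time point
    t72_lad_prob_common: float = 0.9
    t72_lad_prob_variable: float = 0.5

    # replicate LAD calls
    n_replicates: int = 2
    replicate_jitter_sd_bp: float = 5_000.0
    lad_dropout_prob: float = 0.0

    # signal tracks
    track_bin_bp: int = 1_000
    lmnb1_mu_lad: float = 0.5
    lmnb1_mu_ilad: float = -0.3
    lmnb1_shared_sd: float = 0.2
    lmnb1_rep_sd: float = 0.05
    h3k9me3_mu_lad: float = 0.4
    h3k9me3_mu_ilad: float = -0.2
    h3k9me3_sd: float = 0.2
    dip_depth: float = 0.6
    dip_halfwidth_bp: int = 5_000
    ptm_baseline: float = 0.2
    ptm_noise_sd: float = 0.05
    ptm_peak_height: float = 3.0
    ptm_peak_halfwidth_bp: int = 1_000

    # genes and expression
    max_genes_per_element: int = 2
    n_ilad_genes: int = 120
    n_multiclass_genes: int = 2
    escaper_fraction: float = 0.15
    gene_min_bp: int = 5_000
    gene_max_bp: int = 30_000
    expressed_mean: float = 100.0
    silent_mean: float = 2.0
    escaper_mean: float = 60.0
    de_log2_amplitude: float = 2.0
    de_wave_width: float = 1.0  # in time-point index units
    nb_dispersion: float | None = 20.0  # None => noise-free rounded counts
    expressed_fraction_ilad: float = 0.8
    de_fraction_ilad: float = 0.3
    n_expr_replicates: int = 2
    time_points: tuple[str, ...] = (
        "T00", "T04", "T08", "T12", "T16", "T20", "T24", "T72",
    )
    lad_time_points: tuple[str, ...] = ("T00", "T24", "T72")

    # enhancers
    enhancers_min: int = 1
    enhancers_max: int = 5
    enhancer_distance_mean_bp: float = 24_000.0
    enhancer_p_downstream: float = 0.42
    enhancer_min_bp: int = 800
    enhancer_max_bp: int = 2_000
    copartition_frac: float = 0.7

    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chrom))
        return GenomeLayout(names, tuple([self.chrom_length_bp] * self.n_chrom))


@dataclass
class SyntheticTruth:
    """Planted labels and parameters, re-derivable from the emitted files."""

    config: SimulationConfig
    layout: GenomeLayout
    elements: pd.DataFrame  # element_id, category, chrom, start, end, t72_lad, class_label
    category_regions: dict[ChangeCategory, IntervalSet]
    class_regions: dict[str, IntervalSet]
    genes: pd.DataFrame | None = None
    enhancers: pd.DataFrame | None = None

    def gene_records(self) -> list[GeneRecord]:
        if self.genes is None:
            raise ValueError("genes not simulated yet")
        return [
            GeneRecord(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
            for r in self.genes.itertuples(index=False)
        ]

    def enhancer_records(self) -> list[EnhancerRecord]:
        if self.enhancers is None:
            raise ValueError("enhancers not simulated yet")
        return [
            EnhancerRecord(
                r.enhancer_id, r.chrom, int(r.start), int(r.end),
                tuple(r.target_gene_ids.split(",")),
            )
            for r in self.enhancers.itertuples(index=False)
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "layout": {
                "chrom_names": list(self.layout.chrom_names),
                "chrom_lengths": list(self.layout.chrom_lengths),
            },
            "elements": self.elements.to_dict(orient="records"),
            "category_regions": {
                cat.value: [[iv.chrom, iv.start, iv.end] for iv in iset]
                for cat, iset in self.category_regions.items()
            },
            "class_regions": {
                lbl: [[iv.chrom, iv.start, iv.end] for iv in iset]
                for lbl, iset in self.class_regions.items()
            },
            "genes": None if self.genes is None else self.genes.to_dict(orient="records"),
            "enhancers": (
                None if self.enhancers is None
                else self.enhancers.to_dict(orient="records")
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg_dict = payload["config"]
        for key in ("time_points", "lad_time_points"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = SimulationConfig(**cfg_dict)
        layout = GenomeLayout(
            tuple(payload["layout"]["chrom_names"]),
            tuple(payload["layout"]["chrom_lengths"]),
        )
        cat_regions = {
            ChangeCategory(k): IntervalSet.from_intervals(
                [(c, s, e) for c, s, e in v], layout
            )
            for k, v in payload["category_regions"].items()
        }
        class_regions = {
            k: IntervalSet.from_intervals([(c, s, e) for c, s, e in v], layout)
            for k, v in payload["class_regions"].items()
        }
        return cls(
            config=cfg,
            layout=layout,
            elements=pd.DataFrame(payload["elements"]),
            category_regions=cat_regions,
            class_regions=class_regions,
            genes=None if payload["genes"] is None else pd.DataFrame(payload["genes"]),
            enhancers=(
                None if payload["enhancers"] is None
                else pd.DataFrame(payload["enhancers"])
            ),
        )


# --------------------------------------------------------------------- #
# LAD timeline


def _draw_size(rng: np.random.Generator, median_bp: int, log_sd: float) -> int:
    return max(20_000, int(rng.lognormal(np.log(median_bp), log_sd)))


def _place_blocks(
    rng: np.random.Generator, cfg: SimulationConfig, block_sizes: list[int]
) -> list[tuple[str, int, int]]:
    """Place blocks on the genome, non-overlapping, >= min_spacing_bp apart."""
    layout = cfg.layout()
    order = rng.permutation(len(block_sizes))
    chrom_of = [layout.chrom_names[i % cfg.n_chrom] for i in range(len(block_sizes))]
    per_chrom: dict[str, list[int]] = {c: [] for c in layout.chrom_names}
    for idx in order:
        per_chrom[chrom_of[idx]].append(idx)
    placements: dict[int, tuple[str, int, int]] = {}
    for chrom, idxs in per_chrom.items():
        if not idxs:
            continue
        sizes = [block_sizes[i] for i in idxs]
        n = len(sizes)
        occupied = sum(sizes) + (n + 1) * cfg.min_spacing_bp
        free = layout.length(chrom) - occupied
        if free < 0:
            raise ValueError(
                f"genome too small: {chrom} needs {occupied} bp "
                f"for {n} planted blocks but has {layout.length(chrom)}"
            )
        cuts = np.sort(rng.random(n + 1))
        extra = np.diff(np.concatenate([[0.0], cuts / cuts[-1]])) * free
        pos = cfg.min_spacing_bp + int(extra[0])
        for k, i in enumerate(idxs):
            placements[i] = (chrom, pos, pos + sizes[k])
            pos += sizes[k] + cfg.min_spacing_bp + int(extra[k + 1]) if k + 1 < len(extra) else 0
    return [placements[i] for i in range(len(block_sizes))]


def _jitter_set(
    iset: IntervalSet,
    layout: GenomeLayout,
    rng: np.random.Generator,
    sd_bp: float,
    dropout_prob: float,
) -> IntervalSet:
    """Replicate LAD call: independent Gaussian jitter on each boundary,
    inverted segments repaired by swapping, plus optional whole-LAD dropout."""
    ivs = []
    for iv in iset:
        if dropout_prob > 0 and rng.random() < dropout_prob:
            continue
        s = iv.start + int(round(rng.normal(0, sd_bp))) if sd_bp > 0 else iv.start
        e = iv.end + int(round(rng.normal(0, sd_bp))) if sd_bp > 0 else iv.end
        if s > e:
            s, e = e, s
        length = layout.length(iv.chrom)
        s = max(0, min(s, length - 1))
        e = max(s + 1, min(e, length))
        ivs.append((iv.chrom, s, e))
    return IntervalSet.from_intervals(ivs, layout)


def simulate_lad_timeline(
    cfg: SimulationConfig,
) -> tuple[LADTimeline, dict[str, list[IntervalSet]], SyntheticTruth]:
    """Plant the LAD timeline and per-replicate LAD calls.

    Returns the truth timeline (keyed by the LAD time points), the
    per-time-point replicate call sets, and the SyntheticTruth carrying the
    per-base category and class labels.
    """
    root = np.random.SeedSequence(cfg.seed)
    rng_place, rng_script, rng_rep = [
        np.random.default_rng(s) for s in root.spawn(3)
    ]
    layout = cfg.layout()
    t0, t1, t2 = cfg.lad_time_points

    # block composition: (kind, sizes)
    blocks: list[tuple[str, list[int]]] = []
    for _ in range(cfg.n_clads):
        blocks.append(("clad", [_draw_size(rng_place, cfg.clad_size_median_bp, cfg.size_log_sd)]))
    for _ in range(cfg.n_gained_lads):
        blocks.append(("gained_lad", [_draw_size(rng_place, cfg.vlad_size_median_bp, cfg.size_log_sd)]))
    for _ in range(cfg.n_lost_lads):
        blocks.append(("lost_lad", [_draw_size(rng_place, cfg.vlad_size_median_bp, cfg.size_log_sd)]))
    for _ in range(cfg.n_gained_edges):
        blocks.append(
            ("gained_edge", [
                _draw_size(rng_place, cfg.clad_size_median_bp, cfg.size_log_sd),
                _draw_size(rng_place, cfg.vlad_size_median_bp, cfg.size_log_sd),
            ])
        )
    for _ in range(cfg.n_lost_edges):
        blocks.append(
            ("lost_edge", [
                _draw_size(rng_place, cfg.clad_size_median_bp, cfg.size_log_sd),
                _draw_size(rng_place, cfg.vlad_size_median_bp, cfg.size_log_sd),
            ])
        )
    placements = _place_blocks(rng_place, cfg, [sum(s) for _, s in blocks])

    element_rows = []
    eid = 0

    def add_element(category: ChangeCategory, chrom: str, s: int, e: int, t72: bool):
        nonlocal eid
        element_rows.append(
            {
                "element_id": f"el{eid:03d}",
                "category": category.value,
                "chrom": chrom,
                "start": int(s),
                "end": int(e),
                "t72_lad": bool(t72),
                "class_label": class_label(category, "LAD" if t72 else "i-LAD"),
            }
        )
        eid += 1

    for (kind, sizes), (chrom, bs, be) in zip(blocks, placements):
        if kind == "clad":
            t72 = rng_script.random() < cfg.t72_lad_prob_common
            add_element(ChangeCategory.COMMON, chrom, bs, be, t72)
        elif kind == "gained_lad":
            t72 = rng_script.random() < cfg.t72_lad_prob_variable
            add_element(ChangeCategory.GAINED_LAD, chrom, bs, be, t72)
        elif kind == "lost_lad":
            t72 = rng_script.random() < cfg.t72_lad_prob_variable
            add_element(ChangeCategory.LOST_LAD, chrom, bs, be, t72)
        else:
            core, edge = sizes
            edge_left = bool(rng_script.random() < 0.5)
            if edge_left:
                edge_iv, core_iv = (bs, bs + edge), (bs + edge, be)
            else:
                core_iv, edge_iv = (bs, bs + core), (bs + core, be)
            # the host core stays a LAD throughout
            add_element(ChangeCategory.COMMON, chrom, core_iv[0], core_iv[1], True)
            cat = (
                ChangeCategory.GAINED_EDGE if kind == "gained_edge"
                else ChangeCategory.LOST_EDGE
            )
            t72 = rng_script.random() < cfg.t72_lad_prob_variable
            add_element(cat, chrom, edge_iv[0], edge_iv[1], t72)

    elements = pd.DataFrame(element_rows)

    def regions(mask) -> IntervalSet:
        sub = elements[mask]
        return IntervalSet.from_intervals(
            [(r.chrom, r.start, r.end) for r in sub.itertuples(index=False)], layout
        )

    cat_of = elements["category"]
    category_regions = {
        cat: regions(cat_of == cat.value)
        for cat in (
            ChangeCategory.COMMON,
            ChangeCategory.GAINED_LAD,
            ChangeCategory.LOST_LAD,
            ChangeCategory.GAINED_EDGE,
            ChangeCategory.LOST_EDGE,
        )
    }
    footprint = IntervalSet.empty(layout)
    for iset in category_regions.values():
        footprint = footprint.union(iset)
    category_regions[ChangeCategory.ILAD] = footprint.complement()

    class_regions = {
        lbl: regions(elements["class_label"] == lbl)
        for lbl in {r["class_label"] for r in element_rows} | set()
    }
    from .fate import CLASS_LABELS

    for lbl in CLASS_LABELS:
        class_regions.setdefault(lbl, IntervalSet.empty(layout))

    t00 = regions(
        cat_of.isin(
            [ChangeCategory.COMMON.value, ChangeCategory.LOST_LAD.value,
             ChangeCategory.LOST_EDGE.value]
        )
    )
    t24 = regions(
        cat_of.isin(
            [ChangeCategory.COMMON.value, ChangeCategory.GAINED_LAD.value,
             ChangeCategory.GAINED_EDGE.value]
        )
    )
    t72 = regions(elements["t72_lad"])
    timeline = LADTimeline(
        time_points=[t0, t1, t2], lads_per_tp={t0: t00, t1: t24, t2: t72}
    )

    replicate_calls = {
        tp: [
            _jitter_set(
                timeline[tp], layout, rng_rep,
                cfg.replicate_jitter_sd_bp, cfg.lad_dropout_prob,
            )
            for _ in range(cfg.n_replicates)
        ]
        for tp in timeline.time_points
    }

    truth = SyntheticTruth(
        config=cfg,
        layout=layout,
        elements=elements,
        category_regions=category_regions,
        class_regions=class_regions,
    )
    return timeline, replicate_calls, truth


# --------------------------------------------------------------------- #
# genes and expression


def _place_genes_in_interval(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    chrom: str,
    lo: int,
    hi: int,
    n: int,
    margin: int = 1_000,
) -> list[tuple[int, int]]:
    """Up to n non-overlapping genes strictly inside [lo+margin, hi-margin)."""
    out: list[tuple[int, int]] = []
    cursor = lo + margin
    for _ in range(n):
        size = int(rng.integers(cfg.gene_min_bp, cfg.gene_max_bp + 1))
        space = hi - margin - cursor - size
        if space <= 0:
            break
        start = cursor + int(rng.integers(0, min(space, 50_000) + 1))
        out.append((start, start + size))
        cursor = start + size + 2_000
    return out


def simulate_expression(
    cfg: SimulationConfig, truth: SyntheticTruth
) -> ExpressionMatrix:
    """Place genes relative to the planted classes and draw expression counts.

    LAD-element genes are mostly silent; a fraction (the escapers) are DE
    with wave-shaped profiles peaking at a scripted time point and always
    satisfy the expressed threshold. i-LAD genes are mostly expressed, some
    DE. Counts are negative-binomial per replicate (or noise-free rounded
    means when ``nb_dispersion`` is None); the stored matrix averages
    replicates. Gene truth labels are recorded in ``truth.genes``.
    """
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root.spawn(5)[3])
    layout = truth.layout
    gene_rows = []
    gid = 0

    def add_gene(chrom, s, e, truth_class, escaper, expressed, de):
        nonlocal gid
        strand = "+" if rng.random() < 0.5 else "-"
        peak = int(rng.integers(1, len(cfg.time_points))) if de else -1
        direction = 1 if (escaper or rng.random() < 0.5) else -1
        gene_rows.append(
            {
                "gene_id": f"g{gid:04d}",
                "chrom": chrom,
                "start": int(s),
                "end": int(e),
                "strand": strand,
                "truth_class": truth_class,
                "escaper": bool(escaper),
                "expressed": bool(expressed),
                "de": bool(de),
                "peak_tp_index": peak,
                "de_direction": int(direction) if de else 0,
            }
        )
        gid += 1

    # genes inside planted elements
    for el in truth.elements.itertuples(index=False):
        n = int(rng.integers(1, cfg.max_genes_per_element + 1))
        for s, e in _place_genes_in_interval(rng, cfg, el.chrom, el.start, el.end, n):
            escaper = rng.random() < cfg.escaper_fraction
            add_gene(
                el.chrom, s, e, el.class_label,
                escaper=escaper, expressed=escaper, de=escaper,
            )

    # genes straddling a class boundary (removed by the multi-class rule)
    hosts = truth.elements[
        truth.elements["category"].isin(["gained_edge", "lost_edge"])
    ]
    for el in hosts.head(cfg.n_multiclass_genes).itertuples(index=False):
        # straddle the boundary shared with the adjacent host core
        commons = truth.elements[truth.elements["category"] == "common"]
        if ((commons["chrom"] == el.chrom) & (commons["end"] == el.start)).any():
            boundary = el.start
        elif ((commons["chrom"] == el.chrom) & (commons["start"] == el.end)).any():
            boundary = el.end
        else:
            continue
        half = min(5_000, el.end - el.start - 1)
        add_gene(
            el.chrom, boundary - half, boundary + half, MULTI_CLASS,
            escaper=False, expressed=False, de=False,
        )

    # i-LAD genes, placed away from every planted element
    ilad = truth.category_regions[ChangeCategory.ILAD]
    big = [iv for iv in ilad if iv.length > cfg.gene_max_bp + 30_000]
    for _ in range(cfg.n_ilad_genes):
        iv = big[int(rng.integers(0, len(big)))]
        placed = _place_genes_in_interval(
            rng, cfg, iv.chrom,
            int(rng.integers(iv.start, iv.end - cfg.gene_max_bp - 10_000)),
            iv.end, 1, margin=5_000,
        )
        if not placed:
            continue
        s, e = placed[0]
        expressed = rng.random() < cfg.expressed_fraction_ilad
        de = expressed and rng.random() < cfg.de_fraction_ilad
        add_gene(iv.chrom, s, e, ILAD_LABEL, escaper=False, expressed=expressed, de=de)

    genes = pd.DataFrame(gene_rows)
    truth.genes = genes

    # expression counts
    tps = list(cfg.time_points)
    n_tp = len(tps)
    means = np.zeros((len(genes), n_tp))
    for i, g in enumerate(genes.itertuples(index=False)):
        if g.escaper:
            base = cfg.escaper_mean
        elif g.expressed:
            base = cfg.expressed_mean * float(rng.lognormal(0, 0.3))
        else:
            base = cfg.silent_mean
        profile = np.full(n_tp, base)
        if g.de:
            idx = np.arange(n_tp)
            wave = np.exp(-((idx - g.peak_tp_index) ** 2) / (2 * cfg.de_wave_width**2))
            profile = base * 2.0 ** (g.de_direction * cfg.de_log2_amplitude * wave)
        means[i] = profile

    reps = []
    for _ in range(cfg.n_expr_replicates):
        if cfg.nb_dispersion is None:
            counts = np.round(means)
        else:
            r = cfg.nb_dispersion
            p = r / (r + means)
            counts = rng.negative_binomial(r, p)
        reps.append(counts.astype(float))
    avg = np.mean(reps, axis=0)
    counts_df = pd.DataFrame(avg, index=genes["gene_id"], columns=tps)
    de_flags = pd.Series(genes["de"].to_numpy(), index=genes["gene_id"])
    expr = ExpressionMatrix(counts_df, de_flags)
    expr.replicate_counts = {  # type: ignore[attr-defined]
        k: pd.DataFrame(reps[k], index=genes["gene_id"], columns=tps)
        for k in range(cfg.n_expr_replicates)
    }
    return expr


# --------------------------------------------------------------------- #
# enhancers


def simulate_enhancers(
    cfg: SimulationConfig, truth: SyntheticTruth, timeline: LADTimeline
) -> list[EnhancerRecord]:
    """Attach 1-5 enhancers to each DE gene at short signed distances.

    |distance| is exponential with the configured mean; the sign is
    downstream with probability ``enhancer_p_downstream``. A configurable
    fraction of enhancers of LAD-class genes is forced inside the gene's
    planted element so that it co-partitions with its target; the rest land
    wherever the drawn distance puts them. Truth statuses (vLAD/cLAD/i-LAD
    at each time point) are recorded in ``truth.enhancers``.
    """
    if truth.genes is None:
        raise ValueError("simulate genes/expression before enhancers")
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root.spawn(5)[4])
    layout = truth.layout
    clads = constitutive_lads(timeline)
    elements = truth.elements
    rows = []
    records = []
    eid = 0
    for g in truth.genes[truth.genes["de"]].itertuples(index=False):
        tss = g.start if g.strand == "+" else g.end - 1
        n_enh = int(rng.integers(cfg.enhancers_min, cfg.enhancers_max + 1))
        for _ in range(n_enh):
            width = int(rng.integers(cfg.enhancer_min_bp, cfg.enhancer_max_bp + 1))
            dist = float(rng.exponential(cfg.enhancer_distance_mean_bp))
            sign = 1 if rng.random() < cfg.enhancer_p_downstream else -1
            d = sign * dist
            center = int(tss + d) if g.strand == "+" else int(tss - d)
            copart = rng.random() < cfg.copartition_frac
            if copart and g.truth_class not in (ILAD_LABEL, MULTI_CLASS):
                el = elements[
                    (elements["chrom"] == g.chrom)
                    & (elements["start"] <= g.start)
                    & (elements["end"] >= g.end)
                ]
                if len(el):
                    lo = int(el["start"].iloc[0]) + width
                    hi = int(el["end"].iloc[0]) - width
                    center = max(lo, min(center, hi))
            length = layout.length(g.chrom)
            start = max(0, min(center - width // 2, length - width))
            end = start + width
            rec = EnhancerRecord(
                f"enh{eid:04d}", g.chrom, start, end, (g.gene_id,)
            )
            status, in_lad = enhancer_status(rec, timeline, clads)
            row = {
                "enhancer_id": rec.enhancer_id,
                "chrom": g.chrom,
                "start": start,
                "end": end,
                "target_gene_ids": g.gene_id,
                "status": status,
                "signed_distance_bp": (
                    rec.center - tss if g.strand == "+" else tss - rec.center
                ),
            }
            row.update({f"in_lad_{tp}": in_lad[tp] for tp in timeline.time_points})
            rows.append(row)
            records.append(rec)
            eid += 1
    truth.enhancers = pd.DataFrame(rows)
    return records


# --------------------------------------------------------------------- #
# tracks


def _bin_centers_mask(
    layout: GenomeLayout, bin_bp: int, regions: IntervalSet, chrom: str, n_bins: int
) -> np.ndarray:
    """Boolean per-bin mask: bin center inside regions."""
    centers = np.arange(n_bins) * bin_bp + bin_bp // 2
    mask = np.zeros(n_bins, dtype=bool)
    for s, e in regions.segments_on(chrom):
        mask |= (centers >= s) & (centers < e)
    return mask


def simulate_tracks(
    cfg: SimulationConfig, truth: SyntheticTruth, timeline: LADTimeline
) -> dict:
    """Simulate lamin B1 / H3K9me3 log2-ratio tracks and PTM count tracks.

    Lamin B1 bins are Normal(mu_LAD, sd) inside the time point's LADs and
    Normal(mu_iLAD, sd) outside, with a per-time-point latent field shared
    between replicates (plus small replicate noise) so replicate
    correlations are high by construction. Around each escaper-gene TSS the
    lamin B1 and H3K9me3 means are lowered by ``dip_depth`` (the planted
    low-lamin sub-domain), and promoter/enhancer PTM peaks are planted as
    Gaussian bumps with matching BED peak calls.

    Returns {"lmnb1": {tp: [rep tracks]}, "h3k9me3": {tp: track},
    "ptm": {mark: {tp: track}}, "peaks": {mark: {tp: IntervalSet}}}.
    """
    if truth.genes is None:
        raise ValueError("simulate genes/expression before tracks")
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root.spawn(5)[2])
    layout = truth.layout
    b = cfg.track_bin_bp

    escapers = truth.genes[truth.genes["escaper"]]
    expressed_ilad = truth.genes[
        truth.genes["expressed"] & (truth.genes["truth_class"] == ILAD_LABEL)
    ]

    def tss_of(g) -> int:
        return g.start if g.strand == "+" else g.end - 1

    # dip mask (escaper TSS +/- halfwidth), shared across time points
    dip_regions = IntervalSet.from_intervals(
        [
            (g.chrom,
             max(0, tss_of(g) - cfg.dip_halfwidth_bp),
             min(layout.length(g.chrom), tss_of(g) + cfg.dip_halfwidth_bp))
            for g in escapers.itertuples(index=False)
        ],
        layout,
    )

    out: dict = {"lmnb1": {}, "h3k9me3": {}, "ptm": {m: {} for m in PTM_MARKS},
                 "peaks": {m: {} for m in PTM_MARKS}}

    for tp in timeline.time_points:
        lads = timeline[tp]
        reps = [BinnedTrack.empty(layout, b) for _ in range(cfg.n_replicates)]
        k9 = BinnedTrack.empty(layout, b)
        for chrom in layout.chrom_names:
            n_bins = len(reps[0].values[chrom])
            in_lad = _bin_centers_mask(layout, b, lads, chrom, n_bins)
            in_dip = _bin_centers_mask(layout, b, dip_regions, chrom, n_bins)
            mu = np.where(in_lad, cfg.lmnb1_mu_lad, cfg.lmnb1_mu_ilad)
            mu = mu - cfg.dip_depth * in_dip
            shared = rng.normal(0, cfg.lmnb1_shared_sd, n_bins)
            for r in range(cfg.n_replicates):
                noise = (
                    rng.normal(0, cfg.lmnb1_rep_sd, n_bins)
                    if cfg.lmnb1_rep_sd > 0 else 0.0
                )
                reps[r].values[chrom] = mu + shared + noise
            mu9 = np.where(in_lad, cfg.h3k9me3_mu_lad, cfg.h3k9me3_mu_ilad)
            mu9 = mu9 - cfg.dip_depth * in_dip
            noise9 = rng.normal(0, cfg.h3k9me3_sd, n_bins) if cfg.h3k9me3_sd > 0 else 0.0
            k9.values[chrom] = mu9 + noise9
        out["lmnb1"][tp] = reps
        out["h3k9me3"][tp] = k9

    # PTM peak sites: escaper promoters (all marks), expressed i-LAD
    # promoters (H3K4me3/H3K27ac), enhancers (H3K4me1/H3K27ac)
    sites: dict[str, list[tuple[str, int]]] = {m: [] for m in PTM_MARKS}
    for g in escapers.itertuples(index=False):
        for m in PTM_MARKS:
            sites[m].append((g.chrom, tss_of(g)))
    for g in expressed_ilad.itertuples(index=False):
        for m in ("H3K4me3", "H3K27ac"):
            sites[m].append((g.chrom, tss_of(g)))
    if truth.enhancers is not None:
        for e in truth.enhancers.itertuples(index=False):
            for m in ("H3K4me1", "H3K27ac"):
                sites[m].append((e.chrom, (e.start + e.end) // 2))

    hw = cfg.ptm_peak_halfwidth_bp
    for mark in PTM_MARKS:
        peak_set = IntervalSet.from_intervals(
            [
                (c, max(0, p - hw), min(layout.length(c), p + hw))
                for c, p in sites[mark]
            ],
            layout,
        )
        for tp in timeline.time_points:
            track = BinnedTrack.empty(layout, b)
            for chrom in layout.chrom_names:
                n_bins = len(track.values[chrom])
                base = np.abs(
                    cfg.ptm_baseline
                    + (rng.normal(0, cfg.ptm_noise_sd, n_bins)
                       if cfg.ptm_noise_sd > 0 else 0.0)
                )
                centers = np.arange(n_bins) * b + b // 2
                for c, p in sites[mark]:
                    if c != chrom:
                        continue
                    base = base + cfg.ptm_peak_height * np.exp(
                        -((centers - p) ** 2) / (2.0 * hw**2)
                    )
                track.values[chrom] = base
            out["ptm"][mark][tp] = track
            out["peaks"][mark][tp] = peak_set
    return out


# --------------------------------------------------------------------- #
# full study


@dataclass
class StudyBundle:
    """In-memory synthetic study: truth, timeline, replicate calls, data."""

    config: SimulationConfig
    layout: GenomeLayout
    truth: SyntheticTruth
    timeline: LADTimeline  # truth LADs
    replicate_calls: dict[str, list[IntervalSet]]
    expression: ExpressionMatrix
    enhancers: list[EnhancerRecord]
    tracks: dict

    @property
    def genes(self) -> list[GeneRecord]:
        return self.truth.gene_records()

    def merged_timeline(self) -> LADTimeline:
        """Replicate-union LAD maps, as the pipeline would build them."""
        from .lad_maps import merge_replicates

        return LADTimeline(
            time_points=list(self.timeline.time_points),
            lads_per_tp={
                tp: merge_replicates(self.replicate_calls[tp])
                for tp in self.timeline.time_points
            },
        )


def simulate_study(cfg: SimulationConfig) -> StudyBundle:
    """Run all simulation stages in order; deterministic given cfg.seed."""
    timeline, replicate_calls, truth = simulate_lad_timeline(cfg)
    expression = simulate_expression(cfg, truth)
    enhancers = simulate_enhancers(cfg, truth, timeline)
    tracks = simulate_tracks(cfg, truth, timeline)
    return StudyBundle(
        config=cfg,
        layout=truth.layout,
        truth=truth,
        timeline=timeline,
        replicate_calls=replicate_calls,
        expression=expression,
        enhancers=enhancers,
        tracks=tracks,
    )


def write_study(bundle: StudyBundle, outdir: str | Path) -> dict[str, object]:
    """Emit the study as plain-text files; returns the path manifest."""
    outdir = Path(outdir)
    (outdir / "lads").mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    cfg = bundle.config
    paths: dict[str, object] = {}

    write_chrom_sizes(bundle.layout, outdir / "chrom.sizes")
    paths["chrom_sizes"] = str(outdir / "chrom.sizes")

    lad_paths: dict[str, list[str]] = {}
    for tp in bundle.timeline.time_points:
        rep_paths = []
        for r, iset in enumerate(bundle.replicate_calls[tp]):
            p = outdir / "lads" / f"{tp}_rep{r + 1}.bed"
            write_bed(iset, p)
            rep_paths.append(str(p))
        lad_paths[tp] = rep_paths
        truth_p = outdir / "lads" / f"{tp}_truth.bed"
        write_bed(bundle.timeline[tp], truth_p)
    paths["lads"] = lad_paths

    track_paths: dict[str, object] = {"lmnb1": {}, "h3k9me3": {}, "ptm": {}}
    for tp, reps in bundle.tracks["lmnb1"].items():
        track_paths["lmnb1"][tp] = []
        for r, track in enumerate(reps):
            p = outdir / "tracks" / f"lmnb1_{tp}_rep{r + 1}.bedgraph"
            track.to_bedgraph(p)
            track_paths["lmnb1"][tp].append(str(p))
    for tp, track in bundle.tracks["h3k9me3"].items():
        p = outdir / "tracks" / f"h3k9me3_{tp}.bedgraph"
        track.to_bedgraph(p)
        track_paths["h3k9me3"][tp] = str(p)
    for mark, per_tp in bundle.tracks["ptm"].items():
        track_paths["ptm"][mark] = {}
        for tp, track in per_tp.items():
            p = outdir / "tracks" / f"{mark}_{tp}.bedgraph"
            track.to_bedgraph(p)
            track_paths["ptm"][mark][tp] = str(p)
    paths["tracks"] = track_paths

    peak_paths: dict[str, dict[str, str]] = {}
    for mark, per_tp in bundle.tracks["peaks"].items():
        peak_paths[mark] = {}
        for tp, iset in per_tp.items():
            p = outdir / "peaks" / f"{mark}_{tp}.bed"
            write_bed(iset, p)
            peak_paths[mark][tp] = str(p)
    paths["peaks"] = peak_paths

    genes_p = outdir / "genes.bed"
    with open(genes_p, "w") as fh:
        for g in bundle.truth.genes.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    paths["genes"] = str(genes_p)

    enh_p = outdir / "enhancers.tsv"
    bundle.truth.enhancers[
        ["enhancer_id", "chrom", "start", "end", "target_gene_ids"]
    ].to_csv(enh_p, sep="\t", index=False)
    paths["enhancers"] = str(enh_p)

    expr_p = outdir / "expression.tsv"
    rep_counts = bundle.expression.replicate_counts  # type: ignore[attr-defined]
    wide = pd.concat(
        {f"rep{k + 1}": rep_counts[k] for k in sorted(rep_counts)}, axis=1
    )
    wide.columns = [f"{tp}_rep{rep[3:]}" for rep, tp in wide.columns]
    wide["de"] = bundle.expression.de_flags
    wide.index.name = "gene_id"
    wide.to_csv(expr_p, sep="\t")
    paths["expression"] = str(expr_p)

    truth_p = outdir / "truth.json"
    bundle.truth.to_json(truth_p)
    paths["truth"] = str(truth_p)
    return paths
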