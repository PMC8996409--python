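"""Config-driven orchestration of the full LAD-dynamics analysis.

Stage order: replicate merge and timeline QC -> change classification
(first to second time point) -> ten-class fate (vs the final time point)
-> O/E permutation tests -> gene/expression annotation -> enhancer analyses
-> signal profiles. Every artifact is written under the output directory
and hashed into ``manifest.json`` (inputs, parameters, seed, version, file
digests); reruns with the same config and seed are byte-identical. Optional
inputs (enhancers, tracks, peaks) that are absent skip their stages with a
warning instead of failing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    ExpressionMatrix,
    assign_genes,
    category_foldchange_test,
    enhancer_partition,
    enhancer_gene_distance,
    expression_zscores,
    flag_expressed,
    read_enhancers_tsv,
    read_genes_bed6,
    read_genes_gtf,
)
from .dynamics import LAD_CATEGORIES, ChangeCategory, category_summary, classify_changes
from .fate import CLASS_LABELS, build_lad_classes, flow_table
from .genome import GenomeLayout, IntervalSet, read_bed, read_chrom_sizes
from .lad_maps import LADTimeline, binned_correlation, constitutive_lads, merge_replicates
from .permutation import run_family
from .signal import (
    average_tracks,
    read_bedgraph,
    region_mean_signal,
    subdomain_partition,
    tss_metaprofile,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunParams:
    bin_bp: int = 100_000
    track_bin_bp: int = 1_000
    n_perm: int = 50
    n_perm_external: int = 250
    seed: int = 0
    fate_mode: str = "split"
    frac_threshold: float = 0.5
    min_overlap_bp: int = 0
    expressed_threshold: float = 15.0
    pseudocount: float = 1.0
    fisher_unit_bp: int = 100_000
    half_window_bp: int = 3_000
    profile_bin_bp: int = 50


@dataclass
class RunConfig:
    chrom_sizes: str
    time_points: list[str]
    lads: dict[str, list[str]]  # time point -> replicate BED paths
    outdir: str
    genes: str | None = None
    genes_format: str = "bed6"  # or "gtf"
    expression: str | None = None
    enhancers: str | None = None
    lads_external: str | None = None  # e.g. proliferating-cell LAD BED
    tracks: dict[str, Any] = field(default_factory=dict)
    peaks: dict[str, Any] = field(default_factory=dict)
    params: RunParams = field(default_factory=RunParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = RunParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def validate(self) -> None:
        if len(self.time_points) < 2:
            raise ValueError("need >= 2 time points for dynamics")
        for tp in self.time_points:
            if tp not in self.lads:
                raise ValueError(f"no LAD replicate files for time point {tp}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    return path


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the manifest dictionary."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    results: dict[str, Any] = {}
    stage = "setup"

    def track_out(path: Path) -> Path:
        outputs.append(path)
        return path

    try:
        stage = "load"
        layout = read_chrom_sizes(cfg.chrom_sizes)
        rep_sets = {
            tp: [read_bed(p, layout) for p in cfg.lads[tp]]
            for tp in cfg.time_points
        }

        stage = "lad_maps"
        timeline = LADTimeline(
            time_points=list(cfg.time_points),
            lads_per_tp={tp: merge_replicates(rep_sets[tp]) for tp in cfg.time_points},
        )
        clads = constitutive_lads(timeline)
        lad_stats = pd.DataFrame(
            [
                {
                    "time_point": tp,
                    "n_lads": timeline[tp].n_segments,
                    "mb": timeline[tp].total_mb,
                    "pct_genome": 100.0 * timeline[tp].total_bp / layout.total_bp,
                }
                for tp in cfg.time_points
            ]
        )
        track_out(_write_tsv(lad_stats, outdir / "lad_maps.tsv"))
        clads.write_bed(track_out(outdir / "clads.bed"), name="cLAD")
        results["clad_mb"] = clads.total_mb

        # replicate concordance QC from lamin tracks, when supplied
        lmnb1_cfg = cfg.tracks.get("lmnb1", {})
        qc_rows = []
        lmnb1_tracks: dict[str, list] = {}
        for tp, rep_paths in lmnb1_cfg.items():
            tracks = [
                read_bedgraph(p, layout, cfg.params.track_bin_bp) for p in rep_paths
            ]
            lmnb1_tracks[tp] = tracks
            if len(tracks) >= 2:
                r_genome = binned_correlation(tracks[0], tracks[1], cfg.params.bin_bp)
                r_lads = binned_correlation(
                    tracks[0], tracks[1], cfg.params.bin_bp,
                    restrict_to=timeline[tp] if tp in cfg.time_points else None,
                )
                qc_rows.append(
                    {"time_point": tp, "pearson_genome": r_genome,
                     "pearson_in_lads": r_lads}
                )
        if qc_rows:
            track_out(_write_tsv(pd.DataFrame(qc_rows), outdir / "replicate_qc.tsv"))
            results["replicate_qc"] = qc_rows

        stage = "classify"
        t_from, t_to = cfg.time_points[0], cfg.time_points[1]
        t_final = cfg.time_points[-1]
        partition = classify_changes(
            timeline[t_from], timeline[t_to], layout,
            min_overlap_bp=cfg.params.min_overlap_bp,
        )
        partition.t_from, partition.t_to = t_from, t_to
        partition.validate()
        for p in partition.write_beds(outdir / "categories").values():
            track_out(p)
        summary = category_summary(partition)
        track_out(_write_tsv(summary, outdir / "category_summary.tsv"))
        results["category_mb"] = dict(zip(summary["category"], summary["mb"]))

        stage = "fate"
        if len(cfg.time_points) >= 3:
            classes = build_lad_classes(
                partition, timeline[t_final],
                mode=cfg.params.fate_mode, frac_threshold=cfg.params.frac_threshold,
            )
            for p in classes.write_beds(outdir / "classes").values():
                track_out(p)
            track_out(_write_tsv(classes.summary(), outdir / "class_summary.tsv"))
            flows = flow_table(partition, timeline[t_final])
            track_out(_write_tsv(flows, outdir / "flow_table.tsv"))
            results["class_mb"] = dict(
                zip(classes.summary()["class"], classes.summary()["mb"])
            )
        else:
            classes = None
            logger.warning("fewer than 3 time points: ten-class fate skipped")

        stage = "permtest"
        background = timeline.union_all()
        external = (
            read_bed(cfg.lads_external, layout) if cfg.lads_external else None
        )
        if external is not None:
            background = background.union(external)
        cat_queries = {cat.value: partition[cat] for cat in LAD_CATEGORIES}
        perm_cat = run_family(
            cat_queries, timeline[t_final], background,
            n_perm=cfg.params.n_perm, rng_seed=cfg.params.seed,
        )
        track_out(_write_tsv(perm_cat, outdir / "permtest_categories.tsv"))
        results["perm_categories"] = perm_cat.to_dict(orient="records")
        if classes is not None and external is not None:
            class_queries = {lbl: classes[lbl] for lbl in CLASS_LABELS}
            perm_cls = run_family(
                class_queries, external, background,
                n_perm=cfg.params.n_perm_external, rng_seed=cfg.params.seed + 1,
            )
            track_out(_write_tsv(perm_cls, outdir / "permtest_classes.tsv"))
            results["perm_classes"] = perm_cls.to_dict(orient="records")

        stage = "annotate"
        genes = None
        assignment = None
        if cfg.genes and classes is not None:
            genes = (
                read_genes_gtf(cfg.genes, layout)
                if cfg.genes_format == "gtf"
                else read_genes_bed6(cfg.genes, layout)
            )
            assignment = assign_genes(genes, classes)
            if cfg.expression:
                expr = ExpressionMatrix.from_tsv(cfg.expression)
                expressed = flag_expressed(expr, cfg.params.expressed_threshold)
                z = expression_zscores(expr)
                gene_table = assignment.copy()
                gene_table["expressed"] = expressed.reindex(gene_table.index)
                gene_table["de"] = expr.de_flags.reindex(gene_table.index)
                track_out(
                    _write_tsv(gene_table, outdir / "gene_assignment.tsv", index=True)
                )
                track_out(_write_tsv(z, outdir / "expression_zscores.tsv", index=True))
                fc = category_foldchange_test(
                    expr, assignment, t_from, t_to,
                    pseudocount=cfg.params.pseudocount,
                )
                track_out(_write_tsv(fc, outdir / "class_foldchange.tsv"))
                # discordance: DE genes inside constitutive LAD classes
                in_clad = gene_table["assignment"].isin(["Common>LAD"])
                n_clad_genes = int(in_clad.sum())
                n_discordant = int((in_clad & gene_table["de"].fillna(False)).sum())
                results["clad_genes"] = n_clad_genes
                results["clad_discordant_de_genes"] = n_discordant
            else:
                track_out(
                    _write_tsv(assignment, outdir / "gene_assignment.tsv", index=True)
                )
        elif cfg.genes:
            logger.warning("gene annotation skipped (no ten-class map)")

        stage = "enhancers"
        if cfg.enhancers and genes is not None and assignment is not None:
            enhancers = read_enhancers_tsv(cfg.enhancers, layout)
            per_enh, props = enhancer_partition(
                enhancers, timeline, classes, assignment
            )
            track_out(_write_tsv(per_enh, outdir / "enhancer_status.tsv"))
            track_out(_write_tsv(props, outdir / "enhancer_partition.tsv"))
            gene_by_id = {g.gene_id: g for g in genes}
            dist_rows = []
            for enh in enhancers:
                for gid in enh.target_gene_ids:
                    g = gene_by_id.get(gid)
                    if g is None or g.chrom != enh.chrom:
                        continue
                    d = enhancer_gene_distance(enh, g)
                    dist_rows.append(
                        {"enhancer_id": enh.enhancer_id, "gene_id": gid,
                         "signed_distance_bp": d}
                    )
            dist = pd.DataFrame(dist_rows)
            track_out(_write_tsv(dist, outdir / "enhancer_distances.tsv"))
            if len(dist):
                results["enhancer_mean_abs_distance_bp"] = float(
                    dist["signed_distance_bp"].abs().mean()
                )
                results["enhancer_frac_downstream"] = float(
                    (dist["signed_distance_bp"] >= 0).mean()
                )
        elif cfg.enhancers:
            logger.warning("enhancer stage skipped (genes/classes unavailable)")

        stage = "profile"
        if lmnb1_tracks:
            pooled = average_tracks(
                [t for reps in lmnb1_tracks.values() for t in reps]
            )
            rows = []
            for cat in LAD_CATEGORIES + (ChangeCategory.ILAD,):
                regions = partition[cat]
                if not regions:
                    continue
                _, summ = region_mean_signal(pooled, regions)
                rows.append({"category": cat.value, **summ})
            track_out(
                _write_tsv(pd.DataFrame(rows), outdir / "lmnb1_by_category.tsv")
            )
            k4me1_peaks = cfg.peaks.get("H3K4me1", {})
            if k4me1_peaks and clads:
                peak_sets = [
                    read_bed(p, layout) for p in k4me1_peaks.values()
                ]
                sub_in, sub_out = subdomain_partition(clads, peak_sets)
                rows = []
                for name, regions in (
                    ("H3K4me1_regions", sub_in),
                    ("non_H3K4me1_regions", sub_out),
                    ("all_cLADs", clads),
                ):
                    if not regions:
                        continue
                    _, summ = region_mean_signal(pooled, regions)
                    rows.append({"regions": name, **summ})
                track_out(
                    _write_tsv(pd.DataFrame(rows), outdir / "lmnb1_subdomains.tsv")
                )
                results["subdomain_mb"] = {
                    "h3k4me1": sub_in.total_mb, "non_h3k4me1": sub_out.total_mb,
                }
        ptm_cfg = cfg.tracks.get("ptm", {})
        if ptm_cfg and genes is not None:
            prof_frames = []
            for mark, per_tp in ptm_cfg.items():
                tracks = [
                    read_bedgraph(p, layout, cfg.params.track_bin_bp)
                    for p in per_tp.values()
                ]
                pooled_ptm = average_tracks(tracks)
                prof = tss_metaprofile(
                    pooled_ptm, genes,
                    half_window_bp=cfg.params.half_window_bp,
                    profile_bin_bp=cfg.params.profile_bin_bp,
                )
                df = prof.to_dataframe()
                df.insert(0, "mark", mark)
                prof_frames.append(df)
            track_out(
                _write_tsv(pd.concat(prof_frames), outdir / "tss_metaprofiles.tsv")
            )

        stage = "manifest"
        manifest = {
            "laddyn_version": __version__,
            "seed": cfg.params.seed,
            "params": dataclasses.asdict(cfg.params),
            "inputs": {
                "chrom_sizes": cfg.chrom_sizes,
                "lads": cfg.lads,
                "genes": cfg.genes,
                "expression": cfg.expression,
                "enhancers": cfg.enhancers,
                "lads_external": cfg.lads_external,
            },
            "results": results,
            "outputs": {
                str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
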