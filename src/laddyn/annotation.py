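"""Genes, enhancers, expression, and their relation to LAD classes.

Assignment rules follow the >= 1 bp overlap convention: a gene belongs to
the unique LAD class it touches; genes spanning more than one class are
removed from class-level analyses; genes touching none are i-LAD. Enhancers
(GeneHancer-double-elite style intervals with target-gene links) use the
same rule per time point. Expression is a gene x time-point matrix of
replicate-averaged normalized counts with externally supplied differential
expression (DE) flags; a gene counts as expressed when its normalized count
reaches 15 at >= 1 time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fate import CLASS_LABELS, LADClassMap
from .genome import GenomeLayout, IntervalSet
from .lad_maps import LADTimeline, constitutive_lads

__all__ = [
    "GeneRecord",
    "EnhancerRecord",
    "ExpressionMatrix",
    "read_genes_bed6",
    "read_genes_gtf",
    "read_enhancers_tsv",
    "assign_genes",
    "flag_expressed",
    "expression_zscores",
    "category_foldchange_test",
    "enhancer_partition",
    "enhancer_gene_distance",
    "fisher_2x2",
    "coverage_fisher",
    "group_welch_test",
    "MULTI_CLASS",
    "ILAD_LABEL",
]

logger = logging.getLogger(__name__)

MULTI_CLASS = "multi-class (removed)"
ILAD_LABEL = "i-LAD"

EXPRESSED_THRESHOLD = 15  # normalized read count at >= 1 time point


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Transcription start site: start on +, end - 1 on - strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class EnhancerRecord:
    enhancer_id: str
    chrom: str
    start: int
    end: int
    target_gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"enhancer {self.enhancer_id}: start >= end")
        if not self.target_gene_ids:
            raise ValueError(f"enhancer {self.enhancer_id}: needs >= 1 target gene")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class ExpressionMatrix:
    """Replicate-averaged normalized counts, gene x time point, plus DE flags.

    Derived per-gene z-scores use the population standard deviation across
    time points; constant genes get all-zero z-scores.
    """

    def __init__(self, counts: pd.DataFrame, de_flags: pd.Series) -> None:
        if counts.index.has_duplicates:
            raise ValueError("duplicate gene_id in expression matrix")
        if (counts.to_numpy() < 0).any():
            raise ValueError("normalized counts must be >= 0")
        self.counts = counts.astype(float)
        self.de_flags = de_flags.reindex(counts.index).fillna(False).astype(bool)

    @property
    def time_points(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        """Read a TSV with gene_id, per-replicate count columns ``<tp>_rep<k>``
        (or plain ``<tp>``), and a boolean ``de`` column; replicates are
        averaged per time point."""
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        de = df.pop("de").astype(bool) if "de" in df.columns else pd.Series(
            False, index=df.index
        )
        tp_of = {c: c.split("_rep")[0] for c in df.columns}
        counts = df.T.groupby([tp_of[c] for c in df.columns]).mean().T
        # keep original time-point order
        order = list(dict.fromkeys(tp_of[c] for c in df.columns))
        return cls(counts[order], de)


def read_genes_bed6(path: str | Path, layout: GenomeLayout) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            if chrom not in layout:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            genes.append(GeneRecord(name, chrom, int(start), int(end), strand))
    return genes


def read_genes_gtf(path: str | Path, layout: GenomeLayout) -> list[GeneRecord]:
    """Read gene features from a GTF (1-based closed -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.seqid not in layout:
            raise ValueError(f"gene on unknown chromosome {feat.seqid!r}")
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        genes.append(
            GeneRecord(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    return genes


def read_enhancers_tsv(path: str | Path, layout: GenomeLayout) -> list[EnhancerRecord]:
    """Columns: enhancer_id, chrom, start, end, target_gene_ids (comma-sep)."""
    df = pd.read_csv(path, sep="\t")
    enhancers = []
    for row in df.itertuples(index=False):
        if row.chrom not in layout:
            raise ValueError(f"enhancer {row.enhancer_id}: unknown chromosome")
        targets = tuple(str(row.target_gene_ids).split(","))
        enhancers.append(
            EnhancerRecord(str(row.enhancer_id), row.chrom, int(row.start),
                           int(row.end), targets)
        )
    return enhancers


# --------------------------------------------------------------------- #
# gene assignment


def assign_genes(genes: Sequence[GeneRecord], classes: LADClassMap) -> pd.DataFrame:
    """Assign each gene to its unique LAD class by the >= 1 bp rule.

    Returns a table indexed by gene_id with an ``assignment`` column that is
    a class label, ``"i-LAD"``, or ``"multi-class (removed)"``.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in gene list")
    rows = {}
    for g in genes:
        hits = [
            lbl
            for lbl in CLASS_LABELS
            if classes[lbl].overlaps_interval(g.chrom, g.start, g.end)
        ]
        if len(hits) == 0:
            rows[g.gene_id] = ILAD_LABEL
        elif len(hits) == 1:
            rows[g.gene_id] = hits[0]
        else:
            rows[g.gene_id] = MULTI_CLASS
    return pd.DataFrame({"assignment": pd.Series(rows, name="assignment")})


def flag_expressed(
    expr: ExpressionMatrix, threshold: float = EXPRESSED_THRESHOLD
) -> pd.Series:
    """True iff the normalized count reaches ``threshold`` at >= 1 time point."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return expr.counts.max(axis=1) >= threshold


def expression_zscores(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene z-scores across time points (population sd; constant -> 0)."""
    if expr.counts.shape[1] < 2:
        raise ValueError("z-scores require >= 2 time points")
    x = expr.counts.to_numpy()
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    z = np.divide(x - mu, sd, out=np.zeros_like(x), where=sd > 0)
    return pd.DataFrame(z, index=expr.counts.index, columns=expr.counts.columns)


def category_foldchange_test(
    expr: ExpressionMatrix,
    assignment: pd.DataFrame | pd.Series,
    t_from: str,
    t_to: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-class log2 fold-change of DE genes between two time points.

    log2FC = log2((count_to + c) / (count_from + c)) with pseudocount c
    (default 1). Each class with >= 3 DE genes gets a two-sided one-sample
    t-test of the fold-changes against 0; smaller classes report NaN.
    """
    assign = assignment["assignment"] if isinstance(assignment, pd.DataFrame) else assignment
    de_genes = expr.de_flags[expr.de_flags].index
    lfc = np.log2(
        (expr.counts[t_to] + pseudocount) / (expr.counts[t_from] + pseudocount)
    )
    rows = []
    for lbl in assign.loc[assign.index.intersection(de_genes)].unique():
        genes = assign.index[(assign == lbl)].intersection(de_genes)
        vals = lfc.loc[genes].to_numpy()
        if len(vals) >= 3 and np.std(vals) > 0:
            _, p = stats.ttest_1samp(vals, 0.0)
        else:
            p = float("nan")
        rows.append(
            {
                "class": lbl,
                "n_de_genes": len(vals),
                "mean_log2fc": float(np.mean(vals)) if len(vals) else float("nan"),
                "median_log2fc": float(np.median(vals)) if len(vals) else float("nan"),
                "p_one_sample_t": float(p) if p == p else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# enhancers


def enhancer_status(
    enh: EnhancerRecord, timeline: LADTimeline, clads: IntervalSet
) -> tuple[str, dict[str, bool]]:
    """Per-time-point LAD membership and the overall status label.

    vLAD: overlaps a variable LAD (LAD-but-not-cLAD bases) at >= 1 time
    point; cLAD: in LADs at all time points without any vLAD overlap;
    i-LAD: outside LADs at every time point; mixed otherwise.
    """
    in_lad = {
        tp: timeline[tp].overlaps_interval(enh.chrom, enh.start, enh.end)
        for tp in timeline.time_points
    }
    in_vlad = any(
        timeline[tp].subtract(clads).overlaps_interval(enh.chrom, enh.start, enh.end)
        for tp in timeline.time_points
    )
    if in_vlad:
        status = "vLAD"
    elif all(in_lad.values()):
        status = "cLAD"
    elif not any(in_lad.values()):
        status = "i-LAD"
    else:
        status = "mixed"
    return status, in_lad


def enhancer_partition(
    enhancers: Sequence[EnhancerRecord],
    timeline: LADTimeline,
    classes: LADClassMap,
    assignment: pd.DataFrame | pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enhancer LAD/i-LAD membership over time, grouped by target-gene class.

    Returns (per-enhancer table, proportion table). Enhancers whose every
    target gene is absent from the assignment or was removed as multi-class
    are dropped with a log entry. An enhancer with several surviving targets
    contributes once per distinct target-gene class.
    """
    assign = assignment["assignment"] if isinstance(assignment, pd.DataFrame) else assignment
    clads = constitutive_lads(timeline)
    per_rows = []
    for enh in enhancers:
        target_classes = sorted(
            {
                assign[g]
                for g in enh.target_gene_ids
                if g in assign.index and assign[g] != MULTI_CLASS
            }
        )
        if not target_classes:
            logger.info("enhancer %s dropped: no surviving target gene", enh.enhancer_id)
            continue
        status, in_lad = enhancer_status(enh, timeline, clads)
        for cls in target_classes:
            row = {
                "enhancer_id": enh.enhancer_id,
                "target_gene_class": cls,
                "status": status,
            }
            row.update({f"in_lad_{tp}": in_lad[tp] for tp in timeline.time_points})
            per_rows.append(row)
    per_enh = pd.DataFrame(per_rows)
    props = []
    if len(per_enh):
        for cls, grp in per_enh.groupby("target_gene_class"):
            for tp in timeline.time_points:
                props.append(
                    {
                        "target_gene_class": cls,
                        "time_point": tp,
                        "n_enhancers": len(grp),
                        "frac_in_lad": float(grp[f"in_lad_{tp}"].mean()),
                    }
                )
    return per_enh, pd.DataFrame(props)


def enhancer_gene_distance(enh: EnhancerRecord, gene: GeneRecord) -> int:
    """Signed bp from enhancer center to the gene start site (TSS).

    Negative = upstream of the gene start, positive = downstream (0 counts
    as downstream); the sign convention is strand-aware.
    """
    if enh.chrom != gene.chrom:
        raise ValueError(
            f"enhancer {enh.enhancer_id} and gene {gene.gene_id} "
            "are on different chromosomes (trans pairs out of scope)"
        )
    center = enh.center
    return center - gene.tss if gene.strand == "+" else gene.tss - center


# --------------------------------------------------------------------- #
# generic statistics


def fisher_2x2(table: Sequence[Sequence[int]]) -> dict[str, float]:
    """Fisher's exact test (two-tailed) with Haldane-corrected odds ratio.

    The p-value is the exact hypergeometric two-tailed probability (sum over
    tables at least as extreme as observed); when any cell is zero the odds
    ratio uses the Haldane-Anscombe +0.5 correction.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("Fisher test undefined with an all-zero margin")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel().astype(float)
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return {"odds_ratio": (a * d) / (b * c), "p_two_tailed": float(p)}


def coverage_fisher(
    in_a: int, total_a: int, in_b: int, total_b: int, unit_bp: int = 100_000
) -> dict[str, float]:
    """Fisher test on genomic coverage, counted in ``unit_bp`` units.

    Raw bp counts would wildly inflate the evidence, so coverage is first
    converted to (rounded) 100-kb units by default.
    """
    if unit_bp <= 0:
        raise ValueError("unit_bp must be positive")
    u = lambda bp: int(round(bp / unit_bp))
    table = [
        [u(in_a), max(u(total_a) - u(in_a), 0)],
        [u(in_b), max(u(total_b) - u(in_b), 0)],
    ]
    out = fisher_2x2(table)
    out["unit_bp"] = unit_bp
    return out


def group_welch_test(groups: Sequence[Sequence[float]]) -> float:
    """Welch-corrected comparison of group means.

    Two groups: unpaired two-tailed Welch t-test. More than two: Welch's
    ANOVA. Each group needs n >= 2, and at least one group nonzero variance.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    if all(np.var(g) == 0 for g in arrays):
        raise ValueError("all groups have zero variance; Welch test undefined")
    if len(arrays) == 2:
        _, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        return float(p)
    import pingouin as pg

    long = pd.DataFrame(
        {
            "value": np.concatenate(arrays),
            "group": np.concatenate(
                [np.full(len(g), i) for i, g in enumerate(arrays)]
            ),
        }
    )
    res = pg.welch_anova(data=long, dv="value", between="group")
    p_col = "p_unc" if "p_unc" in res.columns else "p-unc"
    return float(res[p_col].iloc[0])
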