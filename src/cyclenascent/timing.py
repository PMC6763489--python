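"""Replication-timing gene classification and time-course summaries.

Genes are classified by the distance from an anchor point (TSS by default)
to the nearest early- and late-firing origin: within the 4 kb window of one
timing only -> that class; within both -> ambiguous (excluded from both
classes, reported separately); neither -> unclassified. Time-course
summaries give per-class/genotype/timepoint medians and quartiles of
per-gene normalized counts (replicates averaged per gene first), contrasts
of mutant vs wild type per timepoint (fold ratio of medians with a
Mann-Whitney p), and the within-genotype G2 vs G1 dosage step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mann_whitney_u
from .types import CycleNascentError, GeneRecord, GeneSet, OriginSet, TIMEPOINTS

logger = logging.getLogger(__name__)

ORIGIN_WINDOW = 4000
CLASSES = ("early", "late")


def _anchor_distance(gene: GeneRecord, position: int, anchor: str) -> int:
    if anchor == "tss":
        return abs(gene.tss - position)
    if anchor == "midpoint":
        return abs((gene.start + gene.end) // 2 - position)
    if anchor == "body":
        if gene.start <= position < gene.end:
            return 0
        return min(abs(gene.start - position), abs(gene.end - 1 - position))
    raise ValueError(f"unknown anchor {anchor!r}")


def classify_genes(
    genes: GeneSet,
    origins: OriginSet,
    window: int = ORIGIN_WINDOW,
    anchor: str = "tss",
) -> pd.DataFrame:
    """Per-gene timing class and distance to the nearest origin.

    Returns a frame indexed by gene id with columns ``timing_class``
    (early | late | ambiguous | unclassified), ``distance_early`` and
    ``distance_late`` (bp; inf when no origin of that timing lies on the
    gene's chromosome).
    """
    by_timing = {t: list(origins.by_timing(t)) for t in CLASSES}
    rows = []
    for gene in genes:
        dists = {}
        for timing in CLASSES:
            candidates = [
                _anchor_distance(gene, o.position, anchor)
                for o in by_timing[timing]
                if o.chrom == gene.chrom
            ]
            dists[timing] = min(candidates) if candidates else np.inf
        near_early = dists["early"] <= window
        near_late = dists["late"] <= window
        if near_early and near_late:
            cls = "ambiguous"
        elif near_early:
            cls = "early"
        elif near_late:
            cls = "late"
        else:
            cls = "unclassified"
        rows.append(
            {
                "gene_id": gene.id,
                "timing_class": cls,
                "distance_early": dists["early"],
                "distance_late": dists["late"],
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class TimecourseSummary:
    """Distribution summaries and contrasts across the release time course."""

    summary: pd.DataFrame  # timing_class, genotype, timepoint, n, median, q1, q3
    contrasts: pd.DataFrame  # contrast rows with fold_ratio, U, p


def _per_gene_means(counts: pd.DataFrame) -> pd.DataFrame:
    """Average replicates per (gene, genotype, timepoint)."""
    return (
        counts.groupby(["region_id", "genotype", "timepoint"], as_index=False)["count"]
        .mean()
    )


def timecourse_summary(
    counts: pd.DataFrame,
    classes: pd.DataFrame,
    reference_genotype: str = "WT",
    timepoints: tuple[str, ...] = TIMEPOINTS,
) -> TimecourseSummary:
    """Summarize a tidy counts table by timing class across the time course.

    ``counts`` needs columns region_id, genotype, timepoint, replicate,
    count; ``classes`` is the classify_genes output. Contrasts cover every
    non-reference genotype vs the reference at each timepoint (fold ratio
    of medians, Mann-Whitney U and p over per-gene values) and each
    genotype's S90 (G2) vs G1 median ratio.
    """
    means = _per_gene_means(counts)
    means = means.join(classes["timing_class"], on="region_id")
    genotypes = sorted(means["genotype"].unique())
    summary_rows = []
    contrast_rows = []
    for cls in ("early", "late", "unclassified", "all"):
        cls_means = means if cls == "all" else means[means["timing_class"] == cls]
        if cls_means.empty:
            logger.warning("timecourse_summary: no genes in class %r", cls)
            continue
        for geno in genotypes:
            for tp in timepoints:
                vals = cls_means[
                    (cls_means["genotype"] == geno) & (cls_means["timepoint"] == tp)
                ]["count"].to_numpy()
                if vals.size == 0:
                    continue
                summary_rows.append(
                    {
                        "timing_class": cls,
                        "genotype": geno,
                        "timepoint": tp,
                        "n": vals.size,
                        "median": float(np.median(vals)),
                        "q1": float(np.percentile(vals, 25)),
                        "q3": float(np.percentile(vals, 75)),
                    }
                )
        # mutant vs reference at each timepoint
        for geno in genotypes:
            if geno == reference_genotype:
                continue
            for tp in timepoints:
                ref = cls_means[
                    (cls_means["genotype"] == reference_genotype)
                    & (cls_means["timepoint"] == tp)
                ]["count"].to_numpy()
                mut = cls_means[
                    (cls_means["genotype"] == geno) & (cls_means["timepoint"] == tp)
                ]["count"].to_numpy()
                if ref.size == 0 or mut.size == 0:
                    continue
                ref_med = float(np.median(ref))
                u, p = mann_whitney_u(mut, ref)
                contrast_rows.append(
                    {
                        "contrast": f"{geno}_vs_{reference_genotype}",
                        "timing_class": cls,
                        "timepoint": tp,
                        "fold_ratio": float(np.median(mut)) / ref_med
                        if ref_med > 0
                        else np.nan,
                        "U": u,
                        "p": p,
                    }
                )
        # within-genotype G2 vs G1 step
        for geno in genotypes:
            g1 = cls_means[
                (cls_means["genotype"] == geno) & (cls_means["timepoint"] == "G1")
            ]["count"].to_numpy()
            g2 = cls_means[
                (cls_means["genotype"] == geno) & (cls_means["timepoint"] == "S90")
            ]["count"].to_numpy()
            if g1.size == 0 or g2.size == 0:
                continue
            g1_med = float(np.median(g1))
            u, p = mann_whitney_u(g2, g1)
            contrast_rows.append(
                {
                    "contrast": f"{geno}_S90_vs_G1",
                    "timing_class": cls,
                    "timepoint": "S90",
                    "fold_ratio": float(np.median(g2)) / g1_med if g1_med > 0 else np.nan,
                    "U": u,
                    "p": p,
                }
            )
    return TimecourseSummary(pd.DataFrame(summary_rows), pd.DataFrame(contrast_rows))


def buffering_step(
    counts_wt: pd.DataFrame, classes: pd.DataFrame
) -> dict[str, float]:
    """Per-class (and overall) G2/G1 ratio of across-gene median counts for
    the wild type: the dosage step released when buffering ends."""
    means = _per_gene_means(counts_wt).join(classes["timing_class"], on="region_id")
    result = {}
    for cls in ("early", "late", "unclassified", "all"):
        sub = means if cls == "all" else means[means["timing_class"] == cls]
        g1 = sub[sub["timepoint"] == "G1"]["count"].to_numpy()
        g2 = sub[sub["timepoint"] == "S90"]["count"].to_numpy()
        if g1.size == 0 or g2.size == 0:
            continue
        g1_med = float(np.median(g1))
        if g1_med == 0:
            raise CycleNascentError(f"class {cls}: zero G1 median, ratio undefined")
        result[cls] = float(np.median(g2)) / g1_med
    return result
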