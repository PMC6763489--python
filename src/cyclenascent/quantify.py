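"""Region quantification and differential nascent expression.

Counts are sums of normalized per-base signal over each annotated region:
sense mode on the region's own strand, antisense mode on the opposite
strand over the same body (cryptic antisense transcription). Overlapping
regions each receive the full signal of the shared bases; a position on the
shared boundary of bookended regions belongs to the half-open interval
containing it.

Differential calls use log2 fold changes of replicate means with a
pseudocount, a two-sided Welch test on log2(count + pc) across replicates
(a documented simple substitute for dispersion-modeling count tests), and
Benjamini-Hochberg FDR control, flagged at the >= 1.5 fold / FDR <= 0.05
thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, welch_log_test
from .types import CycleNascentError, GeneSet, LibrarySample, SignalTrack

FC_THRESHOLD = 1.5
FDR_THRESHOLD = 0.05


def quantify_regions(
    track: SignalTrack, regions: GeneSet, mode: str = "sense"
) -> pd.Series:
    """Sum per-base signal over each region; returns a Series keyed by id."""
    if mode not in ("sense", "antisense"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = {}
    for region in regions:
        if region.end > track.chrom_sizes.get(region.chrom, -1):
            raise CycleNascentError(
                f"region {region.id} [{region.start}, {region.end}) extends beyond "
                f"chromosome {region.chrom}"
            )
        strand = region.strand if mode == "sense" else region.antisense_strand
        arr = track.array(region.chrom, strand)
        counts[region.id] = float(arr[region.start : region.end].sum())
    return pd.Series(counts, name="count")


def build_counts_table(
    samples: list[LibrarySample], regions: GeneSet, mode: str = "sense"
) -> pd.DataFrame:
    """Tidy counts table: one row per (region, sample)."""
    frames = []
    biotype = {g.id: g.biotype for g in regions}
    for s in samples:
        counts = quantify_regions(s.track, regions, mode=mode)
        frames.append(
            pd.DataFrame(
                {
                    "region_id": counts.index,
                    "region_class": [
                        "antisense" if mode == "antisense" else biotype[r]
                        for r in counts.index
                    ],
                    "sample_id": s.sample_id,
                    "genotype": s.genotype,
                    "timepoint": s.timepoint,
                    "replicate": s.replicate,
                    "count": counts.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fold_change_table(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential table B vs A from replicate count matrices.

    ``counts_a`` / ``counts_b``: regions x replicates (index = region id).
    log2FC = log2((mean_B + pc) / (mean_A + pc)); p from a Welch test on
    log2(count + pc) when both conditions have >= 2 replicates, else 1
    (flagging then depends on the fold change only); q by BH over all
    regions.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if len(counts_a) == 0:
        raise CycleNascentError("fold_change_table requires at least one region")
    if not counts_a.index.equals(counts_b.index):
        counts_b = counts_b.reindex(counts_a.index)
        if counts_b.isna().any().any():
            raise CycleNascentError("conditions cover different region sets")
    a = counts_a.to_numpy(dtype=float)
    b = counts_b.to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        log_a = np.log2(a + pseudocount)
        log_b = np.log2(b + pseudocount)
        p = np.array(
            [welch_log_test(log_a[i], log_b[i]) for i in range(len(counts_a))]
        )
    else:
        p = np.ones(len(counts_a))
    q = benjamini_hochberg(p)
    table = pd.DataFrame(
        {
            "region_id": counts_a.index,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2FC": log2fc,
            "p_value": p,
            "q_value": q,
        }
    ).set_index("region_id")
    table["flag_up"] = (table["log2FC"] >= np.log2(FC_THRESHOLD)) & (
        table["q_value"] <= FDR_THRESHOLD
    )
    table["flag_down"] = (table["log2FC"] <= -np.log2(FC_THRESHOLD)) & (
        table["q_value"] <= FDR_THRESHOLD
    )
    return table


def count_regulated(
    table: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> tuple[int, int]:
    """(n_up, n_down) at the given fold-change and FDR thresholds."""
    if len(table) == 0:
        return 0, 0
    sig = table["q_value"] <= fdr_threshold
    n_up = int((sig & (table["log2FC"] >= np.log2(fc_threshold))).sum())
    n_down = int((sig & (table["log2FC"] <= -np.log2(fc_threshold))).sum())
    return n_up, n_down


def replicate_matrix(
    counts: pd.DataFrame, genotype: str, timepoint: str
) -> pd.DataFrame:
    """Pivot a tidy counts table into regions x replicates for one condition."""
    sub = counts[(counts["genotype"] == genotype) & (counts["timepoint"] == timepoint)]
    if sub.empty:
        raise CycleNascentError(f"no counts for ({genotype}, {timepoint})")
    return sub.pivot(index="region_id", columns="replicate", values="count")
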