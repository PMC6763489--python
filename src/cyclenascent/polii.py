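"""RNA Pol II distribution statistics along gene bodies.

Three views of where polymerase sits: the 5'/3' ratio (signal in a window
downstream of the TSS over signal in a window upstream of the TTS, compared
between strains with a Mann-Whitney U test), the expression-normalized
metagene (each gene's TSS-100..TTS+200 window rescaled into 500 bins and
divided by the gene's own mean per-bp body signal, then averaged across
genes with a 95% CI), and the length-ordered heatmap of per-position log2
fold changes between two strains over TSS..TSS+4 kb.

The 5'/3' window default is 300 bp; the ratio is invariant under any
positive rescaling of the track, and the metagene is invariant under
per-gene rescaling by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mann_whitney_u
from .types import GeneRecord, GeneSet, SignalTrack

logger = logging.getLogger(__name__)

RATIO_WINDOW = 300
METAGENE_BINS = 500
METAGENE_FLANK_UP = 100
METAGENE_FLANK_DOWN = 200
HEATMAP_SPAN = 4000
HEATMAP_BIN = 25


def _window_sum(track: SignalTrack, gene: GeneRecord, interval: tuple[int, int]) -> float:
    start, end = interval
    return float(track.array(gene.chrom, gene.strand)[start:end].sum())


def five_three_ratio(
    track: SignalTrack, gene: GeneRecord, window: int = RATIO_WINDOW
) -> float | None:
    """Sum of signal over the first ``window`` bp from the TSS divided by the
    sum over the last ``window`` bp up to the TTS (strand-aware). Returns
    None when the 3' window is empty (ratio undefined)."""
    r5 = _window_sum(track, gene, gene.five_prime_window(window))
    r3 = _window_sum(track, gene, gene.three_prime_window(window))
    if r3 == 0:
        return None
    return r5 / r3


@dataclass
class RatioSet:
    """Per-gene 5'/3' ratios for one strain."""

    table: pd.DataFrame  # gene_id, r5, r3, ratio (NaN when undefined)
    window: int
    n_short_excluded: int

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio"].dropna().to_numpy()


def ratio_set(track: SignalTrack, genes: GeneSet, window: int = RATIO_WINDOW) -> RatioSet:
    """Compute ratios over all genes long enough for non-overlapping windows
    (length >= 2 * window); shorter genes are excluded and counted."""
    rows = []
    n_short = 0
    for gene in genes:
        if gene.length < 2 * window:
            n_short += 1
            continue
        r5 = _window_sum(track, gene, gene.five_prime_window(window))
        r3 = _window_sum(track, gene, gene.three_prime_window(window))
        rows.append(
            {
                "gene_id": gene.id,
                "r5": r5,
                "r3": r3,
                "ratio": r5 / r3 if r3 > 0 else np.nan,
            }
        )
    if n_short:
        logger.info("ratio_set: excluded %d genes shorter than %d bp", n_short, 2 * window)
    return RatioSet(pd.DataFrame(rows), window, n_short)


def ratio_compare(ratios_a, ratios_b) -> tuple[float, float]:
    """Mann-Whitney U comparison of two strains' ratio vectors."""
    return mann_whitney_u(ratios_a, ratios_b)


# ------------------------------------------------------------------- metagene

def rebin(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a per-base vector into ``n_bins`` equal-width bins, splitting
    bases fractionally across bin boundaries (total signal is conserved)."""
    length = len(x)
    cumulative = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    edges = np.linspace(0.0, length, n_bins + 1)
    integral = np.interp(edges, np.arange(length + 1), cumulative)
    return np.diff(integral) / (length / n_bins)


def _oriented_window(
    track: SignalTrack, gene: GeneRecord, start_off: int, end_off: int
) -> np.ndarray | None:
    """Signal on the gene's strand over oriented TSS offsets
    [start_off, end_off); None when the window leaves the chromosome."""
    size = track.chrom_sizes[gene.chrom]
    arr = track.array(gene.chrom, gene.strand)
    if gene.strand == "+":
        lo, hi = gene.tss + start_off, gene.tss + end_off
        if lo < 0 or hi > size:
            return None
        return arr[lo:hi]
    lo, hi = gene.tss - end_off + 1, gene.tss - start_off + 1
    if lo < 0 or hi > size:
        return None
    return arr[lo:hi][::-1]


@dataclass
class MetageneProfile:
    """Mean expression-normalized profile across genes with a 95% CI."""

    table: pd.DataFrame  # bin, mean, lo, hi
    n_genes: int
    n_excluded_short: int
    n_excluded_edge: int
    n_excluded_zero: int


def metagene(
    track: SignalTrack,
    genes: GeneSet,
    n_bins: int = METAGENE_BINS,
    flank_up: int = METAGENE_FLANK_UP,
    flank_down: int = METAGENE_FLANK_DOWN,
    min_length: int = 500,
) -> MetageneProfile:
    """Expression-normalized metagene over genes with body length > min_length.

    Each gene's TSS-flank_up .. TTS+flank_down window (strand-oriented, the
    whole region fitted into ``n_bins`` bins) is divided by the gene's mean
    per-bp body signal; the profile is the across-gene mean per bin with a
    normal-approximation 95% CI.
    """
    profiles = []
    n_short = n_edge = n_zero = 0
    for gene in genes:
        if gene.length <= min_length:
            n_short += 1
            continue
        window = _oriented_window(track, gene, -flank_up, gene.length + flank_down)
        if window is None:
            n_edge += 1
            continue
        body_mean = float(
            track.array(gene.chrom, gene.strand)[gene.start : gene.end].mean()
        )
        if body_mean == 0:
            n_zero += 1
            continue
        profiles.append(rebin(window, n_bins) / body_mean)
    if n_zero:
        logger.info("metagene: excluded %d genes with zero body signal", n_zero)
    stacked = np.array(profiles)
    n = len(profiles)
    if n == 0:
        mean = np.full(n_bins, np.nan)
        half = np.full(n_bins, np.nan)
    else:
        mean = stacked.mean(axis=0)
        se = stacked.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(n_bins)
        half = 1.96 * se
    table = pd.DataFrame(
        {"bin": np.arange(n_bins), "mean": mean, "lo": mean - half, "hi": mean + half}
    )
    return MetageneProfile(table, n, n_short, n_edge, n_zero)


# -------------------------------------------------------------------- heatmap

@dataclass
class HeatmapMatrix:
    """Per-gene log2(mutant/WT) over binned TSS offsets, rows ordered by
    gene length; positions past a gene's end (or the chromosome edge) are
    NaN-masked."""

    matrix: np.ndarray  # n_genes x n_bins, NaN = masked
    gene_ids: list[str]
    gene_lengths: np.ndarray
    bin_size: int
    span: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bp_{i * self.bin_size}" for i in range(self.matrix.shape[1])]
        df = pd.DataFrame(self.matrix, index=self.gene_ids, columns=cols)
        df.insert(0, "length", self.gene_lengths)
        return df.rename_axis("gene_id").reset_index()


def heatmap_matrix(
    track_wt: SignalTrack,
    track_mut: SignalTrack,
    genes: GeneSet,
    span: int = HEATMAP_SPAN,
    bin_size: int = HEATMAP_BIN,
    pseudocount: float = 1.0,
) -> HeatmapMatrix:
    """log2 fold-change matrix mutant vs WT over TSS..TSS+span per gene."""
    if span % bin_size != 0:
        raise ValueError("span must be a multiple of bin_size")
    n_bins = span // bin_size
    ordered = sorted(genes, key=lambda g: (g.length, g.id))
    rows = np.full((len(ordered), n_bins), np.nan)
    for i, gene in enumerate(ordered):
        wt = _padded_window(track_wt, gene, span)
        mut = _padded_window(track_mut, gene, span)
        wt_b = wt.reshape(n_bins, bin_size).mean(axis=1)
        mut_b = mut.reshape(n_bins, bin_size).mean(axis=1)
        row = np.log2((mut_b + pseudocount) / (wt_b + pseudocount))
        offsets = np.arange(n_bins) * bin_size
        # past the TTS (off-chromosome padding always lies past the TTS too)
        row[offsets >= gene.length] = np.nan
        rows[i] = row
    return HeatmapMatrix(
        matrix=rows,
        gene_ids=[g.id for g in ordered],
        gene_lengths=np.array([g.length for g in ordered]),
        bin_size=bin_size,
        span=span,
    )


def _padded_window(track: SignalTrack, gene: GeneRecord, span: int) -> np.ndarray:
    """Oriented TSS..TSS+span signal, zero-padded beyond the chromosome
    (padded offsets always exceed the gene length and are masked later)."""
    size = track.chrom_sizes[gene.chrom]
    arr = track.array(gene.chrom, gene.strand)
    out = np.zeros(span)
    if gene.strand == "+":
        hi = min(gene.tss + span, size)
        out[: hi - gene.tss] = arr[gene.tss : hi]
    else:
        lo = max(gene.tss - span + 1, 0)
        vals = arr[lo : gene.tss + 1][::-1]
        out[: len(vals)] = vals
    return out
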