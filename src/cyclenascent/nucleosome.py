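"""Nucleosome maturation metrics from TSS-aligned dyad profiles.

The average profile is the across-gene mean of strand-oriented dyad density
over TSS offsets -200..+1400, smoothed with a centered moving average
(default width 31 bp, reflected boundaries). Peaks are local maxima
downstream of the NDR minimum; the first is the +1 nucleosome. Positioning
strength is the mean peak/trough ratio over nucleosomes +2..+7 (each peak
height over the mean of its two flanking troughs) and the linker length is
the mean peak-to-peak spacing over the pairs (+1,+2), (+2,+3), (+3,+4)
minus the 147 bp nucleosome footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .types import CycleNascentError, GeneSet, NUCLEOSOME_FOOTPRINT, SignalTrack

logger = logging.getLogger(__name__)

DEFAULT_FLANK = (-200, 1400)
SMOOTH_WIDTH = 31
NDR_SEARCH = (-150, 50)
PEAK_INDICES = range(2, 8)  # +2 .. +7 for the peak/trough ratio
LINKER_PAIRS = ((1, 2), (2, 3), (3, 4))


class NoPeaks(CycleNascentError):
    """Fewer than the required number of peaks could be detected."""


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with reflected boundaries (odd width)."""
    if width <= 1:
        return x.astype(float)
    if width % 2 == 0:
        raise ValueError("smoothing width must be odd")
    half = width // 2
    padded = np.pad(x, half, mode="reflect")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


@dataclass
class NucleosomeProfile:
    """TSS-aligned average dyad density with its smoothed version."""

    offsets: np.ndarray  # bp relative to TSS, contiguous at 1 bp
    density: np.ndarray  # raw across-gene mean
    smoothed: np.ndarray
    smooth_width: int
    n_genes: int
    n_skipped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "density": self.density, "smoothed": self.smoothed}
        )


def tss_profile(
    dyad_track: SignalTrack,
    genes: GeneSet,
    flank: tuple[int, int] = DEFAULT_FLANK,
    smooth_width: int = SMOOTH_WIDTH,
) -> NucleosomeProfile:
    """Average strand-oriented dyad density across genes.

    Genes whose window extends off the chromosome are skipped (logged).
    """
    lo, hi = flank
    offsets = np.arange(lo, hi + 1)
    acc = np.zeros(len(offsets))
    n = 0
    n_skipped = 0
    for gene in genes:
        size = dyad_track.chrom_sizes[gene.chrom]
        arr = dyad_track.array(gene.chrom, "+")
        if gene.strand == "+":
            a, b = gene.tss + lo, gene.tss + hi + 1
            if a < 0 or b > size:
                n_skipped += 1
                continue
            acc += arr[a:b]
        else:
            a, b = gene.tss - hi, gene.tss - lo + 1
            if a < 0 or b > size:
                n_skipped += 1
                continue
            acc += arr[a:b][::-1]
        n += 1
    if n_skipped:
        logger.info("tss_profile: skipped %d genes with off-chromosome windows", n_skipped)
    density = acc / n if n else acc
    return NucleosomeProfile(
        offsets=offsets,
        density=density,
        smoothed=moving_average(density, smooth_width),
        smooth_width=smooth_width,
        n_genes=n,
        n_skipped=n_skipped,
    )


@dataclass
class PeakCalls:
    """Ordered nucleosome peaks (+1 onward) with interleaved troughs.

    ``trough_positions[k]`` / ``trough_heights[k]`` flank ``positions[k]``
    on the upstream side; index ``k+1`` flanks it downstream, so troughs
    has one more entry than peaks.
    """

    positions: np.ndarray  # bp offsets of peaks +1..+K
    heights: np.ndarray
    trough_positions: np.ndarray  # K+1 entries, interleaving the peaks
    trough_heights: np.ndarray

    @property
    def n_peaks(self) -> int:
        return len(self.positions)

    def spacing(self) -> np.ndarray:
        return np.diff(self.positions)


def call_peaks(
    profile: NucleosomeProfile,
    expected_peaks: int = 7,
    min_peaks: int = 4,
    ndr_search: tuple[int, int] = NDR_SEARCH,
) -> PeakCalls:
    """Detect phased nucleosome peaks on the smoothed profile.

    The +1 nucleosome is the first local maximum downstream of the global
    minimum within the NDR search window; troughs are the minima between
    consecutive retained peaks (the NDR minimum serves as the trough
    upstream of +1, the minimum before the next extremum or window end as
    the trough after the last peak).
    """
    y = profile.smoothed
    offsets = profile.offsets
    in_ndr = (offsets >= ndr_search[0]) & (offsets <= ndr_search[1])
    if not in_ndr.any():
        raise ValueError("NDR search window outside the profile")
    ndr_idx = np.flatnonzero(in_ndr)[np.argmin(y[in_ndr])]

    # peaks must be at least a nucleosome footprint apart (minus jitter
    # allowance) and rise visibly above local noise
    span = float(y.max() - y.min())
    if span <= 0:
        raise NoPeaks("flat profile: no peaks")
    max_idx, _ = find_peaks(y, distance=120, prominence=0.02 * span)
    max_idx = max_idx[max_idx > ndr_idx][:expected_peaks]
    if len(max_idx) < min_peaks:
        raise NoPeaks(
            f"only {len(max_idx)} peaks detected downstream of the NDR "
            f"(need >= {min_peaks})"
        )

    trough_idx = [ndr_idx + int(np.argmin(y[ndr_idx : max_idx[0] + 1]))]
    for left, right in zip(max_idx[:-1], max_idx[1:]):
        trough_idx.append(left + int(np.argmin(y[left : right + 1])))
    # trough after the last peak: search up to one median spacing downstream
    last = max_idx[-1]
    reach = int(np.median(np.diff(max_idx))) if len(max_idx) > 1 else len(y) - last - 1
    stop = min(len(y), last + reach + 1)
    trough_idx.append(last + int(np.argmin(y[last:stop])))
    trough_idx = np.asarray(trough_idx)

    return PeakCalls(
        positions=offsets[max_idx].astype(float),
        heights=y[max_idx],
        trough_positions=offsets[trough_idx].astype(float),
        trough_heights=y[trough_idx],
    )


@dataclass
class MaturationMetrics:
    """Summary positioning metrics for one profile."""

    peak_trough_ratio: float  # mean over +2..+7
    linker_length: float  # mean over pairs (+1,+2), (+2,+3), (+3,+4), bp
    per_peak_ratios: dict[int, float]  # nucleosome index -> ratio
    per_pair_linkers: dict[str, float]
    mean_spacing: float  # mean peak-to-peak spacing over all called peaks


def maturation_metrics(
    calls: PeakCalls, footprint: int = NUCLEOSOME_FOOTPRINT
) -> MaturationMetrics:
    """Peak/trough ratio and linker length from called peaks."""
    if calls.n_peaks < 4:
        raise NoPeaks(f"need >= 4 peaks for maturation metrics, got {calls.n_peaks}")
    ratios = {}
    for k in PEAK_INDICES:  # 1-based nucleosome index
        i = k - 1
        if i >= calls.n_peaks:
            logger.info("maturation_metrics: peak +%d missing, skipped", k)
            continue
        flank = 0.5 * (calls.trough_heights[i] + calls.trough_heights[i + 1])
        if flank <= 0:
            logger.info("maturation_metrics: zero trough at peak +%d, skipped", k)
            continue
        ratios[k] = float(calls.heights[i] / flank)
    linkers = {}
    for k1, k2 in LINKER_PAIRS:
        if k2 - 1 >= calls.n_peaks:
            continue
        linker = float(calls.positions[k2 - 1] - calls.positions[k1 - 1] - footprint)
        if linker < 0:
            logger.warning(
                "maturation_metrics: negative linker %.1f bp for pair (+%d,+%d)",
                linker, k1, k2,
            )
        linkers[f"+{k1}/+{k2}"] = linker
    return MaturationMetrics(
        peak_trough_ratio=float(np.mean(list(ratios.values()))) if ratios else np.nan,
        linker_length=float(np.mean(list(linkers.values()))) if linkers else np.nan,
        per_peak_ratios=ratios,
        per_pair_linkers=linkers,
        mean_spacing=float(np.mean(calls.spacing())),
    )


def compare_states(
    metrics_by_state: dict[tuple[str, str], list[MaturationMetrics]]
) -> pd.DataFrame:
    """Tidy mean +- SD of each metric across timepoints per (genotype, state).

    ``metrics_by_state`` maps (genotype, chromatin_state) to the list of
    per-timepoint metrics; SD is the sample SD (ddof=1), NaN for a single
    timepoint.
    """
    rows = []
    for (genotype, state), metrics in sorted(metrics_by_state.items()):
        for name in ("peak_trough_ratio", "linker_length", "mean_spacing"):
            vals = np.array([getattr(m, name) for m in metrics], dtype=float)
            rows.append(
                {
                    "genotype": genotype,
                    "state": state,
                    "metric": name,
                    "n_timepoints": len(vals),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
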