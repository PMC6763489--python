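"""Two-stage spike-in normalization.

Stage one scales every library so its spike-in genome contributes a fixed
total of 100,000 reads (spike_factor = 100,000 / spike_reads). Stage two
corrects for sequencing-run depth: the spike-scaled read totals of the
reference-genotype libraries in a batch are brought to 1,000,000 reads, and
that same depth factor is applied to every library in the batch. Factors
are stored on the sample and logged on the track, never baked invisibly
into files; re-normalizing an already-normalized sample is an error.
"""

from __future__ import annotations

import pandas as pd

from .types import CycleNascentError, LibrarySample, ScaleFactors

SPIKE_TARGET = 100_000
DEPTH_TARGET = 1_000_000


class NormalizationError(CycleNascentError):
    pass


def compute_spike_factor(spike_reads: int) -> float:
    """Factor scaling the library so its spike-in reads total 100,000."""
    if spike_reads <= 0:
        raise NormalizationError(
            f"sample not normalizable: spike_reads must be > 0, got {spike_reads}"
        )
    return SPIKE_TARGET / spike_reads


def compute_depth_factor(
    batch: list[LibrarySample], reference_genotype: str = "WT"
) -> float:
    """Batch depth factor: 1 M / mean spike-scaled read total of the
    reference-genotype libraries."""
    reference = [s for s in batch if s.genotype == reference_genotype]
    if not reference:
        raise NormalizationError(
            f"no {reference_genotype!r} reference sample in batch of {len(batch)}"
        )
    scaled = [compute_spike_factor(s.spike_reads) * s.target_reads for s in reference]
    mean_scaled = sum(scaled) / len(scaled)
    if mean_scaled <= 0:
        raise NormalizationError("reference libraries have zero scaled reads")
    return DEPTH_TARGET / mean_scaled


def apply_normalization(
    sample: LibrarySample, factors: ScaleFactors | None = None
) -> LibrarySample:
    """Multiply the sample's track by the composite factor, in place.

    Factors default to the ones already attached to the sample. The
    normalization log guards idempotence: a second application raises.
    """
    if sample.is_normalized:
        raise NormalizationError(
            f"sample {sample.sample_id} is already normalized "
            f"(log: {sample.track.normalization_log})"
        )
    factors = factors or sample.scale_factors
    if factors is None:
        raise NormalizationError(
            f"sample {sample.sample_id} has no scale factors; run normalize_batch"
        )
    sample.track.scale(factors.spike_factor, "spike_factor")
    sample.track.scale(factors.depth_factor, "depth_factor")
    sample.scale_factors = factors
    return sample


def normalize_batch(
    batch: list[LibrarySample], reference_genotype: str = "WT"
) -> list[LibrarySample]:
    """Compute both factors for a batch and apply them to every sample."""
    depth_factor = compute_depth_factor(batch, reference_genotype)
    for sample in batch:
        factors = ScaleFactors(
            spike_factor=compute_spike_factor(sample.spike_reads),
            depth_factor=depth_factor,
        )
        apply_normalization(sample, factors)
    return batch


def factors_table(batch: list[LibrarySample]) -> pd.DataFrame:
    """Sidecar audit table of the factors applied to each sample."""
    rows = []
    for s in batch:
        f = s.scale_factors
        rows.append(
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "timepoint": s.timepoint,
                "replicate": s.replicate,
                "spike_reads": s.spike_reads,
                "target_reads": s.target_reads,
                "spike_factor": f.spike_factor if f else float("nan"),
                "depth_factor": f.depth_factor if f else float("nan"),
                "composite_factor": f.composite if f else float("nan"),
            }
        )
    return pd.DataFrame(rows)
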