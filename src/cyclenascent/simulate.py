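"""Synthetic worlds and libraries with recorded ground truth.

The generator emulates the study design at desk scale: a small yeast-like
genome with replication origins labelled early/late, non-overlapping genes
planted near early origins, near late origins, or far from both; NET-seq
style libraries whose per-gene read counts are Poisson draws around a
planted rate modified by cell-cycle gene dosage, dosage buffering, and
genotype effect multipliers; and phased nucleosome dyad tracks with tunable
repeat length, positional jitter and occupancy for the nascent-vs-mature
chromatin comparison.

Gene dosage follows the replication program: genes near early origins
double their copy number at S30 (early S phase), genes near late origins at
S60 (late S phase), and genes far from any origin at a configurable S60/S90
split; every gene is doubled by S90 (G2). Dosage buffering holds the
per-copy transcription rate at 1/dosage until S90 and releases it in G2, so
wild-type expression stays flat through S phase and steps ~2x in G2 — the
behaviour the analysis modules are asked to recover.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    CycleNascentError,
    GeneRecord,
    GeneSet,
    LibrarySample,
    NUCLEOSOME_FOOTPRINT,
    OriginRecord,
    OriginSet,
    SignalTrack,
    TIMEPOINTS,
)


class PackingError(CycleNascentError):
    """Genes could not be placed without overlap under the config."""


# --------------------------------------------------------------------- config

@dataclass
class WorldConfig:
    """Geometry and planted-rate configuration for a synthetic world."""

    n_genes: int = 300
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chrI": 400_000, "chrII": 400_000}
    )
    n_origins_early: int = 20
    n_origins_late: int = 20
    frac_near_early: float = 1 / 3
    frac_near_late: float = 1 / 3
    origin_window: int = 4000
    gene_length_median: float = 1000.0
    gene_length_log_sd: float = 0.3
    gene_length_min: int = 700
    gene_length_max: int = 2500
    rate_median: float = 0.5  # expected reads/bp at depth 1 in WT G1
    rate_log_sd: float = 0.6
    alpha_mean: float = 0.45  # fraction of a gene's reads in its first 300 bp
    alpha_sd: float = 0.03
    far_s60_fraction: float = 0.5
    dosage_buffering: bool = True
    antisense_fraction: float = 0.05
    edge_margin: int = 2000
    min_gene_gap: int = 150


@dataclass(frozen=True)
class NucleosomeParams:
    """Planted dyad-array parameters for one chromatin state."""

    repeat: float = 160.0  # dyad-to-dyad spacing, bp
    jitter: float = 20.0  # Gaussian positional SD per dyad read, bp
    occupancy: float = 1.0  # fraction of nominal dyad coverage retained
    plus1_offset: int = 75  # +1 dyad position downstream of the TSS, bp
    ndr_width: int = 80  # edge-to-edge nucleosome-depleted region, bp
    n_nucleosomes: int = 8  # +1 .. +8
    include_minus1: bool = True
    background: float = 1.0  # unpositioned-nucleosome density relative to
    # nominal coverage (background reads/bp = background * depth / repeat)

    def __post_init__(self) -> None:
        if self.repeat < NUCLEOSOME_FOOTPRINT:
            raise ValueError(
                f"repeat length {self.repeat} < footprint {NUCLEOSOME_FOOTPRINT}: "
                "nucleosomes would overlap"
            )

    @property
    def linker(self) -> float:
        return self.repeat - NUCLEOSOME_FOOTPRINT


#: Mature chromatin: tightly phased, fully occupied arrays (linker 13 bp).
MATURE_STATE = NucleosomeParams(repeat=160.0, jitter=20.0, occupancy=1.0)
#: Newly replicated chromatin: expanded repeat (linker 20 bp), fuzzier,
#: partially occupied arrays.
NASCENT_STATE = NucleosomeParams(repeat=167.0, jitter=35.0, occupancy=0.6)

CHROMATIN_STATES = {"mature": MATURE_STATE, "nascent": NASCENT_STATE}


@dataclass
class GenotypeSpec:
    """A genotype's planted effects on transcription.

    ``sense_multipliers`` / ``antisense_multipliers`` map timing class
    ("early" | "late" | "far") -> timepoint -> fold multiplier applied on
    top of the wild-type expectation; missing entries default to 1.
    ``alpha`` overrides the per-gene 5'-enrichment fraction (None keeps the
    planted per-gene value).
    """

    name: str
    sense_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    antisense_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    alpha: float | None = None
    global_multiplier: float = 1.0

    def sense_multiplier(self, timing_class: str, timepoint: str) -> float:
        return self.global_multiplier * self.sense_multipliers.get(
            timing_class, {}
        ).get(timepoint, 1.0)

    def antisense_multiplier(self, timing_class: str, timepoint: str) -> float:
        return self.global_multiplier * self.antisense_multipliers.get(
            timing_class, {}
        ).get(timepoint, 1.0)


def wildtype_genotype() -> GenotypeSpec:
    return GenotypeSpec(name="WT")


def assembly_delay_genotype(
    name: str = "asf1_delay",
    early_s30: float = 8.0,
    late_s60: float = 10.5,
    g1_decrease: float = 0.6,
    alpha: float | None = 0.29,
) -> GenotypeSpec:
    """Nucleosome-assembly-delay genotype: a global decrease of nascent
    transcription in arrested G1 cells, a transient burst of promiscuous
    transcription in the window just after a gene's locus replicates
    (decaying by the next timepoint) with matching antisense derepression,
    and a reduced 5'-enrichment shape."""
    sense = {
        "early": {"G1": g1_decrease, "S30": early_s30, "S60": 1.5, "S90": 1.1},
        "late": {"G1": g1_decrease, "S30": 1.1, "S60": late_s60, "S90": 1.5},
        "far": {"G1": g1_decrease},
    }
    antisense = {
        "early": {"S30": early_s30, "S60": 1.5, "S90": 1.1},
        "late": {"S30": 1.1, "S60": late_s60, "S90": 1.5},
    }
    return GenotypeSpec(
        name=name,
        sense_multipliers=sense,
        antisense_multipliers=antisense,
        alpha=alpha,
    )


def strong_assembly_delay_genotype(name: str = "cac1_rtt106_delay") -> GenotypeSpec:
    """Stronger assembly-defect preset (chaperone double mutant scale)."""
    return assembly_delay_genotype(name=name, early_s30=25.0, late_s60=13.0)


@dataclass
class SampleSpec:
    """Names one library to simulate."""

    genotype: GenotypeSpec
    timepoint: str
    replicate: int = 1

    @property
    def sample_id(self) -> str:
        return f"{self.genotype.name}_{self.timepoint}_rep{self.replicate}"


@dataclass
class LibraryParams:
    """Sequencing-emulation parameters shared across libraries."""

    depth: float = 1.0
    spike_median: int = 100_000
    spike_noise_sd: float = 0.02  # residual spike measurement noise (log scale)
    efficiency_sd: float = 0.3  # library efficiency spread (log scale)
    shape_window: int = 300  # width of the 5'-enriched segment, bp


# ---------------------------------------------------------------------- truth

@dataclass
class SyntheticTruth:
    """Planted ground truth: sufficient to recompute every expectation."""

    config: WorldConfig
    chrom_sizes: dict[str, int]
    base_rate: dict[str, float]  # gene id -> lambda (reads/bp, WT G1, depth 1)
    alpha: dict[str, float]  # gene id -> 5'-fraction
    timing_class: dict[str, str]  # gene id -> early | late | far
    far_double_at: dict[str, str]  # far gene id -> S60 | S90
    antisense_fraction: float = 0.05
    nucleosome_states: dict[str, NucleosomeParams] = field(
        default_factory=lambda: dict(CHROMATIN_STATES)
    )

    def dosage(self, gene_id: str, timepoint: str) -> int:
        """Gene copy number at a timepoint (1 before replication, 2 after)."""
        if timepoint in ("G1", "async"):
            return 1
        order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
        cls = self.timing_class[gene_id]
        double_at = {"early": "S30", "late": "S60"}.get(
            cls, self.far_double_at.get(gene_id, "S90")
        )
        return 2 if order[timepoint] >= order[double_at] else 1

    def buffering_factor(self, gene_id: str, timepoint: str) -> float:
        """Per-copy rate attenuation: 1/dosage until G2, released at S90."""
        if not self.config.dosage_buffering or timepoint in ("S90", "async"):
            return 1.0
        return 1.0 / self.dosage(gene_id, timepoint)

    def expected_sense_count(
        self,
        gene: GeneRecord,
        genotype: GenotypeSpec,
        timepoint: str,
        depth: float = 1.0,
    ) -> float:
        cls = self.timing_class[gene.id]
        return (
            self.base_rate[gene.id]
            * gene.length
            * self.dosage(gene.id, timepoint)
            * self.buffering_factor(gene.id, timepoint)
            * genotype.sense_multiplier(cls, timepoint)
            * depth
        )

    def expected_antisense_count(
        self,
        gene: GeneRecord,
        genotype: GenotypeSpec,
        timepoint: str,
        depth: float = 1.0,
    ) -> float:
        cls = self.timing_class[gene.id]
        return (
            self.base_rate[gene.id]
            * gene.length
            * self.dosage(gene.id, timepoint)
            * self.buffering_factor(gene.id, timepoint)
            * self.antisense_fraction
            * genotype.antisense_multiplier(cls, timepoint)
            * depth
        )


@dataclass
class World:
    genes: GeneSet
    origins: OriginSet
    truth: SyntheticTruth

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.truth.chrom_sizes

    def __iter__(self):
        return iter((self.genes, self.origins, self.truth))


# --------------------------------------------------------------- world layout

def _place_origins(config: WorldConfig, rng: np.random.Generator) -> OriginSet:
    labels = ["early"] * config.n_origins_early + ["late"] * config.n_origins_late
    chroms = sorted(config.chrom_sizes)
    # round-robin over chromosomes so both timing classes appear on each
    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    for i, lab in enumerate(labels):
        per_chrom[chroms[i % len(chroms)]].append(lab)
    origins = []
    counter = 0
    for chrom in chroms:
        labs = per_chrom[chrom]
        if not labs:
            continue
        size = config.chrom_sizes[chrom]
        usable = size - 2 * config.edge_margin
        slot = usable / len(labs)
        min_sep = 2 * config.origin_window + config.gene_length_max + 2000
        if slot < min_sep:
            raise PackingError(
                f"chromosome {chrom}: {len(labs)} origins need >= {min_sep} bp "
                f"separation but slots are {slot:.0f} bp"
            )
        for i, lab in enumerate(labs):
            jitter = rng.integers(-int(slot * 0.1), int(slot * 0.1) + 1)
            pos = int(config.edge_margin + (i + 0.5) * slot) + int(jitter)
            origins.append(OriginRecord(chrom, pos, lab, name=f"ORI{counter:03d}"))
            counter += 1
    return OriginSet(origins)


def _min_distance(tss: int, chrom: str, origins: list[OriginRecord]) -> float:
    dists = [abs(tss - o.position) for o in origins if o.chrom == chrom]
    return min(dists) if dists else math.inf


def simulate_world(config: WorldConfig | None = None, seed: int = 0) -> World:
    """Place origins and non-overlapping genes; record planted truth.

    A configurable fraction of genes is placed with its TSS within the
    origin window (default 4 kb) of an early origin and outside the window
    of every late origin, symmetrically for late, and the remainder strictly
    outside both windows; the planted class is therefore exactly recoverable
    by distance-based classification.
    """
    config = config or WorldConfig()
    rng = np.random.default_rng(seed)
    origins = _place_origins(config, rng)
    early = origins.by_timing("early")
    late = origins.by_timing("late")

    n_early = round(config.n_genes * config.frac_near_early)
    n_late = round(config.n_genes * config.frac_near_late)
    if n_early + n_late > config.n_genes:
        raise ValueError("frac_near_early + frac_near_late exceeds 1")
    classes = (
        ["early"] * n_early
        + ["late"] * n_late
        + ["far"] * (config.n_genes - n_early - n_late)
    )

    chroms = sorted(config.chrom_sizes)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes = GeneSet()
    truth = SyntheticTruth(
        config=config,
        chrom_sizes=dict(config.chrom_sizes),
        base_rate={},
        alpha={},
        timing_class={},
        far_double_at={},
        antisense_fraction=config.antisense_fraction,
    )
    window = config.origin_window
    guard = 200  # keep planted TSSs away from the classification boundary

    for gi, cls in enumerate(classes):
        gene_id = f"g{gi:04d}"
        length = int(
            np.clip(
                rng.lognormal(math.log(config.gene_length_median), config.gene_length_log_sd),
                config.gene_length_min,
                config.gene_length_max,
            )
        )
        strand = "+" if rng.random() < 0.5 else "-"
        for _attempt in range(2000):
            if cls == "early" and early:
                anchor = early[rng.integers(len(early))]
                chrom = anchor.chrom
                tss = anchor.position + int(rng.integers(-(window - guard), window - guard + 1))
            elif cls == "late" and late:
                anchor = late[rng.integers(len(late))]
                chrom = anchor.chrom
                tss = anchor.position + int(rng.integers(-(window - guard), window - guard + 1))
            else:
                chrom = chroms[rng.integers(len(chroms))]
                tss = int(
                    rng.integers(
                        config.edge_margin, config.chrom_sizes[chrom] - config.edge_margin
                    )
                )
            start = tss if strand == "+" else tss - length + 1
            end = start + length
            if start < config.edge_margin or end > config.chrom_sizes[chrom] - config.edge_margin:
                continue
            d_early = _min_distance(tss, chrom, early)
            d_late = _min_distance(tss, chrom, late)
            if cls == "early" and not (d_early <= window and d_late > window + guard):
                continue
            if cls == "late" and not (d_late <= window and d_early > window + guard):
                continue
            if cls == "far" and not (
                d_early > window + guard and d_late > window + guard
            ):
                continue
            gap = config.min_gene_gap
            if any(start - gap < e and end + gap > s for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            genes.add(GeneRecord(gene_id, chrom, start, end, strand))
            truth.base_rate[gene_id] = float(
                rng.lognormal(math.log(config.rate_median), config.rate_log_sd)
            )
            truth.alpha[gene_id] = float(
                np.clip(rng.normal(config.alpha_mean, config.alpha_sd), 0.0, 0.9)
            )
            truth.timing_class[gene_id] = cls
            if cls == "far":
                truth.far_double_at[gene_id] = (
                    "S60" if rng.random() < config.far_s60_fraction else "S90"
                )
            break
        else:
            raise PackingError(
                f"could not place gene {gene_id} (class {cls}, length {length}) "
                "after 2000 attempts; genome too crowded for the config"
            )
    return World(genes, origins, truth)


# ------------------------------------------------------------------ libraries

def _draw_positions(
    gene: GeneRecord,
    n: int,
    alpha: float,
    shape_window: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """3'-end positions under the two-segment shape: a fraction ``alpha`` of
    reads uniform over the first ``shape_window`` bp of the gene (5' side),
    the rest uniform over the remainder. Genes not longer than the window
    collapse to a uniform body distribution."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if gene.length <= shape_window or alpha <= 0:
        offsets = rng.integers(0, gene.length, size=n)
    else:
        n5 = rng.binomial(n, alpha)
        off5 = rng.integers(0, shape_window, size=n5)
        off3 = rng.integers(shape_window, gene.length, size=n - n5)
        offsets = np.concatenate([off5, off3])
    if gene.strand == "+":
        return gene.start + offsets
    return gene.end - 1 - offsets


def simulate_netseq_library(
    world: World,
    sample_spec: SampleSpec,
    params: LibraryParams | None = None,
    seed: int = 0,
) -> LibrarySample:
    """Simulate one NET-seq-like library as a raw 3'-end count track.

    Per-gene sense counts are Poisson around the planted expectation times a
    library-wide efficiency factor; the same efficiency scales the spike-in
    median, which is what makes spike normalization informative. Antisense
    reads are drawn at the planted antisense fraction, uniform over the gene
    body on the opposite strand.
    """
    params = params or LibraryParams()
    if params.depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    truth = world.truth
    efficiency = float(rng.lognormal(0.0, params.efficiency_sd))
    track = SignalTrack.zeros(world.chrom_sizes, stranded=True)
    total = 0
    for gene in world.genes:
        geno = sample_spec.genotype
        mean_sense = (
            truth.expected_sense_count(gene, geno, sample_spec.timepoint, params.depth)
            * efficiency
        )
        n_sense = int(rng.poisson(mean_sense))
        alpha = geno.alpha if geno.alpha is not None else truth.alpha[gene.id]
        pos = _draw_positions(gene, n_sense, alpha, params.shape_window, rng)
        np.add.at(track.array(gene.chrom, gene.strand), pos, 1.0)

        mean_anti = (
            truth.expected_antisense_count(gene, geno, sample_spec.timepoint, params.depth)
            * efficiency
        )
        n_anti = int(rng.poisson(mean_anti))
        anti_pos = gene.start + rng.integers(0, gene.length, size=n_anti)
        np.add.at(track.array(gene.chrom, gene.antisense_strand), anti_pos, 1.0)
        total += n_sense + n_anti

    spike_reads = max(
        1,
        int(
            round(
                params.spike_median
                * efficiency
                * rng.lognormal(0.0, params.spike_noise_sd)
            )
        ),
    )
    return LibrarySample(
        sample_id=sample_spec.sample_id,
        genotype=sample_spec.genotype.name,
        timepoint=sample_spec.timepoint,
        replicate=sample_spec.replicate,
        track=track,
        spike_reads=spike_reads,
        target_reads=float(total),
    )


def simulate_timecourse(
    world: World,
    genotypes: list[GenotypeSpec],
    timepoints: tuple[str, ...] = TIMEPOINTS,
    n_replicates: int = 2,
    params: LibraryParams | None = None,
    seed: int = 0,
) -> list[LibrarySample]:
    """Simulate the full release time course: every genotype at every
    timepoint with the given replicate count, seeded independently."""
    seeds = np.random.SeedSequence(seed).spawn(
        len(genotypes) * len(timepoints) * n_replicates
    )
    samples = []
    i = 0
    for geno in genotypes:
        for tp in timepoints:
            for rep in range(1, n_replicates + 1):
                sub_seed = int(seeds[i].generate_state(1)[0] % (2**31))
                i += 1
                samples.append(
                    simulate_netseq_library(
                        world, SampleSpec(geno, tp, rep), params, seed=sub_seed
                    )
                )
    return samples


# ---------------------------------------------------------------- dyad tracks

def resolve_state(state: str | NucleosomeParams, world: World | None = None) -> NucleosomeParams:
    if isinstance(state, NucleosomeParams):
        return state
    states = world.truth.nucleosome_states if world is not None else CHROMATIN_STATES
    if state not in states:
        raise ValueError(f"unknown chromatin state {state!r}")
    return states[state]


def simulate_dyad_track(
    world: World,
    chromatin_state: str | NucleosomeParams = "mature",
    depth: float = 40.0,
    seed: int = 0,
) -> SignalTrack:
    """Pool phased per-gene dyad arrays into an unstranded density track.

    For every gene, dyads are planted at TSS + plus1_offset + k*repeat
    (k = 0..n_nucleosomes-1, strand-oriented), optionally with a -1 dyad
    upstream of the NDR; each dyad receives Poisson(depth * occupancy) reads
    jittered by a Gaussian of SD ``jitter`` bp. Unpositioned nucleosomes are
    emulated as a uniform read background over the gene's TSS neighborhood
    at ``background`` times the nominal per-bp coverage (depth / repeat).
    """
    params = resolve_state(chromatin_state, world)
    rng = np.random.default_rng(seed)
    track = SignalTrack.zeros(world.chrom_sizes, stranded=False)
    offsets = [
        params.plus1_offset + k * params.repeat for k in range(params.n_nucleosomes)
    ]
    if params.include_minus1:
        offsets = [
            params.plus1_offset - NUCLEOSOME_FOOTPRINT - params.ndr_width
        ] + offsets
    offsets_arr = np.asarray(offsets, dtype=float)
    for gene in world.genes:
        direction = 1 if gene.strand == "+" else -1
        centers = gene.tss + direction * offsets_arr
        counts = rng.poisson(depth * params.occupancy, size=len(centers))
        size = world.chrom_sizes[gene.chrom]
        arr = track.array(gene.chrom, "+")
        for center, n in zip(centers, counts):
            if n == 0:
                continue
            pos = np.rint(center + rng.normal(0.0, params.jitter, size=n)).astype(
                np.int64
            )
            np.clip(pos, 0, size - 1, out=pos)
            np.add.at(arr, pos, 1.0)
        if params.background > 0:
            bg_lo, bg_hi = -400, 1800  # oriented TSS neighborhood
            n_bg = rng.poisson(
                depth * params.background * (bg_hi - bg_lo) / params.repeat
            )
            bg_off = rng.integers(bg_lo, bg_hi, size=n_bg)
            bg_pos = gene.tss + direction * bg_off
            bg_pos = bg_pos[(bg_pos >= 0) & (bg_pos < size)]
            np.add.at(arr, bg_pos, 1.0)
    return track


def maturation_state(
    chase_minutes: float,
    tau: float = 4.0,
    nascent: NucleosomeParams = NASCENT_STATE,
    mature: NucleosomeParams = MATURE_STATE,
) -> NucleosomeParams:
    """Chromatin state a given chase time after replication: parameters relax
    exponentially from the nascent toward the mature values with timescale
    ``tau`` minutes (slow assembly genotypes use a larger tau)."""
    w = math.exp(-chase_minutes / tau)
    mix = lambda a, b: b + (a - b) * w  # noqa: E731
    return replace(
        nascent,
        repeat=mix(nascent.repeat, mature.repeat),
        jitter=mix(nascent.jitter, mature.jitter),
        occupancy=mix(nascent.occupancy, mature.occupancy),
    )
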