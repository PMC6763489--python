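"""Core domain types shared by every stage of the pipeline.

Coordinates are 0-based half-open everywhere (BED-native). The TSS of a
minus-strand gene is ``end - 1`` and its TTS is ``start``; window helpers on
:class:`GeneRecord` take care of the strand reflection so downstream code can
reason in "5' window" / "3' window" terms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

TIMEPOINTS = ("G1", "S30", "S60", "S90")
VALID_TIMEPOINTS = TIMEPOINTS + ("async",)
BIOTYPES = ("coding", "CUT", "SUT")
NUCLEOSOME_FOOTPRINT = 147  # bp wrapped by the histone octamer


class CycleNascentError(Exception):
    """Base class for pipeline errors."""


class ParseError(CycleNascentError):
    """A file could not be parsed; message carries path and line number."""


@dataclass(frozen=True)
class GeneRecord:
    """A transcribed region: coding gene, CUT or SUT.

    ``start``/``end`` are 0-based half-open on ``chrom``; ``strand`` is
    ``"+"`` or ``"-"``.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: unknown strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def five_prime_window(self, width: int) -> tuple[int, int]:
        """Half-open interval covering the first ``width`` bp from the TSS."""
        w = min(width, self.length)
        if self.strand == "+":
            return self.start, self.start + w
        return self.end - w, self.end

    def three_prime_window(self, width: int) -> tuple[int, int]:
        """Half-open interval covering the last ``width`` bp up to the TTS."""
        w = min(width, self.length)
        if self.strand == "+":
            return self.end - w, self.end
        return self.start, self.start + w

    @property
    def antisense_strand(self) -> str:
        return "-" if self.strand == "+" else "+"


class GeneSet:
    """Ordered collection of :class:`GeneRecord` with unique ids."""

    def __init__(self, genes: list[GeneRecord] | None = None):
        self._genes: list[GeneRecord] = []
        self._by_id: dict[str, GeneRecord] = {}
        for g in genes or []:
            self.add(g)

    def add(self, gene: GeneRecord) -> None:
        if gene.id in self._by_id:
            raise ValueError(f"duplicate gene id {gene.id!r}")
        self._genes.append(gene)
        self._by_id[gene.id] = gene

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSet):
            return NotImplemented
        return self._genes == other._genes

    def subset(self, ids) -> "GeneSet":
        return GeneSet([self._by_id[i] for i in ids])

    def by_biotype(self, biotype: str) -> "GeneSet":
        return GeneSet([g for g in self if g.biotype == biotype])


@dataclass(frozen=True)
class OriginRecord:
    """A replication origin with its firing-timing label."""

    chrom: str
    position: int
    timing: str
    name: str = "."

    def __post_init__(self) -> None:
        if self.timing not in ("early", "late"):
            raise ValueError(
                f"origin {self.name} at {self.chrom}:{self.position}: "
                f"timing must be 'early' or 'late', got {self.timing!r}"
            )


class OriginSet:
    """Replication origins, kept sorted by (chrom, position)."""

    def __init__(self, origins: list[OriginRecord] | None = None):
        self._origins = sorted(
            origins or [], key=lambda o: (o.chrom, o.position)
        )

    def __len__(self) -> int:
        return len(self._origins)

    def __iter__(self) -> Iterator[OriginRecord]:
        return iter(self._origins)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OriginSet):
            return NotImplemented
        return self._origins == other._origins

    def by_timing(self, timing: str) -> list[OriginRecord]:
        return [o for o in self._origins if o.timing == timing]


class SignalTrack:
    """Per-base non-negative signal, one dense array per chromosome per strand.

    A stranded track (NET-seq 3'-end counts) carries ``plus`` and ``minus``
    arrays; an unstranded track (nucleosome dyad density) carries only
    ``plus`` and has ``stranded == False``. ``normalization_log`` is the
    ordered list of (factor_name, factor_value) pairs already applied, so the
    raw -> normalized mapping is reproducible from the object alone.
    """

    def __init__(
        self,
        chrom_sizes: dict[str, int],
        plus: dict[str, np.ndarray],
        minus: dict[str, np.ndarray] | None,
        normalization_log: list[tuple[str, float]] | None = None,
    ):
        self.chrom_sizes = dict(chrom_sizes)
        self.plus = plus
        self.minus = minus
        self.normalization_log = list(normalization_log or [])
        self._validate()

    def _validate(self) -> None:
        for arrays in filter(None, (self.plus, self.minus)):
            if set(arrays) != set(self.chrom_sizes):
                raise ValueError("track chromosomes do not match chrom_sizes")
            for chrom, arr in arrays.items():
                if len(arr) != self.chrom_sizes[chrom]:
                    raise ValueError(
                        f"{chrom}: array length {len(arr)} != size {self.chrom_sizes[chrom]}"
                    )
                if np.any(arr < 0):
                    raise ValueError(f"{chrom}: negative signal values")

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int], stranded: bool = True) -> "SignalTrack":
        plus = {c: np.zeros(n) for c, n in chrom_sizes.items()}
        minus = {c: np.zeros(n) for c, n in chrom_sizes.items()} if stranded else None
        return cls(chrom_sizes, plus, minus)

    @property
    def stranded(self) -> bool:
        return self.minus is not None

    def array(self, chrom: str, strand: str = "+") -> np.ndarray:
        if strand == "+":
            return self.plus[chrom]
        if strand == "-":
            if self.minus is None:
                raise ValueError("unstranded track has no minus strand")
            return self.minus[chrom]
        raise ValueError(f"unknown strand {strand!r}")

    def total(self) -> float:
        tot = sum(float(a.sum()) for a in self.plus.values())
        if self.minus is not None:
            tot += sum(float(a.sum()) for a in self.minus.values())
        return tot

    def scale(self, factor: float, name: str) -> None:
        """Multiply every value by ``factor`` in place, logging the step."""
        if factor <= 0:
            raise ValueError(f"scale factor {name} must be > 0, got {factor}")
        for arrays in filter(None, (self.plus, self.minus)):
            for arr in arrays.values():
                arr *= factor
        self.normalization_log.append((name, float(factor)))

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            self.chrom_sizes,
            {c: a.copy() for c, a in self.plus.items()},
            None if self.minus is None else {c: a.copy() for c, a in self.minus.items()},
            list(self.normalization_log),
        )

    def allclose(self, other: "SignalTrack", rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        if self.chrom_sizes != other.chrom_sizes or self.stranded != other.stranded:
            return False
        for strand_self, strand_other in (
            [(self.plus, other.plus)] + ([(self.minus, other.minus)] if self.stranded else [])
        ):
            for chrom in self.chrom_sizes:
                if not np.allclose(strand_self[chrom], strand_other[chrom], rtol=rtol, atol=atol):
                    return False
        return True


@dataclass
class ScaleFactors:
    """The two-stage spike-in normalization factors for one library.

    ``spike_factor`` scales the library so its spike-in genome contributes a
    fixed read total; ``depth_factor`` is shared across a batch and scales
    the spike-corrected reference-genotype libraries to a fixed depth.
    """

    spike_factor: float
    depth_factor: float = 1.0

    @property
    def composite(self) -> float:
        return self.spike_factor * self.depth_factor


@dataclass
class LibrarySample:
    """One sequencing library with its metadata and (possibly raw) track."""

    sample_id: str
    genotype: str
    timepoint: str
    replicate: int
    track: SignalTrack
    spike_reads: int
    target_reads: float
    scale_factors: ScaleFactors | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in VALID_TIMEPOINTS:
            raise ValueError(
                f"sample {self.sample_id}: unknown timepoint {self.timepoint!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id}: replicate must be >= 1")

    @property
    def is_normalized(self) -> bool:
        return any(name == "spike_factor" for name, _ in self.track.normalization_log)
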