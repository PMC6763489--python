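"""Readers and writers for the plain-text formats the pipeline touches.

Annotations come in as BED6 (0-based half-open, an optional 7th column
carrying the biotype) or GFF3 (1-based closed, converted on read); signal
travels as 4-column bedGraph, one file per strand with the suffixes
``.plus.bedgraph`` / ``.minus.bedgraph``; origins as 5-column BED-like with
an early/late timing column; sample sheets and count tables as TSV with a
header row.
"""

from __future__ import annotations

import os
from urllib.parse import unquote

import numpy as np
import pandas as pd

from .types import (
    GeneRecord,
    GeneSet,
    LibrarySample,
    OriginRecord,
    OriginSet,
    ParseError,
    SignalTrack,
)

PLUS_SUFFIX = ".plus.bedgraph"
MINUS_SUFFIX = ".minus.bedgraph"


def _lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


# ---------------------------------------------------------------- chrom sizes

def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in _lines(path):
        fields = line.split()
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad size {fields[1]!r}") from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ----------------------------------------------------------------- annotation

def read_gene_annotation(path: str, format: str = "BED6") -> GeneSet:
    """Read genes from BED6 (optionally BED6+biotype) or GFF3.

    GFF3 coordinates (1-based closed) are converted to the internal 0-based
    half-open convention. Duplicate ids are rejected.
    """
    if format == "BED6":
        return _read_bed6(path)
    if format == "GFF3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_bed6(path: str) -> GeneSet:
    genes = GeneSet()
    for lineno, line in _lines(path):
        fields = line.split()
        if len(fields) not in (6, 7):
            raise ParseError(
                f"{path}:{lineno}: expected 6 or 7 columns, got {len(fields)}"
            )
        chrom, start, end, name, _score, strand = fields[:6]
        biotype = fields[6] if len(fields) == 7 else "coding"
        try:
            record = GeneRecord(name, chrom, int(start), int(end), strand, biotype)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        try:
            genes.add(record)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _read_gff3(path: str) -> GeneSet:
    genes = GeneSet()
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
        chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
        if ftype not in ("gene", "ncRNA_gene", "transcript"):
            continue
        attributes = {}
        for item in attrs.split(";"):
            if "=" in item:
                key, value = item.split("=", 1)
                attributes[key.strip()] = unquote(value.strip())
        gene_id = attributes.get("ID") or attributes.get("Name")
        if gene_id is None:
            raise ParseError(f"{path}:{lineno}: feature has no ID attribute")
        biotype = attributes.get("biotype", "coding")
        try:
            # GFF3 is 1-based closed: [start, end] -> [start-1, end).
            record = GeneRecord(gene_id, chrom, int(start) - 1, int(end), strand, biotype)
            genes.add(record)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_annotation(genes: GeneSet, path: str) -> None:
    """Write BED6 plus a 7th biotype column (readable back losslessly)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\t{g.biotype}\n"
            )


# -------------------------------------------------------------------- origins

def read_origin_annotation(path: str) -> OriginSet:
    """BED-like origins: chrom, start, end, name, timing (early|late)."""
    origins = []
    for lineno, line in _lines(path):
        fields = line.split()
        if len(fields) < 5:
            raise ParseError(
                f"{path}:{lineno}: expected >= 5 columns (chrom start end name timing)"
            )
        chrom, start, _end, name, timing = fields[:5]
        try:
            origins.append(OriginRecord(chrom, int(start), timing, name))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return OriginSet(origins)


def write_origin_annotation(origins: OriginSet, path: str) -> None:
    with open(path, "w") as fh:
        for o in origins:
            fh.write(f"{o.chrom}\t{o.position}\t{o.position + 1}\t{o.name}\t{o.timing}\n")


# ------------------------------------------------------------------- bedGraph

def _read_bedgraph_into(arrays: dict[str, np.ndarray], path: str) -> None:
    for lineno, line in _lines(path):
        fields = line.split()
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        chrom, start, end, value = fields
        if chrom not in arrays:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            start_i, end_i, val = int(start), int(end), float(value)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad interval/value") from exc
        if not (0 <= start_i < end_i <= len(arrays[chrom])):
            raise ParseError(
                f"{path}:{lineno}: interval [{start_i}, {end_i}) outside "
                f"chromosome {chrom} of length {len(arrays[chrom])}"
            )
        if val < 0:
            raise ParseError(f"{path}:{lineno}: negative value {val}")
        arrays[chrom][start_i:end_i] = val


def read_signal_track(
    path_plus: str, path_minus: str, chrom_sizes: dict[str, int]
) -> SignalTrack:
    """Densify a bedGraph pair into per-base arrays; uncovered bases are 0."""
    track = SignalTrack.zeros(chrom_sizes, stranded=True)
    _read_bedgraph_into(track.plus, path_plus)
    _read_bedgraph_into(track.minus, path_minus)
    return track


def read_dyad_track(path: str, chrom_sizes: dict[str, int]) -> SignalTrack:
    """Read an unstranded (dyad-density) bedGraph."""
    track = SignalTrack.zeros(chrom_sizes, stranded=False)
    _read_bedgraph_into(track.plus, path)
    return track


def _write_bedgraph(arrays: dict[str, np.ndarray], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(arrays):
            arr = arrays[chrom]
            if len(arr) == 0:
                continue
            # run-length merge; zero runs omitted
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(v)}\n")


def _fmt(v: float) -> str:
    return repr(float(v))


def write_signal_track(track: SignalTrack, out_plus: str, out_minus: str | None = None) -> None:
    """Write a track as run-length-merged bedGraph, one file per strand."""
    _write_bedgraph(track.plus, out_plus)
    if track.stranded:
        if out_minus is None:
            raise ValueError("stranded track requires an out_minus path")
        _write_bedgraph(track.minus, out_minus)


# --------------------------------------------------------------- sample sheet

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "genotype",
    "timepoint",
    "replicate",
    "spike_reads",
    "target_reads",
    "plus_path",
    "minus_path",
]


def write_sample_sheet(samples: list[LibrarySample], out_dir: str, path: str) -> None:
    """Write each sample's track as a bedGraph pair plus a sheet referencing
    them; track paths are stored relative to the sheet's directory so a run
    directory can be relocated."""
    sheet_dir = os.path.dirname(os.path.abspath(path))
    rows = []
    for s in samples:
        plus_path = os.path.join(out_dir, s.sample_id + PLUS_SUFFIX)
        minus_path = os.path.join(out_dir, s.sample_id + MINUS_SUFFIX)
        write_signal_track(s.track, plus_path, minus_path)
        rows.append(
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "timepoint": s.timepoint,
                "replicate": s.replicate,
                "spike_reads": s.spike_reads,
                "target_reads": s.target_reads,
                "plus_path": os.path.relpath(os.path.abspath(plus_path), sheet_dir),
                "minus_path": os.path.relpath(os.path.abspath(minus_path), sheet_dir),
            }
        )
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str, chrom_sizes: dict[str, int]) -> list[LibrarySample]:
    sheet = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    sheet_dir = os.path.dirname(os.path.abspath(path))
    resolve = lambda p: p if os.path.isabs(p) else os.path.join(sheet_dir, p)  # noqa: E731
    samples = []
    for row in sheet.itertuples(index=False):
        track = read_signal_track(
            resolve(row.plus_path), resolve(row.minus_path), chrom_sizes
        )
        samples.append(
            LibrarySample(
                sample_id=str(row.sample_id),
                genotype=str(row.genotype),
                timepoint=str(row.timepoint),
                replicate=int(row.replicate),
                track=track,
                spike_reads=int(row.spike_reads),
                target_reads=float(row.target_reads),
            )
        )
    return samples


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
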