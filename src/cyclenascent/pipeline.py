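"""End-to-end orchestration: simulate -> normalize -> quantify -> diff ->
profile -> timing -> nucleosome, from one config, fully determined by
(config, seed), with a machine-readable run report.

In synthetic mode (no sample sheet configured) the world and all libraries
are generated; in real-input mode annotations, origins, chrom sizes,
bedGraph pairs and dyad tracks are read from the configured paths. Any
stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io, nucleosome, polii, quantify, timing
from .normalize import factors_table, normalize_batch
from .simulate import (
    LibraryParams,
    WorldConfig,
    assembly_delay_genotype,
    maturation_state,
    simulate_dyad_track,
    simulate_timecourse,
    simulate_world,
    strong_assembly_delay_genotype,
    wildtype_genotype,
)
from .types import CycleNascentError, SignalTrack, TIMEPOINTS

logger = logging.getLogger(__name__)

MUTANT_PRESETS = {
    "asf1_delay": assembly_delay_genotype,
    "cac1_rtt106_delay": strong_assembly_delay_genotype,
}


class PipelineError(CycleNascentError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc


@dataclass
class RunConfig:
    """Flat run configuration; every parameter defaults to the pipeline's
    standard value (300 bp ratio window, 4 kb origin window, 500 metagene
    bins, 1.5 fold / 0.05 FDR thresholds, 147 bp footprint)."""

    seed: int = 0
    out_dir: str = "cyclenascent_run"
    # real-input paths; all None -> synthetic mode
    annotation_path: str | None = None
    annotation_format: str = "BED6"
    origins_path: str | None = None
    chrom_sizes_path: str | None = None
    sample_sheet_path: str | None = None
    dyad_track_paths: dict[str, str] = field(default_factory=dict)
    # synthetic world and libraries
    world: WorldConfig = field(default_factory=WorldConfig)
    library: LibraryParams = field(default_factory=LibraryParams)
    mutant_preset: str = "asf1_delay"
    n_replicates: int = 2
    # stages to run, in order
    stages: tuple[str, ...] = (
        "simulate",
        "normalize",
        "quantify",
        "diff",
        "profile",
        "timing",
        "nucleosome",
    )
    write_tracks: bool = False
    # analysis parameters
    reference_genotype: str = "WT"
    ratio_window: int = polii.RATIO_WINDOW
    metagene_bins: int = polii.METAGENE_BINS
    heatmap_span: int = polii.HEATMAP_SPAN
    heatmap_bin: int = polii.HEATMAP_BIN
    fc_threshold: float = quantify.FC_THRESHOLD
    fdr_threshold: float = quantify.FDR_THRESHOLD
    pseudocount: float = 1.0
    origin_window: int = timing.ORIGIN_WINDOW
    origin_anchor: str = "tss"
    smooth_width: int = nucleosome.SMOOTH_WIDTH
    footprint: int = 147
    profile_flank: tuple[int, int] = nucleosome.DEFAULT_FLANK
    dyad_depth: float = 40.0
    chase_minutes: tuple[float, ...] = (2.0, 5.0, 15.0)
    tau_reference: float = 4.0
    tau_mutant: float = 15.0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "world" in kwargs:
            kwargs["world"] = WorldConfig(**kwargs["world"])
        if "library" in kwargs:
            kwargs["library"] = LibraryParams(**kwargs["library"])
        for key in ("stages", "chase_minutes", "profile_flank"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @property
    def synthetic(self) -> bool:
        return self.sample_sheet_path is None


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _merged_track(samples) -> SignalTrack:
    """Average the (normalized) tracks of replicate samples."""
    merged = samples[0].track.copy()
    for s in samples[1:]:
        for strand_arrays, other in (
            (merged.plus, s.track.plus),
            (merged.minus or {}, s.track.minus or {}),
        ):
            for chrom in strand_arrays:
                strand_arrays[chrom] += other[chrom]
    for arrays in filter(None, (merged.plus, merged.minus)):
        for chrom in arrays:
            arrays[chrom] /= len(samples)
    return merged


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the run report (also written to
    ``<out_dir>/run_report.json``)."""
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda *parts: os.path.join(config.out_dir, *parts)  # noqa: E731
    written: list[str] = []
    report: dict = {
        "parameters": _jsonable(dataclasses.asdict(config)),
        "stages": list(config.stages),
        "excluded": {},
        "results": {},
    }

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    sub_seed = lambda i: int(seeds[i].generate_state(1)[0] % (2**31))  # noqa: E731

    world = None
    samples = None
    genes = None
    chrom_sizes = None

    if "simulate" in config.stages and config.synthetic:
        with _stage("simulate"):
            world = simulate_world(config.world, seed=sub_seed(0))
            genes = world.genes
            chrom_sizes = world.chrom_sizes
            if config.mutant_preset not in MUTANT_PRESETS:
                raise ValueError(f"unknown mutant preset {config.mutant_preset!r}")
            genotypes = [wildtype_genotype(), MUTANT_PRESETS[config.mutant_preset]()]
            samples = simulate_timecourse(
                world,
                genotypes,
                TIMEPOINTS,
                config.n_replicates,
                config.library,
                seed=sub_seed(1),
            )
            os.makedirs(out("world"), exist_ok=True)
            io.write_gene_annotation(genes, out("world", "genes.bed"))
            io.write_origin_annotation(world.origins, out("world", "origins.bed"))
            io.write_chrom_sizes(chrom_sizes, out("world", "chrom.sizes"))
            _write_truth(world, out("world", "truth.tsv"))
            written += [
                out("world", "genes.bed"),
                out("world", "origins.bed"),
                out("world", "chrom.sizes"),
                out("world", "truth.tsv"),
            ]
            if config.write_tracks:
                os.makedirs(out("libraries"), exist_ok=True)
                io.write_sample_sheet(
                    samples, out("libraries"), out("libraries", "sample_sheet.tsv")
                )
                written.append(out("libraries", "sample_sheet.tsv"))
                for s in samples:
                    written.append(out("libraries", s.sample_id + io.PLUS_SUFFIX))
                    written.append(out("libraries", s.sample_id + io.MINUS_SUFFIX))
    elif not config.synthetic:
        with _stage("inputs"):
            if config.chrom_sizes_path is None:
                raise ValueError("real-input mode requires chrom_sizes_path")
            chrom_sizes = io.read_chrom_sizes(config.chrom_sizes_path)
            if config.annotation_path is None:
                raise ValueError("real-input mode requires annotation_path")
            genes = io.read_gene_annotation(
                config.annotation_path, config.annotation_format
            )
            samples = io.read_sample_sheet(config.sample_sheet_path, chrom_sizes)

    mutant_names = sorted(
        {s.genotype for s in samples or []} - {config.reference_genotype}
    )

    if "normalize" in config.stages:
        with _stage("normalize"):
            normalize_batch(samples, config.reference_genotype)
            table = factors_table(samples)
            io.write_table(table, out("scale_factors.tsv"))
            written.append(out("scale_factors.tsv"))
            report["results"]["normalize"] = {
                "n_samples": len(samples),
                "depth_factor": float(table["depth_factor"].iloc[0]),
            }

    counts = counts_anti = None
    if "quantify" in config.stages:
        with _stage("quantify"):
            counts = quantify.build_counts_table(samples, genes, mode="sense")
            counts_anti = quantify.build_counts_table(samples, genes, mode="antisense")
            io.write_table(counts, out("counts_sense.tsv"))
            io.write_table(counts_anti, out("counts_antisense.tsv"))
            written += [out("counts_sense.tsv"), out("counts_antisense.tsv")]

    if "diff" in config.stages and mutant_names:
        with _stage("diff"):
            mutant = mutant_names[0]
            mat_wt = quantify.replicate_matrix(counts, config.reference_genotype, "G1")
            mat_mut = quantify.replicate_matrix(counts, mutant, "G1")
            fc = quantify.fold_change_table(mat_wt, mat_mut, config.pseudocount)
            n_up, n_down = quantify.count_regulated(
                fc, config.fc_threshold, config.fdr_threshold
            )
            io.write_table(fc.reset_index(), out("diff_G1.tsv"))
            written.append(out("diff_G1.tsv"))
            report["results"]["diff_G1"] = {
                "contrast": f"{mutant}_vs_{config.reference_genotype}",
                "n_up": n_up,
                "n_down": n_down,
            }

    if "profile" in config.stages:
        with _stage("profile"):
            by_geno = {}
            for geno in [config.reference_genotype] + mutant_names:
                reps = [
                    s for s in samples if s.genotype == geno and s.timepoint == "G1"
                ]
                if reps:
                    by_geno[geno] = _merged_track(reps)
            ratio_results = {}
            for geno, track in by_geno.items():
                rset = polii.ratio_set(track, genes, config.ratio_window)
                io.write_table(rset.table, out(f"ratios_{geno}.tsv"))
                written.append(out(f"ratios_{geno}.tsv"))
                ratio_results[geno] = rset
                report["excluded"][f"ratio_short_{geno}"] = rset.n_short_excluded
                prof = polii.metagene(track, genes, config.metagene_bins)
                io.write_table(prof.table, out(f"metagene_{geno}.tsv"))
                written.append(out(f"metagene_{geno}.tsv"))
                report["excluded"][f"metagene_short_{geno}"] = prof.n_excluded_short
                report["excluded"][f"metagene_edge_{geno}"] = prof.n_excluded_edge
                report["excluded"][f"metagene_zero_{geno}"] = prof.n_excluded_zero
            prof_results = {}
            ref = ratio_results.get(config.reference_genotype)
            for geno in mutant_names:
                if ref is None or geno not in ratio_results:
                    continue
                u, p = polii.ratio_compare(ratio_results[geno].ratios, ref.ratios)
                prof_results[geno] = {
                    "median_ratio": float(np.median(ratio_results[geno].ratios)),
                    "median_ratio_ref": float(np.median(ref.ratios)),
                    "U": u,
                    "p": p,
                }
                hm = polii.heatmap_matrix(
                    by_geno[config.reference_genotype],
                    by_geno[geno],
                    genes,
                    config.heatmap_span,
                    config.heatmap_bin,
                    config.pseudocount,
                )
                io.write_table(hm.to_frame(), out(f"heatmap_{geno}.tsv"))
                written.append(out(f"heatmap_{geno}.tsv"))
            report["results"]["profile"] = prof_results

    if "timing" in config.stages:
        with _stage("timing"):
            if config.synthetic:
                if world is None:
                    raise ValueError("timing stage needs the simulate stage")
                origins = world.origins
            else:
                if config.origins_path is None:
                    raise ValueError("origins file not configured")
                origins = io.read_origin_annotation(config.origins_path)
            classes = timing.classify_genes(
                genes, origins, config.origin_window, config.origin_anchor
            )
            io.write_table(classes.reset_index(), out("timing_classes.tsv"))
            written.append(out("timing_classes.tsv"))
            tc = timing.timecourse_summary(counts, classes, config.reference_genotype)
            io.write_table(tc.summary, out("timecourse_sense.tsv"))
            io.write_table(tc.contrasts, out("contrasts_sense.tsv"))
            tc_anti = timing.timecourse_summary(
                counts_anti, classes, config.reference_genotype
            )
            io.write_table(tc_anti.summary, out("timecourse_antisense.tsv"))
            io.write_table(tc_anti.contrasts, out("contrasts_antisense.tsv"))
            written += [
                out("timecourse_sense.tsv"),
                out("contrasts_sense.tsv"),
                out("timecourse_antisense.tsv"),
                out("contrasts_antisense.tsv"),
            ]
            wt_counts = counts[counts["genotype"] == config.reference_genotype]
            buffering = timing.buffering_step(wt_counts, classes)
            report["results"]["timing"] = {
                "class_counts": classes["timing_class"].value_counts().to_dict(),
                "buffering_step_G2_vs_G1": buffering,
            }

    if "nucleosome" in config.stages:
        with _stage("nucleosome"):
            report["results"]["nucleosome"] = _nucleosome_stage(
                config, world, genes, out, written, sub_seed(2)
            )

    with _stage("report"):
        report["checksums"] = {
            os.path.relpath(p, config.out_dir): _sha256(p) for p in sorted(written)
        }
        report_path = out("run_report.json")
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _nucleosome_stage(config, world, genes, out, written, seed):
    flank = tuple(config.profile_flank)
    results = {}
    if config.synthetic:
        if world is None:
            raise ValueError("nucleosome stage needs the simulate stage")
        seeds = np.random.SeedSequence(seed).spawn(2 * len(config.chase_minutes) + 2)
        i = 0
        metrics_by: dict[tuple[str, str], list] = {}
        rows = []
        for geno, tau in (
            (config.reference_genotype, config.tau_reference),
            ("mutant", config.tau_mutant),
        ):
            mature_seed = int(seeds[i].generate_state(1)[0] % (2**31))
            i += 1
            track = simulate_dyad_track(world, "mature", config.dyad_depth, mature_seed)
            metrics = _profile_metrics(track, genes, config)
            metrics_by[(geno, "mature")] = [metrics]
            rows.append((geno, "mature", "bulk", metrics))
            nascent_list = []
            for chase in config.chase_minutes:
                state = maturation_state(chase, tau=tau)
                s = int(seeds[i].generate_state(1)[0] % (2**31))
                i += 1
                track = simulate_dyad_track(world, state, config.dyad_depth, s)
                m = _profile_metrics(track, genes, config)
                nascent_list.append(m)
                rows.append((geno, "nascent", f"chase_{chase:g}min", m))
            metrics_by[(geno, "nascent")] = nascent_list
        comparison = nucleosome.compare_states(metrics_by)
        io.write_table(comparison, out("nucleosome_comparison.tsv"))
        written.append(out("nucleosome_comparison.tsv"))
        metric_rows = [
            {
                "genotype": g,
                "state": st,
                "timepoint": tp,
                "peak_trough_ratio": m.peak_trough_ratio,
                "linker_length": m.linker_length,
                "mean_spacing": m.mean_spacing,
            }
            for g, st, tp, m in rows
        ]
        io.write_table(pd.DataFrame(metric_rows), out("nucleosome_metrics.tsv"))
        written.append(out("nucleosome_metrics.tsv"))
        results["comparison"] = {
            f"{g}/{st}/{metric}": {"mean": mean, "sd": sd}
            for g, st, metric, mean, sd in comparison[
                ["genotype", "state", "metric", "mean", "sd"]
            ].itertuples(index=False)
        }
    else:
        for label, path in sorted(config.dyad_track_paths.items()):
            chrom_sizes = io.read_chrom_sizes(config.chrom_sizes_path)
            track = io.read_dyad_track(path, chrom_sizes)
            m = _profile_metrics(track, genes, config)
            results[label] = {
                "peak_trough_ratio": m.peak_trough_ratio,
                "linker_length": m.linker_length,
            }
    return results


def _profile_metrics(track, genes, config):
    prof = nucleosome.tss_profile(
        track, genes, tuple(config.profile_flank), config.smooth_width
    )
    calls = nucleosome.call_peaks(prof)
    return nucleosome.maturation_metrics(calls, config.footprint)


def _write_truth(world, path: str) -> None:
    truth = world.truth
    rows = []
    for gene in world.genes:
        rows.append(
            {
                "gene_id": gene.id,
                "timing_class": truth.timing_class[gene.id],
                "base_rate": truth.base_rate[gene.id],
                "alpha": truth.alpha[gene.id],
                "far_double_at": truth.far_double_at.get(gene.id, ""),
            }
        )
    io.write_table(pd.DataFrame(rows), path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
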