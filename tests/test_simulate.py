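"""Generator properties: determinism, planted structure, sampling laws."""

import numpy as np
import pytest
from scipy import stats as sps

from cyclenascent import timing
from cyclenascent.simulate import (
    LibraryParams,
    NucleosomeParams,
    PackingError,
    SampleSpec,
    WorldConfig,
    _draw_positions,
    assembly_delay_genotype,
    simulate_dyad_track,
    simulate_netseq_library,
    simulate_world,
    wildtype_genotype,
)
from cyclenascent.types import GeneRecord, GeneSet

from conftest import tiny_world_config


def test_empty_world_is_valid():
    world = simulate_world(tiny_world_config(n_genes=0), seed=0)
    assert len(world.genes) == 0
    assert world.truth.base_rate == {}


def test_same_seed_reproduces_world_and_library(tiny_world):
    cfg = tiny_world_config()
    w1 = simulate_world(cfg, seed=11)
    w2 = simulate_world(cfg, seed=11)
    assert w1.genes == w2.genes and w1.origins == w2.origins
    assert w1.truth.base_rate == w2.truth.base_rate
    spec = SampleSpec(wildtype_genotype(), "G1", 1)
    s1 = simulate_netseq_library(w1, spec, seed=3)
    s2 = simulate_netseq_library(w2, spec, seed=3)
    assert s1.spike_reads == s2.spike_reads
    assert s1.track.allclose(s2.track, rtol=0)


def test_genes_do_not_overlap(default_world):
    by_chrom = {}
    for g in default_world.genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for intervals in by_chrom.values():
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2


def test_planted_timing_class_recovered_exactly(default_world):
    classes = timing.classify_genes(default_world.genes, default_world.origins)
    planted = default_world.truth.timing_class
    for gene_id, cls in classes["timing_class"].items():
        expected = planted[gene_id]
        assert cls == ("unclassified" if expected == "far" else expected)


def test_infeasible_packing_raises():
    cfg = tiny_world_config(
        n_genes=400, chrom_sizes={"chrI": 60_000}, gene_length_min=900
    )
    with pytest.raises(PackingError):
        simulate_world(cfg, seed=0)


def test_poisson_mean_recovered_over_seeds():
    """Mean observed count matches lambda*len within 4 SD over 100 seeds."""
    cfg = tiny_world_config(n_genes=1, rate_log_sd=0.0, alpha_sd=0.0)
    world = simulate_world(cfg, seed=5)
    gene = next(iter(world.genes))
    # pin the expectation to exactly 500 reads
    world.truth.base_rate[gene.id] = 500.0 / gene.length
    params = LibraryParams(efficiency_sd=0.0, spike_noise_sd=0.0)
    spec = SampleSpec(wildtype_genotype(), "G1", 1)
    counts = []
    for seed in range(100):
        s = simulate_netseq_library(world, spec, params, seed=seed)
        sense = s.track.array(gene.chrom, gene.strand)
        counts.append(sense[gene.start : gene.end].sum())
    mean = np.mean(counts)
    se = np.sqrt(500.0 / 100)
    assert abs(mean - 500.0) < 4 * se


def test_dosage_doubles_expected_count(default_world):
    truth = default_world.truth
    wt = wildtype_genotype()
    truth.config.dosage_buffering = False
    try:
        for gene in default_world.genes:
            g1 = truth.expected_sense_count(gene, wt, "G1")
            g2 = truth.expected_sense_count(gene, wt, "S90")
            assert g2 == pytest.approx(2 * g1)
    finally:
        truth.config.dosage_buffering = True


def test_buffering_holds_sphase_flat(default_world):
    truth = default_world.truth
    wt = wildtype_genotype()
    for gene in default_world.genes:
        g1 = truth.expected_sense_count(gene, wt, "G1")
        for tp in ("S30", "S60"):
            assert truth.expected_sense_count(gene, wt, tp) == pytest.approx(g1)
        assert truth.expected_sense_count(gene, wt, "S90") == pytest.approx(2 * g1)


def test_positions_uniform_when_alpha_zero():
    gene = GeneRecord("g", "chrI", 1000, 6000, "+")
    rng = np.random.default_rng(0)
    pos = _draw_positions(gene, 10_000, alpha=0.0, shape_window=300, rng=rng)
    offsets = pos - gene.start
    stat = sps.kstest(offsets / gene.length, "uniform")
    assert stat.pvalue > 0.01


def test_short_gene_collapses_to_uniform_shape():
    gene = GeneRecord("g", "chrI", 100, 350, "+")  # 250 bp < shape window
    rng = np.random.default_rng(1)
    pos = offsets = _draw_positions(gene, 20_000, alpha=0.9, shape_window=300, rng=rng)
    offsets = pos - gene.start
    stat = sps.kstest(offsets / gene.length, "uniform")
    assert stat.pvalue > 0.01


def test_five_prime_enrichment_fraction():
    gene = GeneRecord("g", "chrI", 0, 2000, "-")
    rng = np.random.default_rng(2)
    pos = _draw_positions(gene, 50_000, alpha=0.4, shape_window=300, rng=rng)
    # minus strand: first 300 bp are positions end-1 down to end-300
    in5 = np.sum(pos >= gene.end - 300)
    assert in5 / 50_000 == pytest.approx(0.4, abs=0.01)


def test_total_reads_match_analytic_expectation(default_world):
    params = LibraryParams(depth=8.0, efficiency_sd=0.0, spike_noise_sd=0.0)
    spec = SampleSpec(wildtype_genotype(), "G1", 1)
    sample = simulate_netseq_library(default_world, spec, params, seed=9)
    truth = default_world.truth
    wt = wildtype_genotype()
    expected = sum(
        truth.expected_sense_count(g, wt, "G1", 8.0)
        + truth.expected_antisense_count(g, wt, "G1", 8.0)
        for g in default_world.genes
    )
    assert expected > 1e6
    assert abs(sample.target_reads - expected) / expected < 0.02


def test_dyad_track_exact_positions_without_jitter():
    cfg = tiny_world_config(n_genes=1)
    world = simulate_world(cfg, seed=3)
    gene = next(iter(world.genes))
    params = NucleosomeParams(
        repeat=165, jitter=0.0, occupancy=1.0, background=0.0, include_minus1=False
    )
    track = simulate_dyad_track(world, params, depth=10, seed=4)
    arr = track.array(gene.chrom, "+")
    nonzero = np.flatnonzero(arr)
    direction = 1 if gene.strand == "+" else -1
    planted = {gene.tss + direction * (75 + k * 165) for k in range(8)}
    assert set(nonzero.tolist()) <= planted


def test_dyad_track_seed_determinism(tiny_world):
    t1 = simulate_dyad_track(tiny_world, "nascent", depth=10, seed=8)
    t2 = simulate_dyad_track(tiny_world, "nascent", depth=10, seed=8)
    assert t1.allclose(t2, rtol=0)


def test_too_small_repeat_rejected():
    with pytest.raises(ValueError, match="footprint"):
        NucleosomeParams(repeat=140)


def test_mutant_multipliers_apply_only_after_replication(default_world):
    truth = default_world.truth
    mut = assembly_delay_genotype()
    wt = wildtype_genotype()
    early = [g for g in default_world.genes if truth.timing_class[g.id] == "early"]
    gene = early[0]
    ratio = truth.expected_sense_count(gene, mut, "S30") / truth.expected_sense_count(
        gene, wt, "S30"
    )
    assert ratio == pytest.approx(8.0)
    ratio_s90 = truth.expected_sense_count(gene, mut, "S90") / truth.expected_sense_count(
        gene, wt, "S90"
    )
    assert ratio_s90 == pytest.approx(1.1)
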