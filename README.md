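# cyclenascent

Cell-cycle-resolved analysis of nascent transcription and nucleosome
maturation in yeast, built around spike-in-normalized NET-seq-style 3'-end
signal and MNase dyad-density tracks — with a fully seeded synthetic-data
generator so the entire analysis runs, and validates itself, at desk scale.

## The problem

When a replication fork passes, gene copy number doubles but wild-type
cells *buffer* transcription: nascent output stays flat through S phase and
steps up ~2× only in G2. Histone-chaperone mutants that delay nucleosome
assembly behind the fork instead show a transient burst of promiscuous
transcription — sense and cryptic antisense — at genes near early-firing
origins in early S phase and near late-firing origins in late S phase.
The same acetylation-dependent assembly machinery shapes where RNA Pol II
sits along genes (5' enrichment) and how quickly nucleosome arrays on newly
replicated DNA regain mature phasing and spacing.

`cyclenascent` implements the bespoke computations this kind of study
needs, as a tested, reusable Python library:

- **Spike-in normalization** — per library, `spike_factor = 10^5 / spike
  reads`; per batch, `depth_factor = 10^6 / mean(spike-scaled reference
  read totals)`; every factor logged, never baked invisibly into files.
- **Region quantification & differential calls** — counts are sums of
  normalized per-base 3'-end signal over each region (sense or antisense);
  log₂ fold changes with a Welch test on log counts and Benjamini–Hochberg
  FDR, flagged at ≥1.5 fold, FDR ≤ 0.05.
- **RNA Pol II distribution** — per-gene 5'/3' ratio
  `Σ signal[TSS, TSS+300) / Σ signal[TTS−300, TTS)` compared between
  strains by a tie-aware exact Mann–Whitney U test; expression-normalized
  metagene (TSS−100…TTS+200 fitted into 500 bins, each gene divided by its
  mean per-bp body signal); length-ordered log₂ fold-change heatmap over
  TSS…TSS+4 kb.
- **Replication timing** — genes classed early/late by TSS distance ≤ 4 kb
  to origins of one timing (ambiguous if both), then per-class time-course
  summaries over G1/S30/S60/S90: medians, quartiles, mutant/WT fold ratios
  with Mann–Whitney p, and the within-genotype G2/G1 dosage step.
- **Nucleosome maturation** — TSS-aligned average dyad profiles, peak
  calling downstream of the NDR, mean peak/trough ratio over nucleosomes
  +2…+7, and linker length = mean peak spacing over pairs (+1,+2), (+2,+3),
  (+3,+4) minus the 147 bp footprint.
- **Synthetic worlds** — seeded generators for origin-structured genomes,
  Poisson 3'-end libraries with spike-ins, dosage schedules with buffering,
  genotype effect multipliers, and phased dyad arrays with tunable repeat,
  jitter and occupancy; every planted parameter is recorded so estimators
  are validated by recovery, not by eyeballing.

## Worked example

```python
from cyclenascent import quantify, timing
from cyclenascent.normalize import normalize_batch
from cyclenascent.simulate import (
    assembly_delay_genotype, simulate_timecourse, simulate_world,
    wildtype_genotype,
)

world = simulate_world(seed=1)                       # 300 genes, 40 origins
samples = simulate_timecourse(
    world, [wildtype_genotype(), assembly_delay_genotype()], seed=2
)                                                    # 16 libraries
normalize_batch(samples)
counts = quantify.build_counts_table(samples, world.genes)
classes = timing.classify_genes(world.genes, world.origins)

tc = timing.timecourse_summary(counts, classes)
print(tc.contrasts[tc.contrasts.contrast == "asf1_delay_vs_WT"]
      [["timing_class", "timepoint", "fold_ratio", "p"]])
```

prints (among other rows):

```
timing_class timepoint  fold_ratio             p
       early       S30    8.020721  6.539736e-33
       early       S90    1.090963  2.069451e-01
        late       S60   10.483362  7.990704e-34
```

i.e. the assembly-delay mutant bursts ~8-fold at early-replicating genes in
early S phase and ~10.5-fold at late-replicating genes in late S phase, and
is back near wild-type levels by G2 — while

```python
timing.buffering_step(counts[counts.genotype == "WT"], classes)["all"]
# 2.06
```

shows the wild type holding expression flat through S phase and releasing a
~2× dosage step in G2.

The `examples/` directory holds one short narrative script per capability
(normalization, differential calls, Pol II profiles, replication timing,
nucleosome maturation, full pipeline); each prints the numbers it computes
and what they mean.

A thin CLI wraps the same functions for shell use:

```bash
cyclenascent run --seed 12 --out-dir run_out        # full pipeline
cyclenascent simulate|normalize|quantify|diff|profile|timing|nucleosome --help
```

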