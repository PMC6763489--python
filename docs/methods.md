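# Methods

## Signal model and conventions

All coordinates are 0-based half-open (BED-native); the TSS of a minus-strand
gene is `end − 1`. A signal track is a dense per-base, per-strand array per
chromosome. For NET-seq-style data each unit of signal is one recorded 3' end
of a nascent transcript, i.e. one RNA Pol II position; dyad tracks are
unstranded per-base densities of nucleosome centers. Tracks carry an ordered
normalization log so the raw → normalized mapping is always reproducible from
the object (and from the sidecar factor table on disk).

## Spike-in normalization

Two multiplicative stages:

1. `spike_factor = 100,000 / spike_reads` per library, where `spike_reads`
   is the number of reads uniquely attributable to the spike-in genome.
   Only this scalar enters the computation, so the spike-in is represented
   as a count, not a track.
2. `depth_factor = 1,000,000 / mean_r(spike_factor_r × target_reads_r)`
   over the reference-genotype libraries *r* of a batch, applied uniformly
   to every library in the batch. When the reference has several
   replicates their mean scaled total is used — a symmetric, deterministic
   choice. Batch membership is an explicit input: nothing in the data says
   which libraries shared a sequencing run, so the caller decides.

Normalization is idempotence-guarded (a second application raises) and exact:
within-sample ratios are preserved to floating-point round-off, and two
identical tracks end up scaled inversely to their spike counts.

## Differential calls

Counts are sums of normalized signal over each region, sense or antisense
(the opposite strand over the same body — used for cryptic antisense
transcription). Overlapping regions each receive the shared signal in full;
bookended regions split exactly at the half-open boundary.

`log2FC = log2((mean_B + pc) / (mean_A + pc))` with pseudocount `pc = 1`
normalized read by default (the handling of zero-count regions is not
determined by the data, so it is a parameter). The p-value is a two-sided
Welch t-test on `log2(count + pc)` across replicates when both conditions
have ≥ 2, else 1 (flagging then rests on the fold change alone); q-values
are Benjamini–Hochberg. This test is a deliberately simple, clearly named
substitute for dispersion-modeling negative-binomial tests: it preserves the
thresholds and flagging semantics (≥ 1.5 fold, FDR ≤ 0.05) but has low power
at 2 replicates (df ≈ 2); full recovery of planted effects in the test suite
uses 4 replicates at deep coverage. Degenerate zero-variance inputs map to
p = 1 when means agree and p = 0 otherwise.

## RNA Pol II distribution statistics

**5'/3' ratio.** `Σ signal[TSS, TSS+w) / Σ signal[TTS−w, TTS)`,
strand-reflected, with `w = 300` bp by default. The source material states
the window inconsistently (300 bp in one place, 1–250 bp in another); the
window is therefore a parameter, defaulting to the value that matches the
plotted comparison. Genes shorter than `2w` are excluded from strain vectors
(and counted); a zero 3' window marks the gene undefined rather than raising.
The ratio is invariant under positive rescaling of the track, so it needs no
cross-sample normalization.

**Strain comparison.** Mann–Whitney U, two-sided. When the smaller group has
≤ 8 observations and the labeling count is manageable the p-value is computed
by exhaustive enumeration over group labelings using midranks — exact under
ties, which the textbook Wilcoxon null distribution is not. Tie-free inputs
with a small group use the exact Wilcoxon distribution; everything else the
tie-corrected normal approximation (both via scipy).

**Metagene.** Genes with body > 500 bp; the window TSS−100 … TTS+200 is
fitted as a whole into 500 bins (flanks scale with the gene, per the literal
reading of the plotted layout; fixed-resolution flanks would be a different,
also defensible choice). Rebinning splits bases fractionally across bin
edges, conserving total signal. Each gene's binned vector is divided by its
mean per-bp body signal — "individual expression level" is interpreted as
mean per-bp over the body (total count would differ only by a length factor
that the binning already removes). Genes with zero body signal or flanks
crossing a chromosome edge are excluded and counted. The 95% CI is
mean ± 1.96·SE across genes — deterministic; a bootstrap would add noise
without changing the picture at these gene counts.

**Heatmap.** Per gene, binned (25 bp) log₂((mut+pc)/(WT+pc)) over
TSS…TSS+4 kb, rows sorted by gene length, bins whose start offset passes the
TTS masked as NaN (off-chromosome padding necessarily lies past the TTS).

## Replication-timing classification and time course

Distance is measured from the gene's TSS (configurable: midpoint, or
any-overlap of the body) to origin positions. Within 4 kb of one timing only
→ that class; of both → ambiguous, excluded from both classes and reported
separately; of neither → unclassified. Replicates are averaged per gene
before medians are taken, so summaries describe gene-level distributions.
Contrasts report the fold ratio of class medians (mutant/WT per timepoint;
S90/G1 within genotype) with Mann–Whitney p over the per-gene values. The
buffering step is `median_genes(count_S90) / median_genes(count_G1)`.

## Nucleosome maturation metrics

The TSS-aligned profile averages strand-oriented dyad density over offsets
−200…+1400 across genes (off-chromosome windows skipped and counted), then
smooths with a centered moving average, width 31 bp, reflected boundaries —
symmetric, so peak positions of symmetric peaks are preserved. Peak calling:
the NDR minimum is the global minimum in offsets −150…+50; peaks are local
maxima downstream of it, at least 120 bp apart (nucleosomes cannot sit
closer) and with prominence ≥ 2% of the profile's dynamic range (rejects
noise wiggles on the NDR slope); the first is +1, the first seven are
retained, troughs are the minima between consecutive peaks (the NDR minimum
upstream of +1; downstream of the last peak, the minimum within one median
spacing). Fewer than 4 peaks is a `NoPeaks` error.

Peak/trough ratio: mean over nucleosomes +2…+7 of peak height over the mean
of its two flanking troughs (which trough to use is not determined by the
source; the symmetric mean is the package's choice). Linker length: mean
over pairs (+1,+2), (+2,+3), (+3,+4) of peak spacing minus 147 bp — the
canonical footprint; the constant is configurable since the subtraction
convention is ours. Negative linkers are flagged, not silently dropped.
State comparisons report mean ± sample SD (ddof = 1) across chase
timepoints per (genotype, state).

On fuzzy profiles (jitter ≈ 35 bp) individual pair spacings carry ±2–5 bp of
estimator noise at the default smoothing; recovery tests and the acceptance
script therefore average the linker over ~10 replicate tracks, mirroring how
a pulse-chase experiment averages timepoints and biological replicates.

## Synthetic-data generator

The generator emulates the study design, not sequencing chemistry: no reads,
no alignment errors, no fork-progression model beyond the dosage schedule.

**World.** Two 400 kb chromosomes, 20 early + 20 late origins placed in
evenly spaced slots (guaranteeing ≥ 2×4 kb + max gene length separation so
planted classes are unambiguous), 300 non-overlapping genes — one third with
TSS within 4 kb of an early origin (and > 4.2 kb from every late one), one
third near late origins, one third far from all. A 200 bp guard band keeps
planted TSSs away from the 4 kb boundary so distance classification recovers
the planted labels exactly. Gene lengths are log-normal (median 1 kb, capped
at 2.5 kb): the origin windows can hold ~5 genes each, so desk-scale packing
forces slightly shorter genes and more origins than a real chromosome would
have; this changes no estimator, only the packing feasibility.

**Libraries.** Per gene, sense counts are Poisson around
λ_g · len_g · d_{g,t} · b_{g,t} · m_{g,geno,t} · depth · e, where λ_g is the
planted per-bp rate (log-normal, median 0.5 reads/bp), d the dosage (1 → 2
when the gene's class replicates: early at S30, late at S60, far at a
configurable S60/S90 split; everything doubled by S90), b the buffering
factor (1/d until S90, released in G2 — so wild-type expression is flat
through S phase and steps ~2× in G2), and m the genotype multiplier.
Positions follow a two-segment shape: fraction α (planted ≈ 0.45) uniform
over the first 300 bp, the rest uniform over the remainder; genes not longer
than the window collapse to uniform. Antisense reads are drawn at a planted
fraction (default 0.05) of the sense rate, uniform over the body on the
opposite strand. The library efficiency e (log-normal, σ = 0.3) multiplies
both the target counts and the spike-in median — that coupling is precisely
what makes spike-in normalization informative — plus a small residual
spike-count noise (σ = 0.02, since real spike counts of ~10⁵ carry sub-percent
counting error and the cell-mixing ratio is controlled). Spike reads are a
rounded log-normal around 100,000.

**Genotype presets.** The assembly-delay preset mirrors the measured effect
sizes: 8× at early genes in S30 and 10.5× at late genes in S60, decaying
(1.5×, 1.1–1.5×) at later timepoints; the same schedule for antisense; a
global 0.6× decrease in arrested G1 cells; and a flattened 5' shape
(α = 0.29, which halves the median 5'/3' ratio). A stronger preset (25×/13×)
matches the chaperone double-mutant scale. The transient multiplier — applied
only in the window where the locus has just replicated — encodes the
mechanistic claim (delayed assembly → promiscuous transcription) as testable
structure. The antisense/cryptic rate has no measured distribution to copy,
so it stays a free parameter.

**Dyad arrays.** Per gene: a −1 dyad, then +1…+8 at
TSS + 75 + k·repeat with Gaussian jitter, thinned to the occupancy fraction;
a uniform background (density = depth/repeat per bp over TSS−400…+1800)
emulates unpositioned nucleosomes so peak/trough ratios are finite and
realistic. Mature state: repeat 160 bp (linker 13), jitter 20 bp, full
occupancy. Nascent state: repeat 167 bp (linker 20), jitter 35 bp, occupancy
0.6. A chase-time helper relaxes nascent parameters exponentially toward
mature with timescale τ (default 4 min; slow-assembly genotypes 15 min).

**What passing tests show — and don't.** Recovery of planted fold effects,
dosage steps, repeat lengths and shape differences demonstrates that the
estimators are correct and unbiased under the generative model: Poisson
counts, class-homogeneous effects, clean annotations, no mappability or
copy-number artifacts, no cell-cycle heterogeneity within a timepoint. Real
libraries violate all of these to some degree; the tests validate the
arithmetic and the statistical machinery, not robustness to biology the
generator does not model.

## Problem sizes and determinism

Default analyses run on the 300-gene world with 16 libraries (~250 k reads
each) and ~10⁵-read dyad tracks; recovery tests use 20 seeds for fold
effects, 50 for repeat lengths, 10 replicate tracks per chromatin state for
linkers — sizes chosen so the full suite and the acceptance script each
finish in well under a coffee break on one CPU while keeping estimator noise
far inside the asserted tolerances. Every stochastic step draws from a
`numpy` generator seeded from a single run seed via `SeedSequence.spawn`;
pipeline reruns with identical config and seed are byte-identical, which the
run report's checksums make checkable.

## Known limitations

- The Welch-on-log-counts substitute is underpowered at the study's own
  2-replicate design; it is a thresholding harness, not a reimplementation
  of negative-binomial differential testing.
- The exact Mann–Whitney enumeration caps at ~4·10⁵ labelings; beyond that,
  tie-free inputs fall back to the exact Wilcoxon distribution and tied ones
  to the tie-corrected normal approximation.
- Linker estimates on fuzzy (nascent-like) profiles need replicate averaging
  for ±2 bp accuracy; single profiles carry a few bp of peak-position noise.
- Real-input mode expects bedGraph pairs and BED/GFF3 annotations; BAM
  alignment, read trimming and multi-mapping policy are upstream concerns
  and out of scope.
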