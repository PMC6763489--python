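"""RNA Pol II distribution statistics: 5'/3' ratio and metagene.

The wild type concentrates ~45% of a gene's nascent 3'-end signal in the
first 300 bp; the assembly mutant has a flatter shape. The 5'/3' ratio
(TSS window over TTS window) drops roughly twofold and the Mann-Whitney
comparison across genes is decisive.
"""

import numpy as np

from cyclenascent import polii
from cyclenascent.normalize import normalize_batch
from cyclenascent.pipeline import _merged_track
from cyclenascent.simulate import (
    SampleSpec,
    assembly_delay_genotype,
    simulate_netseq_library,
    simulate_world,
    wildtype_genotype,
)

world = simulate_world(seed=1)
tracks = {}
samples = []
for gi, geno in enumerate((wildtype_genotype(), assembly_delay_genotype())):
    reps = [
        simulate_netseq_library(world, SampleSpec(geno, "G1", r), seed=100 * gi + r)
        for r in (1, 2)
    ]
    samples += reps
    tracks[geno.name] = reps
normalize_batch(samples)
merged = {name: _merged_track(reps) for name, reps in tracks.items()}

rsets = {name: polii.ratio_set(track, world.genes) for name, track in merged.items()}
for name, rset in rsets.items():
    print(f"{name}: median 5'/3' ratio {np.median(rset.ratios):.2f} "
          f"over {len(rset.ratios)} genes")
u, p = polii.ratio_compare(rsets["asf1_delay"].ratios, rsets["WT"].ratios)
print(f"Mann-Whitney U={u:.0f}, two-sided p={p:.2e} (mutant shifted low)")

prof = polii.metagene(merged["WT"], world.genes)
peak_bin = int(prof.table["mean"].idxmax())
print(f"\nWT metagene: {prof.n_genes} genes in 500 bins; "
      f"highest mean density at bin {peak_bin} "
      "(5' end, reflecting promoter-proximal polymerase)")
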