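import numpy as np
import pytest

from cyclenascent.simulate import WorldConfig, simulate_world
from cyclenascent.types import GeneRecord, GeneSet, SignalTrack


def tiny_world_config(**overrides) -> WorldConfig:
    """A fast-to-generate world: one 120 kb chromosome, 30 genes."""
    defaults = dict(
        n_genes=30,
        chrom_sizes={"chrI": 120_000},
        n_origins_early=3,
        n_origins_late=3,
        gene_length_median=900.0,
        gene_length_max=1500,
    )
    defaults.update(overrides)
    return WorldConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_world():
    return simulate_world(tiny_world_config(), seed=11)


@pytest.fixture(scope="session")
def default_world():
    return simulate_world(seed=1)


def random_genes(rng: np.random.Generator, n: int, chrom_len: int, chrom="chrI") -> GeneSet:
    """Non-overlapping random genes for oracle comparisons."""
    genes = GeneSet()
    cursor = int(rng.integers(0, 200))
    i = 0
    while i < n and cursor < chrom_len - 2500:
        length = int(rng.integers(400, 2000))
        start = cursor + int(rng.integers(20, 400))
        if start + length > chrom_len:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.add(GeneRecord(f"r{i}", chrom, start, start + length, strand))
        cursor = start + length
        i += 1
    return genes


def random_track(rng: np.random.Generator, chrom_sizes, stranded=True, density=0.05) -> SignalTrack:
    """Sparse random non-negative track."""
    track = SignalTrack.zeros(chrom_sizes, stranded=stranded)
    for arrays in filter(None, (track.plus, track.minus)):
        for chrom, arr in arrays.items():
            n = max(1, int(len(arr) * density))
            pos = rng.integers(0, len(arr), size=n)
            vals = rng.exponential(2.0, size=n)
            np.add.at(arr, pos, vals)
    return track
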