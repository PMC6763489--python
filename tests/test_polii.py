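"""5'/3' ratios, Mann-Whitney comparison, metagene and heatmap."""

import itertools

import numpy as np
import pytest

from cyclenascent import polii
from cyclenascent.stats import mann_whitney_u, _u_statistic
from cyclenascent.types import GeneRecord, GeneSet, SignalTrack

from conftest import random_genes, random_track


def track_with(values, chrom_len=5000, strand="+"):
    track = SignalTrack.zeros({"chrI": chrom_len}, stranded=True)
    arrays = track.plus if strand == "+" else track.minus
    arrays["chrI"][: len(values)] = values
    return track


# ---------------------------------------------------------------- 5'/3' ratio

def test_uniform_signal_gives_ratio_one():
    track = SignalTrack.zeros({"chrI": 5000}, stranded=True)
    track.plus["chrI"][:] = 0.7
    gene = GeneRecord("g", "chrI", 1000, 3000, "+")
    assert polii.five_three_ratio(track, gene) == pytest.approx(1.0)


def test_signal_only_in_three_prime_window():
    track = SignalTrack.zeros({"chrI": 5000}, stranded=True)
    gene = GeneRecord("g", "chrI", 1000, 3000, "+")
    track.plus["chrI"][2700:3000] = 1.0
    assert polii.five_three_ratio(track, gene) == 0.0


def test_zero_denominator_is_undefined_not_error():
    track = SignalTrack.zeros({"chrI": 5000}, stranded=True)
    gene = GeneRecord("g", "chrI", 1000, 3000, "+")
    track.plus["chrI"][1000:1300] = 1.0
    assert polii.five_three_ratio(track, gene) is None


def test_ratio_matches_brute_force_on_random_gene():
    rng = np.random.default_rng(12)
    track = random_track(rng, {"chrI": 5000})
    for strand in "+-":
        gene = GeneRecord("g", "chrI", 1500, 3500, strand)
        arr = track.array("chrI", strand)
        if strand == "+":
            r5 = sum(arr[1500:1800])
            r3 = sum(arr[3200:3500])
        else:
            r5 = sum(arr[3200:3500])
            r3 = sum(arr[1500:1800])
        expected = r5 / r3
        assert polii.five_three_ratio(track, gene) == pytest.approx(expected)


def test_ratio_invariant_under_positive_scaling():
    rng = np.random.default_rng(5)
    track = random_track(rng, {"chrI": 5000})
    gene = GeneRecord("g", "chrI", 1000, 3000, "+")
    before = polii.five_three_ratio(track, gene)
    track.scale(37.5, "arbitrary")
    assert polii.five_three_ratio(track, gene) == pytest.approx(before, rel=1e-12)


def test_ratio_set_excludes_short_genes():
    track = SignalTrack.zeros({"chrI": 5000}, stranded=True)
    track.plus["chrI"][:] = 1.0
    genes = GeneSet(
        [
            GeneRecord("long", "chrI", 100, 800, "+"),
            GeneRecord("short", "chrI", 1000, 1500, "+"),  # < 600 bp
        ]
    )
    rset = polii.ratio_set(track, genes, window=300)
    assert list(rset.table["gene_id"]) == ["long"]
    assert rset.n_short_excluded == 1


# --------------------------------------------------------------- Mann-Whitney

def test_mw_separated_samples_exact():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings as extreme


def test_mw_identical_multisets_p_one():
    _, p = mann_whitney_u([1.0, 2.0, 2.0], [1.0, 2.0, 2.0])
    assert p == 1.0


def brute_force_permutation_p(a, b):
    pooled = np.concatenate([a, b])
    n_a = len(a)
    mu = n_a * len(b) / 2
    u_obs = _u_statistic(np.asarray(a, float), np.asarray(b, float))
    extreme = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            extreme += 1
    return extreme / total


def test_asymptotic_close_to_permutation_oracle():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(8)
    for _ in range(5):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 7)
        p_perm = brute_force_permutation_p(a, b)
        p_approx = float(
            mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        assert abs(p_approx - p_perm) < 0.02


def test_mw_rejects_empty():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ------------------------------------------------------------------- metagene

def flat_world():
    genes = GeneSet(
        [
            GeneRecord("a", "chrI", 1000, 2200, "+"),
            GeneRecord("b", "chrI", 3000, 4500, "-"),
        ]
    )
    track = SignalTrack.zeros({"chrI": 10_000}, stranded=True)
    track.plus["chrI"][:] = 1.0
    track.minus["chrI"][:] = 1.0
    return track, genes


def test_metagene_flat_for_uniform_signal():
    track, genes = flat_world()
    prof = polii.metagene(track, genes)
    np.testing.assert_allclose(prof.table["mean"], 1.0, rtol=1e-9)
    assert prof.n_genes == 2


def test_metagene_expression_normalization_removes_level():
    track, genes = flat_world()
    # gene b at 10x the level of gene a: profile must equal the 1-gene one
    track.minus["chrI"][:] = 10.0
    prof2 = polii.metagene(track, genes)
    prof1 = polii.metagene(track, genes.subset(["a"]))
    np.testing.assert_allclose(prof2.table["mean"], prof1.table["mean"], rtol=1e-9)


def test_metagene_invariant_under_random_per_gene_rescaling():
    rng = np.random.default_rng(9)
    sizes = {"chrI": 30_000}
    track = random_track(rng, sizes, density=0.5)
    # genes spaced so the rescaled windows (body + flanks) cannot overlap
    genes = GeneSet(
        [
            GeneRecord(
                f"g{i}",
                "chrI",
                start := 1000 + 3000 * i,
                start + int(rng.integers(600, 1800)),
                "+" if rng.random() < 0.5 else "-",
            )
            for i in range(8)
        ]
    )
    before = polii.metagene(track, genes).table["mean"].to_numpy()
    scaled = track.copy()
    for g in genes:  # rescale each gene's neighborhood incl. flanks
        mult = float(rng.uniform(0.2, 8.0))
        for arrays in (scaled.plus, scaled.minus):
            arrays["chrI"][g.start - 200 : g.end + 200] *= mult
    after = polii.metagene(scaled, genes).table["mean"].to_numpy()
    np.testing.assert_allclose(after, before, rtol=1e-9)


def test_rebin_matches_brute_force_fractional_assignment():
    rng = np.random.default_rng(4)
    x = rng.exponential(1.0, 137)
    n_bins = 10
    got = polii.rebin(x, n_bins)
    # brute force: distribute each base's value over the bins it overlaps
    width = len(x) / n_bins
    brute = np.zeros(n_bins)
    for j, v in enumerate(x):
        lo, hi = j, j + 1
        for i in range(n_bins):
            blo, bhi = i * width, (i + 1) * width
            overlap = max(0.0, min(hi, bhi) - max(lo, blo))
            brute[i] += v * overlap
    brute /= width
    np.testing.assert_allclose(got, brute, rtol=1e-9)


def test_metagene_excludes_edge_and_zero_genes():
    track = SignalTrack.zeros({"chrI": 3000}, stranded=True)
    track.plus["chrI"][:] = 1.0
    genes = GeneSet(
        [
            GeneRecord("edge", "chrI", 50, 700, "+"),  # TSS-100 < 0
            GeneRecord("zero", "chrI", 1000, 1700, "-"),  # minus strand empty
            GeneRecord("ok", "chrI", 2000, 2700, "+"),
        ]
    )
    prof = polii.metagene(track, genes)
    assert (prof.n_genes, prof.n_excluded_edge, prof.n_excluded_zero) == (1, 1, 1)


# -------------------------------------------------------------------- heatmap

def two_gene_world():
    genes = GeneSet(
        [
            GeneRecord("lng", "chrI", 1000, 3500, "+"),
            GeneRecord("sht", "chrI", 5000, 6000, "-"),
        ]
    )
    track = SignalTrack.zeros({"chrI": 10_000}, stranded=True)
    track.plus["chrI"][:] = 2.0
    track.minus["chrI"][:] = 2.0
    return track, genes


def test_heatmap_identical_tracks_zero():
    track, genes = two_gene_world()
    hm = polii.heatmap_matrix(track, track, genes)
    assert np.all(np.nan_to_num(hm.matrix) == 0.0)


def test_heatmap_doubling_gives_one():
    track, genes = two_gene_world()
    doubled = track.copy()
    doubled.scale(2.0, "x2")
    hm = polii.heatmap_matrix(track, doubled, genes, pseudocount=1e-9)
    unmasked = hm.matrix[~np.isnan(hm.matrix)]
    np.testing.assert_allclose(unmasked, 1.0, atol=1e-6)


def test_heatmap_ordering_and_masking():
    track, genes = two_gene_world()
    hm = polii.heatmap_matrix(track, track, genes, span=4000, bin_size=25)
    assert hm.gene_ids == ["sht", "lng"]  # ascending length
    # short gene (1000 bp) masked from bin 40 onward; long from bin 100
    assert np.all(np.isnan(hm.matrix[0, 40:]))
    assert not np.any(np.isnan(hm.matrix[0, :40]))
    assert np.all(np.isnan(hm.matrix[1, 100:]))
    assert not np.any(np.isnan(hm.matrix[1, :100]))
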