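"""TSS-aligned dyad profiles, peak calling and maturation metrics."""

import numpy as np
import pytest

from cyclenascent import nucleosome
from cyclenascent.nucleosome import (
    MaturationMetrics,
    NoPeaks,
    NucleosomeProfile,
    PeakCalls,
    call_peaks,
    compare_states,
    maturation_metrics,
    moving_average,
    tss_profile,
)
from cyclenascent.simulate import NucleosomeParams, simulate_dyad_track, simulate_world
from cyclenascent.types import GeneRecord, GeneSet, SignalTrack

from conftest import tiny_world_config


def profile_from(density, smooth_width=1, lo=-200, hi=1400):
    density = np.asarray(density, dtype=float)
    return NucleosomeProfile(
        offsets=np.arange(lo, hi + 1),
        density=density,
        smoothed=moving_average(density, smooth_width),
        smooth_width=smooth_width,
        n_genes=1,
        n_skipped=0,
    )


def cosine_profile(baseline=1.0, amplitude=0.5, period=165.0, phase=50.0):
    x = np.arange(-200, 1401)
    return profile_from(baseline + amplitude * np.cos(2 * np.pi * (x - phase) / period))


# ------------------------------------------------------------------- profiles

def test_profile_equals_shared_pattern():
    pattern = np.zeros(1601)
    pattern[np.arange(275, 1500, 165)] = 5.0  # offsets +75, +240, ...
    track = SignalTrack.zeros({"chrI": 20_000}, stranded=False)
    genes = GeneSet(
        [GeneRecord("a", "chrI", 2000, 3000, "+"), GeneRecord("b", "chrI", 9000, 10_000, "+")]
    )
    for g in genes:
        track.plus["chrI"][g.tss - 200 : g.tss + 1401] += pattern
    prof = tss_profile(track, genes, smooth_width=1)
    np.testing.assert_allclose(prof.density, pattern)


def test_minus_strand_gene_mirrors_plus():
    track = SignalTrack.zeros({"chrI": 20_000}, stranded=False)
    pattern = np.zeros(1601)
    pattern[400] = 3.0  # offset +200 downstream of TSS
    plus = GeneRecord("p", "chrI", 5000, 6000, "+")
    minus = GeneRecord("m", "chrI", 11_000, 12_000, "-")
    track.plus["chrI"][plus.tss + 200] = 3.0
    track.plus["chrI"][minus.tss - 200] = 3.0  # oriented +200 for minus gene
    for genes in (GeneSet([plus]), GeneSet([minus])):
        prof = tss_profile(track, genes, smooth_width=1)
        np.testing.assert_allclose(prof.density, pattern)


def test_profile_matches_brute_force_extraction(tiny_world):
    track = simulate_dyad_track(tiny_world, "mature", depth=5, seed=2)
    prof = tss_profile(track, tiny_world.genes, smooth_width=1)
    arr = track.plus["chrI"]
    rows = []
    for g in tiny_world.genes:
        vals = []
        for off in range(-200, 1401):
            pos = g.tss + off if g.strand == "+" else g.tss - off
            vals.append(arr[pos] if 0 <= pos < len(arr) else np.nan)
        if not np.isnan(vals).any():
            rows.append(vals)
    brute = np.mean(rows, axis=0)
    assert prof.n_genes == len(rows)
    np.testing.assert_allclose(prof.density, brute, rtol=1e-12)


def test_profile_scales_linearly_with_track():
    cfg = tiny_world_config()
    world = simulate_world(cfg, seed=11)
    track = simulate_dyad_track(world, "mature", depth=5, seed=3)
    prof1 = tss_profile(track, world.genes)
    scaled = track.copy()
    scaled.scale(4.0, "x4")
    prof2 = tss_profile(scaled, world.genes)
    np.testing.assert_allclose(prof2.density, 4.0 * prof1.density, rtol=1e-12)


# --------------------------------------------------------------- peak calling

def test_cosine_peaks_at_closed_form_positions():
    calls = call_peaks(cosine_profile())
    expected = np.array([50, 215, 380, 545, 710, 875, 1040])
    assert len(calls.positions) == 7
    np.testing.assert_allclose(calls.positions, expected, atol=1)
    # troughs interleave peaks
    for k in range(calls.n_peaks):
        assert calls.trough_positions[k] < calls.positions[k] < calls.trough_positions[k + 1]


def test_flat_profile_raises_nopeaks():
    with pytest.raises(NoPeaks):
        call_peaks(profile_from(np.ones(1601)))


def test_peak_positions_invariant_under_affine_transform():
    base = cosine_profile()
    transformed = profile_from(3.7 * base.density + 11.0)
    np.testing.assert_array_equal(
        call_peaks(base).positions, call_peaks(transformed).positions
    )


def test_peak_trough_ratio_closed_form_and_background_monotonicity():
    # cosine with baseline b and amplitude a: ratio = (b + a) / (b - a)
    for b, a in ((2.0, 0.5), (3.0, 1.0)):
        calls = call_peaks(cosine_profile(baseline=b, amplitude=a))
        m = maturation_metrics(calls)
        assert m.peak_trough_ratio == pytest.approx((b + a) / (b - a), rel=1e-3)
    ratios = [
        maturation_metrics(call_peaks(cosine_profile(baseline=b))).peak_trough_ratio
        for b in (1.0, 2.0, 4.0)
    ]
    assert ratios[0] > ratios[1] > ratios[2]


def test_linker_unbiased_on_noise_free_arrays():
    cfg = tiny_world_config(n_genes=10)
    world = simulate_world(cfg, seed=13)
    for repeat in (155, 160, 165, 170, 180):
        params = NucleosomeParams(
            repeat=repeat, jitter=0.0, occupancy=1.0, background=0.0
        )
        track = simulate_dyad_track(world, params, depth=20, seed=1)
        calls = call_peaks(tss_profile(track, world.genes))
        m = maturation_metrics(calls)
        assert abs(m.linker_length - (repeat - 147)) <= 1


def test_planted_spacing_recovered_within_two_bp(default_world):
    """Peak spacing of a jittered r=165 array recovered to +-2 bp in >=95%
    of 50 seeds at >=1e5 dyad reads."""
    params = NucleosomeParams(repeat=165, jitter=20, occupancy=1.0)
    hits = 0
    for seed in range(50):
        track = simulate_dyad_track(default_world, params, depth=40, seed=seed)
        assert track.total() >= 1e5
        m = maturation_metrics(call_peaks(tss_profile(track, default_world.genes)))
        if abs(m.mean_spacing - 165) <= 2:
            hits += 1
    assert hits >= 48  # 95% of 50 rounded up


def test_nascent_vs_mature_linker_ordering(default_world):
    """Linker difference between nascent (planted 20 bp) and mature (13 bp)
    chromatin, each averaged over replicate tracks as in a pulse-chase
    series, recovers the planted 7 bp expansion within +-2 bp."""

    def mean_linker(state, seeds):
        vals = []
        for seed in seeds:
            track = simulate_dyad_track(default_world, state, depth=40, seed=seed)
            m = maturation_metrics(call_peaks(tss_profile(track, default_world.genes)))
            vals.append(m.linker_length)
        return np.mean(vals)

    linker_mat = mean_linker("mature", range(10))
    linker_nas = mean_linker("nascent", range(100, 110))
    assert linker_nas > linker_mat
    assert abs((linker_nas - linker_mat) - 7) <= 2  # planted repeats 167 vs 160


# -------------------------------------------------------------------- metrics

def hand_calls(positions, heights, trough_heights):
    positions = np.asarray(positions, float)
    troughs = (positions[:-1] + positions[1:]) / 2
    trough_pos = np.concatenate([[positions[0] - 80], troughs, [positions[-1] + 80]])
    return PeakCalls(
        positions=positions,
        heights=np.asarray(heights, float),
        trough_positions=trough_pos[: len(positions) + 1],
        trough_heights=np.asarray(trough_heights, float),
    )


def test_metrics_hand_arithmetic():
    calls = hand_calls(
        positions=[50, 215, 380, 545, 710, 875, 1040],
        heights=[4.0] * 7,
        trough_heights=[2.0] * 8,
    )
    m = maturation_metrics(calls)
    assert m.peak_trough_ratio == pytest.approx(2.0)
    assert m.linker_length == pytest.approx(165 - 147)
    assert m.per_pair_linkers == {"+1/+2": 18.0, "+2/+3": 18.0, "+3/+4": 18.0}


def test_metrics_require_four_peaks():
    calls = hand_calls([50, 215, 380], [4.0] * 3, [2.0] * 4)
    with pytest.raises(NoPeaks):
        maturation_metrics(calls)


def test_compare_states_sd():
    def metrics(ratio):
        return MaturationMetrics(
            peak_trough_ratio=ratio,
            linker_length=18.0,
            per_peak_ratios={},
            per_pair_linkers={},
            mean_spacing=165.0,
        )

    table = compare_states(
        {
            ("WT", "nascent"): [metrics(2.0), metrics(3.0)],
            ("WT", "mature"): [metrics(4.0), metrics(4.0)],
        }
    )
    row = table[(table["state"] == "nascent") & (table["metric"] == "peak_trough_ratio")]
    assert row["mean"].iloc[0] == pytest.approx(2.5)
    assert row["sd"].iloc[0] == pytest.approx(np.sqrt(0.5), rel=1e-6)
    mature = table[(table["state"] == "mature") & (table["metric"] == "peak_trough_ratio")]
    assert mature["sd"].iloc[0] == 0.0
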