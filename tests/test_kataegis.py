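"""Inter-mutation distances, exact PCF segmentation, kataegis calling."""

import itertools

import numpy as np
import pytest

from somacat.catalogue import MutationRecord
from somacat.kataegis import (
    call_kataegis,
    intermutation_distances,
    pcf_objective,
    pcf_segment,
)


def snvs(positions, chrom="chr1", sample="s1"):
    return [MutationRecord(sample, chrom, int(p), "C", "A", "ACA") for p in positions]


def brute_force_pcf(values, gamma, kmin):
    """Enumerate all 2^(n-1) segmentations; return the minimal objective."""
    y = np.asarray(values, dtype=float)
    n = len(y)
    best = np.inf
    best_seg = None
    for mask in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, b in enumerate(mask) if b] + [n]
        segs = [(a, b - 1) for a, b in zip(bounds, bounds[1:])]
        if any(b - a + 1 < kmin for a, b in segs):
            continue
        cost = gamma * len(segs)
        for a, b in segs:
            seg = y[a : b + 1]
            cost += float(((seg - seg.mean()) ** 2).sum())
        if cost < best:
            best = cost
            best_seg = segs
    return best, best_seg


def brute_force_kataegis_windows(positions, min_mut=6, max_mean=1000.0):
    """All maximal windows of >= min_mut consecutive mutations with mean IMD <= max_mean."""
    pos = np.sort(np.unique(positions))
    windows = []
    n = len(pos)
    for i in range(n):
        for j in range(i + min_mut - 1, n):
            imds = np.diff(pos[i : j + 1])
            if imds.mean() <= max_mean:
                windows.append((int(pos[i]), int(pos[j])))
    # keep maximal windows only
    maximal = [w for w in windows if not any(
        (o[0] <= w[0] and w[1] <= o[1] and o != w) for o in windows)]
    return maximal


def test_intermutation_distances_basic():
    d = intermutation_distances(snvs([100, 200, 1200]))
    np.testing.assert_array_equal(d["chr1"], [100, 1000])


def test_single_mutation_gives_empty_distances():
    assert len(intermutation_distances(snvs([500]))["chr1"]) == 0


def test_distances_never_cross_chromosomes():
    recs = snvs([100, 200]) + snvs([150], chrom="chr2")
    d = intermutation_distances(recs)
    np.testing.assert_array_equal(d["chr1"], [100])
    assert len(d["chr2"]) == 0


def test_duplicate_positions_collapsed():
    d = intermutation_distances(snvs([100, 100, 300]))
    np.testing.assert_array_equal(d["chr1"], [200])


def test_pcf_constant_input_single_segment():
    segs = pcf_segment([4.0] * 7, gamma=1.0, kmin=1)
    assert segs == [(0, 6, 4.0)]


def test_pcf_two_level_split():
    segs = pcf_segment([1, 1, 1, 9, 9, 9], gamma=0.5, kmin=1)
    assert [(s[0], s[1]) for s in segs] == [(0, 2), (3, 5)]
    assert [s[2] for s in segs] == [1.0, 9.0]


def test_pcf_huge_gamma_single_segment():
    segs = pcf_segment([1, 1, 9, 9, 1, 1], gamma=1e9, kmin=1)
    assert len(segs) == 1


@pytest.mark.parametrize("kmin", [1, 2, 3])
def test_pcf_matches_exhaustive_enumeration(kmin):
    """DP objective equals the minimum over all segmentations (n <= 10)."""
    rng = np.random.default_rng(7)
    for trial in range(15):
        n = int(rng.integers(2, 11))
        y = rng.choice([0.0, 2.0, 5.0], size=n) + rng.normal(0, 0.2, size=n)
        gamma = float(rng.uniform(0.2, 3.0))
        segs = pcf_segment(y, gamma=gamma, kmin=kmin)
        dp_cost = pcf_objective(y, segs, gamma)
        brute_cost, _ = brute_force_pcf(y, gamma, kmin)
        if np.isfinite(brute_cost):
            assert dp_cost == pytest.approx(brute_cost, abs=1e-9)
            assert all(j - i + 1 >= kmin for i, j, _m in segs)
        else:
            # n < kmin admits no partition: documented single-segment fallback
            assert segs == [(0, n - 1, pytest.approx(float(y.mean())))]


def test_pcf_segments_partition_the_range():
    y = np.random.default_rng(3).normal(size=25)
    segs = pcf_segment(y, gamma=1.0, kmin=2)
    covered = [i for a, b, _m in segs for i in range(a, b + 1)]
    assert covered == list(range(25))


def test_pcf_rejects_bad_parameters():
    with pytest.raises(ValueError):
        pcf_segment([], gamma=1.0)
    with pytest.raises(ValueError):
        pcf_segment([1.0], gamma=0.0)
    with pytest.raises(ValueError):
        pcf_segment([1.0], gamma=1.0, kmin=0)


def test_six_tightly_spaced_mutations_called():
    pos = [10_000 + 100 * i for i in range(6)]
    # flanking background far away so segmentation isolates the cluster
    pos += [5_000_000, 10_000_000, 20_000_000, 30_000_000]
    regions = call_kataegis(snvs(pos))
    assert len(regions) == 1
    r = regions[0]
    assert r.n_mutations == 6
    assert r.mean_imd == pytest.approx(100.0)
    assert (r.start, r.end) == (10_000, 10_500)


def test_five_mutations_below_count_threshold():
    pos = [10_000 + 100 * i for i in range(5)]
    pos += [5_000_000, 10_000_000, 20_000_000, 30_000_000]
    assert call_kataegis(snvs(pos)) == []


def test_mean_imd_threshold_excludes_wide_cluster():
    """Six mutations whose IMDs average > 1000 bp never emit a 6-run region."""
    pos = [10_000]
    for d in (100, 100, 100, 100, 5000):
        pos.append(pos[-1] + d)
    pos += [5_000_000, 10_000_000, 20_000_000]
    regions = call_kataegis(snvs(pos))
    for r in regions:
        assert r.mean_imd <= 1000.0
        assert r.n_mutations >= 6
    # no region may span all six (mean 1080 bp violates the threshold)
    assert not any(r.start == 10_000 and r.end == pos[5] for r in regions)


def test_emitted_regions_revalidate_thresholds():
    """Direct recomputation of both thresholds on every emitted region."""
    from somacat.synthetic import KataegisInjection, simulate_positions

    recs, _ = simulate_positions(
        {"chr1": 50_000_000},
        injections=[KataegisInjection("chr1", 15, 100.0)],
        rng=99,
    )
    regions = call_kataegis(recs)
    assert regions
    pos = np.sort(np.unique([r.pos for r in recs]))
    for reg in regions:
        inside = pos[(pos >= reg.start) & (pos <= reg.end)]
        assert len(inside) == reg.n_mutations >= 6
        assert np.diff(inside).mean() == pytest.approx(reg.mean_imd)
        assert reg.mean_imd <= 1000.0


def test_agrees_with_brute_force_windows_on_small_chromosomes():
    """Where segmentation boundaries permit, calls match exhaustive scanning.

    The cluster sits mid-sequence with background on both sides, so the
    minimum-segment-length constraint never forces a flanking distance
    into the cluster segment.  Every emitted region must lie inside a
    brute-force maximal window, and every window must be recovered.
    """
    rng = np.random.default_rng(11)
    for trial in range(10):
        background = np.cumsum(rng.exponential(100_000, size=30)).astype(int) + 1
        start = int(rng.integers(1_000_000, 1_800_000))
        cluster = start + np.cumsum(rng.geometric(1 / 100.0, size=7))
        pos = np.sort(np.concatenate([background, cluster]))
        regions = call_kataegis(snvs(pos))
        windows = brute_force_kataegis_windows(pos)
        # containment: every emitted region is a qualifying window
        for r in regions:
            assert any(w[0] <= r.start and r.end <= w[1] for w in windows)
        # recovery: every maximal window overlaps an emitted region
        for w in windows:
            assert any(r.start <= w[1] and r.end >= w[0] for r in regions)
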