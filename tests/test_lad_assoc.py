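import numpy as np
import pytest

from oxomap.binning_density import GenomeBin
from oxomap.errors import DegenerateStatisticError, ValidationError
from oxomap.io_formats import GenomeAssembly, IntervalValue, ProbeSignal
from oxomap.lad_assoc import (
    LadSplitParams,
    density_grid,
    fragment_profiles,
    group_histograms,
    group_stats,
    permutation_test,
    split_by_cutoff,
)


def make_fragments(signals, lamins):
    return [
        GenomeBin("chr1", i * 1000, (i + 1) * 1000, n_probes=1,
                  mean_signal=float(s), lamin=float(l))
        for i, (s, l) in enumerate(zip(signals, lamins))
    ]


class TestFragmentProfiles:
    def test_full_coverage_single_interval(self):
        asm = GenomeAssembly((("chr1", 200_000),))
        lamin = [IntervalValue("chr1", 0, 200_000, 1.7)]
        grid = fragment_profiles(asm, [ProbeSignal("chr1", 0, 60, 0.5)], lamin)
        assert grid.bins[0].lamin == pytest.approx(1.7)
        assert grid.bins[0].mean_signal == pytest.approx(0.5)

    def test_half_coverage_uses_covered_bases_only(self):
        asm = GenomeAssembly((("chr1", 200_000),))
        lamin = [IntervalValue("chr1", 0, 100_000, 2.0)]
        grid = fragment_profiles(asm, [ProbeSignal("chr1", 0, 60, 0.0)], lamin)
        assert grid.bins[0].lamin == pytest.approx(2.0)

    def test_fifty_fifty_weighted_mean(self):
        asm = GenomeAssembly((("chr1", 200_000),))
        lamin = [
            IntervalValue("chr1", 0, 100_000, -1.0),
            IntervalValue("chr1", 100_000, 200_000, 3.0),
        ]
        grid = fragment_profiles(asm, [ProbeSignal("chr1", 0, 60, 0.0)], lamin)
        assert grid.bins[0].lamin == pytest.approx(1.0)

    def test_uncovered_fragment_missing(self):
        asm = GenomeAssembly((("chr1", 400_000),))
        lamin = [IntervalValue("chr1", 0, 200_000, 1.0)]
        grid = fragment_profiles(asm, [ProbeSignal("chr1", 300_000, 300_060, 0.0)], lamin)
        assert grid.bins[1].lamin is None

    def test_interval_spanning_fragments_split_by_length(self):
        asm = GenomeAssembly((("chr1", 400_000),))
        lamin = [IntervalValue("chr1", 100_000, 300_000, 4.0)]
        grid = fragment_profiles(asm, [], lamin)
        assert grid.bins[0].lamin == pytest.approx(4.0)
        assert grid.bins[1].lamin == pytest.approx(4.0)


class TestSplitByCutoff:
    def test_one_per_group(self):
        frags = make_fragments([0.1, 0.2], [-1.0, 1.0])
        pos, neg = split_by_cutoff(frags)
        assert len(pos) == 1 and len(neg) == 1

    def test_exact_zero_goes_negative(self):
        frags = make_fragments([0.1, 0.2], [0.0, 1.0])
        pos, neg = split_by_cutoff(frags, cutoff=0.0)
        assert neg[0].lamin == 0.0

    def test_bimodal_sizes_match_direct_count(self):
        rng = np.random.default_rng(1)
        lamins = np.concatenate([rng.normal(-2, 0.5, 60), rng.normal(2, 0.5, 40)])
        frags = make_fragments(np.zeros(100), lamins)
        pos, neg = split_by_cutoff(frags)
        assert len(pos) == int((lamins > 0).sum())
        assert len(neg) == int((lamins <= 0).sum())

    def test_empty_group_is_error(self):
        frags = make_fragments([0.1, 0.2], [1.0, 2.0])
        with pytest.raises(ValidationError):
            split_by_cutoff(frags)


class TestGroupStats:
    def test_constant_groups_error_surfaced(self):
        frags = make_fragments([1.0, 1.0, 1.0, 1.0], [-1, -1, 1, 1])
        pos, neg = split_by_cutoff(frags)
        with pytest.raises(DegenerateStatisticError):
            group_stats(pos, neg)

    def test_recovers_constructed_difference(self):
        rng = np.random.default_rng(2)
        n = 500
        signals = np.concatenate([rng.normal(0.0, 0.1, n), rng.normal(0.38, 0.1, n)])
        lamins = np.concatenate([np.full(n, -2.0), np.full(n, 2.0)])
        pos, neg = split_by_cutoff(make_fragments(signals, lamins))
        res = group_stats(pos, neg)
        se = 0.1 * np.sqrt(2 / n)
        assert abs(res.diff - 0.38) < 3 * se

    def test_single_value_groups_rejected(self):
        frags = make_fragments([1.0, 2.0], [-1, 1])
        pos, neg = split_by_cutoff(frags)
        with pytest.raises(ValidationError):
            group_stats(pos, neg)


class TestPermutationTest:
    def test_constant_signal_degenerate(self):
        frags = make_fragments(np.ones(20), np.linspace(-2, 2, 20))
        res = permutation_test(frags, n_iter=100, seed=0)
        assert res.degenerate and res.observed_diff == 0.0 and res.null_sd == 0.0

    def test_null_z_calibration(self):
        # lamin labels independent of signal: |z| < 3 in >=99% of runs
        rng = np.random.default_rng(7)
        n_extreme = 0
        for rep in range(200):
            signals = rng.normal(size=80)
            lamins = rng.choice([-2.0, 2.0], size=80)
            if len(set(lamins)) < 2:
                continue
            res = permutation_test(make_fragments(signals, lamins), n_iter=500, seed=rep)
            n_extreme += abs(res.z_score) >= 3
        assert n_extreme <= 2

    def test_planted_effect_large_z_and_min_p(self):
        rng = np.random.default_rng(8)
        n = 600
        signals = np.concatenate([rng.normal(0, 0.1, n), rng.normal(1.5, 0.1, n)])
        lamins = np.concatenate([np.full(n, -2.0), np.full(n, 2.0)])
        res = permutation_test(make_fragments(signals, lamins), n_iter=1000, seed=3)
        assert res.z_score > 10
        assert res.empirical_p == pytest.approx(1 / 1001)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        frags = make_fragments(rng.normal(size=50), rng.choice([-2.0, 2.0], 50))
        r1 = permutation_test(frags, n_iter=200, seed=5)
        r2 = permutation_test(frags, n_iter=200, seed=5)
        assert r1 == r2

    def test_exchangeability_two_seeds_agree(self):
        rng = np.random.default_rng(10)
        frags = make_fragments(rng.normal(size=200), rng.choice([-2.0, 2.0], 200))
        r1 = permutation_test(frags, n_iter=1000, seed=1)
        r2 = permutation_test(frags, n_iter=1000, seed=2)
        tol = 4 * max(r1.null_sd, r2.null_sd) / np.sqrt(1000)
        assert abs(r1.null_mean - r2.null_mean) <= tol

    def test_too_few_fragments_rejected(self):
        frags = make_fragments([0.0, 1.0], [-1, 1])
        with pytest.raises(ValidationError):
            permutation_test(frags, n_iter=10, seed=0)

    def test_studentized_variant_runs(self):
        rng = np.random.default_rng(12)
        frags = make_fragments(rng.normal(size=60), rng.choice([-2.0, 2.0], 60))
        res = permutation_test(frags, n_iter=200, seed=0, studentized=True)
        assert np.isfinite(res.z_score)


class TestDensityGrid:
    def test_single_fragment_single_cell(self):
        counts, _, _ = density_grid(make_fragments([0.5], [1.0]), x_bins=4, y_bins=4)
        assert counts.sum() == 1 and (counts == 1).sum() == 1

    def test_counts_conserved_under_refinement(self):
        rng = np.random.default_rng(13)
        frags = make_fragments(rng.normal(size=100), rng.normal(size=100))
        for bins in (5, 20, 50):
            counts, _, _ = density_grid(frags, x_bins=bins, y_bins=bins)
            assert counts.sum() == 100

    def test_hand_counted_two_by_two(self):
        frags = make_fragments([0.0, 0.0, 1.0, 1.0], [0.0, 1.0, 0.0, 1.0])
        counts, _, _ = density_grid(frags, x_bins=2, y_bins=2)
        assert counts.tolist() == [[1.0, 1.0], [1.0, 1.0]]

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            density_grid([])


def test_group_histograms_structure():
    rng = np.random.default_rng(14)
    frags = make_fragments(
        np.concatenate([rng.normal(0, 0.1, 50), rng.normal(0.4, 0.1, 50)]),
        np.concatenate([np.full(50, -2.0), np.full(50, 2.0)]),
    )
    pos, neg = split_by_cutoff(frags)
    df = group_histograms(pos, neg, n_bins=20)
    assert df["positive_count"].sum() == 50
    assert df["negative_count"].sum() == 50
    # unimodal-ish separation: positive mass sits above negative mass
    pos_mean = np.average((df.bin_start + df.bin_end) / 2, weights=df.positive_count)
    neg_mean = np.average((df.bin_start + df.bin_end) / 2, weights=df.negative_count)
    assert pos_mean > neg_mean


def test_params_validation():
    with pytest.raises(ValidationError):
        LadSplitParams(fragment_size=0)
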