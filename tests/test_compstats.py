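"""Co-occupancy Fisher tests, clustering, correlation, conservation windows."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from discbind.compstats import (
    cluster_significance_matrix,
    compare_conservation,
    conservation_window_mean,
    linkage_to_newick,
    merge_regions,
    overlap_fisher,
    pairwise_overlap_fisher,
    windowed_correlation,
)
from discbind.synthdata import TruthConfig, make_genome, plant_sites, simulate_signal
from discbind.tracks import IntervalTrack, ProbeTrack
from conftest import make_peaks


def hypergeom_tail_exact(k, N, n, m):
    """Independent oracle: exact upper-tail by direct combinatorial summation."""
    total = 0
    for x in range(k, min(n, m) + 1):
        total += math.comb(m, x) * math.comb(N - m, n - x)
    return total / math.comb(N, n)


class TestFisher:
    def test_complete_overlap_small_universe(self):
        res = overlap_fisher(5, 5, 5, 20)
        assert res.p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_independence_point_is_not_significant(self):
        # k at the independence expectation n_i*n_j/N
        res = overlap_fisher(50, 40, 10, 200)
        assert res.p > 0.3

    def test_zero_overlap_is_nonsignificant_one_sided(self):
        res = overlap_fisher(80, 90, 0, 200)
        assert res.p > 0.999

    def test_negative_cell_raises_with_pair(self):
        with pytest.raises(ValueError, match="A.*B"):
            overlap_fisher(150, 150, 10, 200, pair=("A", "B"))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 501))
        n = int(rng.integers(1, N + 1))
        m = int(rng.integers(1, N + 1))
        lo = max(0, n + m - N)
        k = int(rng.integers(lo, min(n, m) + 1))
        res = overlap_fisher(n, m, k, N)
        assert res.p == pytest.approx(hypergeom_tail_exact(k, N, n, m), rel=1e-9)


class TestPairwiseMatrix:
    def sets(self):
        a = make_peaks("A", [1000, 5000, 9000, 13_000])
        b = make_peaks("B", [1100, 5200, 40_000])
        c = make_peaks("C", [80_000, 90_000])
        return [a, b, c]

    def test_universe_is_merged_region_count(self):
        N, membership = merge_regions(self.sets())
        # merged: {1000,1100}, {5000,5200}, {9000}, {13000}, {40000}, {80000}, {90000}
        assert N == 7
        assert sum(1 for m in membership if m == {0, 1}) == 2

    def test_self_pair_attains_matrix_maximum(self):
        mat = pairwise_overlap_fisher(self.sets())
        arr = mat.to_numpy()
        assert np.all(np.diag(arr).max() == arr.max())

    def test_matrix_symmetric(self):
        mat = pairwise_overlap_fisher(self.sets())
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)


class TestClustering:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame(
            [[10.0, 10.0, 1.0], [10.0, 10.0, 1.0], [1.0, 1.0, 8.0]],
            index=list("abc"), columns=list("abc"),
        )
        leaves, Z = cluster_significance_matrix(m)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == 0.0

    def test_average_linkage_matches_hand_computation(self):
        # rows: x=(0,0), y=(3,0)  z=(10,0) in 2D -> d(x,y)=3, d(x,z)=10, d(y,z)=7
        m = pd.DataFrame([[0.0, 0.0], [3.0, 0.0], [10.0, 0.0]], index=list("xyz"))
        # not symmetric-square; cluster on a symmetric distance-like matrix instead
        sym = pd.DataFrame(
            [[0.0, 3.0, 10.0], [3.0, 0.0, 7.0], [10.0, 7.0, 0.0]],
            index=list("xyz"), columns=list("xyz"),
        )
        _, Z = cluster_significance_matrix(sym)
        # Euclidean row distances: d(x,y)=sqrt(9+9+9)... compute directly
        rows = sym.to_numpy()
        d = lambda i, j: np.linalg.norm(rows[i] - rows[j])
        first = min(itertools.combinations(range(3), 2), key=lambda ij: d(*ij))
        assert {int(Z[0, 0]), int(Z[0, 1])} == set(first)
        # average linkage height of the last merge: mean distance to the pair
        rest = ({0, 1, 2} - set(first)).pop()
        expect = np.mean([d(rest, first[0]), d(rest, first[1])])
        assert Z[1, 2] == pytest.approx(expect)

    def test_permutation_preserves_merge_heights(self):
        rng = np.random.default_rng(2)
        base = rng.random((4, 4))
        sym = pd.DataFrame((base + base.T) / 2, index=list("abcd"), columns=list("abcd"))
        perm = ["c", "a", "d", "b"]
        _, Z1 = cluster_significance_matrix(sym)
        _, Z2 = cluster_significance_matrix(sym.loc[perm, perm])
        assert np.allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]))

    def test_non_finite_rejected(self):
        m = pd.DataFrame([[np.inf, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="cap"):
            cluster_significance_matrix(m)

    def test_newick_roundtrip_shape(self):
        sym = pd.DataFrame(np.eye(3) * 5, index=list("abc"), columns=list("abc"))
        _, Z = cluster_significance_matrix(sym)
        nwk = linkage_to_newick(Z, list("abc"))
        assert nwk.endswith(";") and nwk.count("(") == 2


def probe_track(values, spacing=100):
    t = ProbeTrack()
    v = np.asarray(values, float)
    t.add("chr1", np.arange(v.size) * spacing, v)
    return t


class TestWindowedCorrelation:
    def test_self_correlation_is_one(self):
        t = probe_track(np.sin(np.arange(100)))
        assert windowed_correlation(t, t) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        t = probe_track(np.sin(np.arange(100)))
        tn = t.map_values(lambda v: -v)
        assert windowed_correlation(t, tn) == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        a = probe_track(rng.normal(size=200))
        b = probe_track(rng.normal(size=200))
        r1 = windowed_correlation(a, b)
        r2 = windowed_correlation(a.map_values(lambda v: 3 * v + 7), b)
        assert r1 == pytest.approx(r2)

    def test_too_few_windows_rejected(self):
        t = probe_track(np.ones(4))
        with pytest.raises(ValueError, match="window"):
            windowed_correlation(t, t)

    @pytest.mark.parametrize("pair_seed", range(4))
    def test_higher_shared_fraction_gives_higher_correlation(self, pair_seed):
        def corr_at(frac, seed):
            cfg = TruthConfig(
                seed=seed, n_chromosomes=1, chrom_length_bp=1_000_000, n_genes=0,
                n_sites={("haltere", "Ubx"): 60, ("leg", "Ubx"): 60,
                         ("haltere", "Hth"): 0, ("leg", "Hth"): 0},
                tissue_shared_fraction=frac, factor_cobound_fraction=0.0,
            )
            truth = plant_sites(cfg, make_genome(cfg))
            ip_h, _ = simulate_signal(truth, cfg, "haltere", "Ubx")
            ip_l, _ = simulate_signal(truth, cfg, "leg", "Ubx")
            return windowed_correlation(ip_h, ip_l)

        assert corr_at(0.8, pair_seed) > corr_at(0.2, pair_seed)


class TestConservation:
    def flat_track(self, value, length=100_000):
        t = IntervalTrack()
        t.add("chr1", [0], [length], [value])
        return t

    def test_constant_track_mean(self):
        peaks = make_peaks("x", [10_000, 20_000])
        means = conservation_window_mean(peaks, self.flat_track(0.7))
        assert np.allclose(means, 0.7)

    def test_half_window_coverage(self):
        t = IntervalTrack()
        # left half-window scores 1, right half 0
        t.add("chr1", [9500, 10_000], [10_000, 10_500], [1.0, 0.0])
        peaks = make_peaks("x", [10_000])
        means = conservation_window_mean(peaks, t)
        assert means.iloc[0] == pytest.approx(0.5)

    def test_uncovered_window_flagged_missing(self):
        t = IntervalTrack()
        t.add("chr1", [0], [1000], [1.0])
        peaks = make_peaks("x", [50_000])
        means = conservation_window_mean(peaks, t)
        assert np.isnan(means.iloc[0])

    def test_planted_class_difference_detected(self):
        rng = np.random.default_rng(3)
        t = IntervalTrack()
        centers_a = [20_000 + 2000 * i for i in range(50)]
        centers_b = [200_000 + 2000 * i for i in range(50)]
        starts, ends, vals = [], [], []
        for c in centers_a:
            starts.append(c - 500); ends.append(c + 500)
            vals.append(rng.normal(0.8, 0.1))
        for c in centers_b:
            starts.append(c - 500); ends.append(c + 500)
            vals.append(rng.normal(0.4, 0.1))
        t.add("chr1", starts, ends, vals)
        ma = conservation_window_mean(make_peaks("a", centers_a), t)
        mb = conservation_window_mean(make_peaks("b", centers_b), t)
        assert compare_conservation(ma, mb) < 1e-6
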