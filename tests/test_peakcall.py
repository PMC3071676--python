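"""Caller analogues and the dual-threshold consensus rule."""

import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from discbind.peakcall import (
    CallerParams,
    call_regions,
    consensus_peaks,
    exact_rank_sum_p,
    score_mat_like,
    score_tas_like,
)
from discbind.synthdata import PlantedTruth, TruthConfig, simulate_signal
from discbind.tracks import ProbeTrack


def track(values, spacing=100, chrom="chr1"):
    t = ProbeTrack()
    values = np.asarray(values, dtype=float)
    t.add(chrom, np.arange(values.size) * spacing, values)
    return t


class TestRankSum:
    def test_complete_separation_gives_exact_combinatorial_p(self):
        p = exact_rank_sum_p(np.arange(10) + 100.0, np.arange(10).astype(float))
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.5, 1, size=8)
        y = rng.normal(0, 1, size=12)
        ours = exact_rank_sum_p(x, y)
        ref = mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_identical_windows_are_not_enriched(self):
        v = np.sin(np.arange(40))
        p = score_tas_like(track(v), track(v), CallerParams(bandwidth_bp=500))
        pos, pv = p["chr1"]
        assert np.all(pv >= 0.5)

    def test_adding_constant_to_ip_never_raises_p(self):
        rng = np.random.default_rng(1)
        ip = rng.normal(0, 1, size=60)
        inp = rng.normal(0, 1, size=60)
        params = CallerParams(bandwidth_bp=500)
        p0 = score_tas_like(track(ip), track(inp), params)["chr1"][1]
        p1 = score_tas_like(track(ip + 1.0), track(inp), params)["chr1"][1]
        assert np.all(p1 <= p0 + 1e-12)

    def test_short_window_edges_flagged_p1(self):
        params = CallerParams(bandwidth_bp=500, min_probes=4)
        p = score_tas_like(track(np.ones(20)), track(np.zeros(20)), params)["chr1"][1]
        assert p[0] == 1.0 and p[-1] == 1.0


class TestMatLike:
    def test_all_zero_log_ratios_score_zero(self):
        z = np.zeros(30)
        scores, _ = score_mat_like(track(z), track(z), CallerParams())
        assert np.all(scores["chr1"][1] == 0.0)

    def test_trimmed_mean_follows_stated_rule(self):
        # 5-probe track, bandwidth covering all 5: center probe's score is
        # the 20%-per-tail trimmed mean of the standardized log-ratios
        vals = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        ip, inp = track(vals), track(np.zeros(5))
        scores, _ = score_mat_like(ip, inp, CallerParams(bandwidth_bp=500, trim_fraction=0.2))
        z = (vals - vals.mean()) / vals.std()
        expected = np.sort(z)[1:4].mean()  # == standardized trimmed mean 3
        assert scores["chr1"][1][2] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_nonconstant_raises(self):
        with pytest.raises(ValueError, match="standardization"):
            score_mat_like(track(np.full(20, 2.0)), track(np.zeros(20)), CallerParams())


class TestCallRegions:
    def test_empty_and_no_pass(self):
        assert call_regions(ProbeTrack(), "top_fraction", CallerParams()) == []

    def test_single_run_center_is_argmax_probe(self):
        # p-values: a dip of 6 passing probes, best (lowest p) at index 12
        p = np.ones(30)
        p[10:16] = [0.02, 0.01, 0.001, 0.01, 0.02, 0.03]
        params = CallerParams(top_fraction=0.2, min_probes=4, max_gap_bp=150)
        regions = call_regions(track(p), "top_fraction", params)
        assert len(regions) == 1
        assert regions[0].center == 12 * 100
        assert regions[0].n_probes == 6

    @pytest.mark.parametrize("spacing,expect", [(100, 1), (400, 2)])
    def test_gap_merge_rule(self, spacing, expect):
        # pass pattern 1,1,0,0,1,1 -> merged iff gap <= max_gap_bp
        p = np.ones(12)
        p[[2, 3, 6, 7]] = 0.001
        p[[4, 5]] = 0.9
        params = CallerParams(top_fraction=0.34, min_probes=2, max_gap_bp=300)
        regions = call_regions(track(p, spacing=spacing), "top_fraction", params)
        assert len(regions) == expect


class TestConsensus:
    def _tas(self, centers):
        params = CallerParams()
        from discbind.peakcall import ScoredRegion

        return [
            ScoredRegion("chr1", c - 100, c + 100, c, 0.0, 0.001, "tas_like")
            for c in centers
        ]

    def _mat(self, intervals):
        from discbind.peakcall import ScoredRegion

        return [
            ScoredRegion("chr1", s, e, (s + e) // 2, 5.0, float("nan"), "mat_like")
            for s, e in intervals
        ]

    def test_empty_mat_means_empty_consensus(self):
        assert len(consensus_peaks(self._tas([1000]), [], CallerParams())) == 0

    def test_keeps_only_tas_near_mat(self):
        cons = consensus_peaks(self._tas([1000, 5000]), self._mat([(900, 1100)]), CallerParams())
        assert [p.center for p in cons] == [1000]

    def test_boundary_distance_inclusive(self):
        # TAS center 1350 vs MAT [900,1100]: gap 250 -> kept; 1351 -> dropped
        cons = consensus_peaks(self._tas([1350, 1351]), self._mat([(900, 1100)]), CallerParams())
        assert [p.center for p in cons] == [1350]

    def test_consensus_subset_of_tas(self):
        rng = np.random.default_rng(5)
        tas = self._tas(sorted(rng.choice(100_000, size=50, replace=False)))
        mat = self._mat([(int(s), int(s) + 400) for s in rng.choice(100_000, size=30)])
        cons = consensus_peaks(tas, mat, CallerParams())
        tas_centers = {r.center for r in tas}
        assert all(p.center in tas_centers for p in cons)


def test_noise_free_planted_sites_recovered_exactly():
    """Every well-separated planted site yields one consensus peak whose
    center is within one probe spacing of the truth."""
    centers = [20_000 + 10_000 * i for i in range(10)]
    sites = {(t, f): [] for t in ("haltere", "leg") for f in ("Ubx", "Hth")}
    sites[("haltere", "Ubx")] = [("chr1", c) for c in centers]
    truth = PlantedTruth(sites=sites, gene_targets={})
    cfg = TruthConfig(
        seed=0, n_chromosomes=1, chrom_length_bp=200_000, n_genes=0,
        n_sites={k: 0 for k in sites}, noise_sd=0.0,
    )
    ip, inp = simulate_signal(truth, cfg, "haltere", "Ubx")
    # noise-free input is constant; add infinitesimal jitter so ranks exist
    rng = np.random.default_rng(0)
    ip = ip.map_values(lambda v: v + rng.normal(0, 1e-9, size=v.size))
    inp = inp.map_values(lambda v: v + rng.normal(0, 1e-9, size=v.size))
    params = CallerParams()
    tas = call_regions(score_tas_like(ip, inp, params), "top_fraction", params)
    scores, fdr_map = score_mat_like(ip, inp, params)
    mat = call_regions(scores, "fdr", params, fdr_map=fdr_map)
    cons = consensus_peaks(tas, mat, params)
    assert len(cons) == len(centers)
    for c, p in zip(centers, sorted(cons, key=lambda p: p.center)):
        assert abs(p.center - c) <= cfg.probe_spacing_bp
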