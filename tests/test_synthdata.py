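"""Generator contracts: composition, planted-count conservation, signal shape."""

import numpy as np
import pytest

from discbind.synthdata import (
    PlantedTruth,
    TruthConfig,
    make_genome,
    plant_motif_instances,
    plant_sites,
    simulate_expression,
    simulate_signal,
)
from discbind.motifscan import PWM, score_site


def _cfg(**kw):
    base = dict(
        seed=3,
        n_chromosomes=1,
        chrom_length_bp=1_000_000,
        n_genes=0,
        n_sites={
            ("haltere", "Ubx"): 100,
            ("leg", "Ubx"): 100,
            ("haltere", "Hth"): 0,
            ("leg", "Hth"): 0,
        },
        factor_cobound_fraction=0.0,
    )
    base.update(kw)
    return TruthConfig(**base)


def test_genome_gc_fraction_within_lln_band():
    cfg = _cfg(gc_fraction=0.5)
    genome = make_genome(cfg)
    seq = genome.seqs["chr1"]
    gc = np.isin(seq, np.frombuffer(b"GC", dtype=np.uint8)).mean()
    assert 0.48 <= gc <= 0.52


def test_empty_gene_annotation_is_valid():
    genome = make_genome(_cfg(n_genes=0))
    assert genome.genes == []
    assert genome.seqs["chr1"].size == 1_000_000


def test_gene_bodies_do_not_overlap():
    genome = make_genome(_cfg(n_genes=60))
    by_chrom = {}
    for g in genome.genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for spans in by_chrom.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


def test_same_seed_reproduces_genome_and_sites():
    cfg = _cfg()
    g1, g2 = make_genome(cfg), make_genome(cfg)
    assert all(np.array_equal(g1.seqs[c], g2.seqs[c]) for c in g1.seqs)
    t1, t2 = plant_sites(cfg, g1), plant_sites(cfg, g2)
    assert t1.sites == t2.sites


@pytest.mark.parametrize("frac,expected_shared", [(1.0, 100), (0.0, 0), (0.3, 30)])
def test_tissue_shared_counts_exact(frac, expected_shared):
    cfg = _cfg(tissue_shared_fraction=frac)
    truth = plant_sites(cfg, make_genome(cfg))
    a = set(truth.sites[("haltere", "Ubx")])
    b = set(truth.sites[("leg", "Ubx")])
    assert len(a) == len(b) == 100
    assert len(a & b) == expected_shared
    if frac == 1.0:
        assert truth.sites[("haltere", "Ubx")] == truth.sites[("leg", "Ubx")]
    if frac == 0.0:
        # non-shared sites keep the minimum spacing from the other tissue's
        dmin = min(
            abs(ca - cb)
            for _, ca in truth.sites[("haltere", "Ubx")]
            for _, cb in truth.sites[("leg", "Ubx")]
        )
        assert dmin >= 2000


def test_factor_cobound_counts_exact():
    cfg = _cfg(
        n_sites={
            ("haltere", "Ubx"): 100,
            ("leg", "Ubx"): 100,
            ("haltere", "Hth"): 50,
            ("leg", "Hth"): 50,
        },
        factor_cobound_fraction=0.4,
        tissue_shared_fraction=0.5,
    )
    truth = plant_sites(cfg, make_genome(cfg))
    for t in ("haltere", "leg"):
        co = set(truth.sites[(t, "Ubx")]) & set(truth.sites[(t, "Hth")])
        assert len(co) == 20  # 0.4 * min(100, 50)


def test_infeasible_density_names_spacing():
    cfg = _cfg(chrom_length_bp=800_000, n_sites={
        ("haltere", "Ubx"): 300, ("leg", "Ubx"): 300,
        ("haltere", "Hth"): 0, ("leg", "Hth"): 0},
        tissue_shared_fraction=0.0)
    with pytest.raises(ValueError, match="spacing"):
        plant_sites(cfg, make_genome(cfg))


def _truth_with_sites(centers, tissue="haltere", factor="Ubx"):
    sites = {(t, f): [] for t in ("haltere", "leg") for f in ("Ubx", "Hth")}
    sites[(tissue, factor)] = [("chr1", c) for c in centers]
    return PlantedTruth(sites=sites, gene_targets={})


def test_signal_shape_noise_free():
    cfg = _cfg(noise_sd=0.0, probe_spacing_bp=25, peak_amplitude=2.0, peak_sd_bp=250)
    truth = _truth_with_sites([5000])  # on the 25 bp probe grid, as is 5250
    ip, inp = simulate_signal(truth, cfg, "haltere", "Ubx")
    pos, val = ip["chr1"]
    assert val.max() == pytest.approx(2.0)
    assert pos[int(np.argmax(val))] == 5000
    # value one spatial sd * (250/250) from the center: amplitude * exp(-1/2)
    at = int(np.searchsorted(pos, 5000 + 250))
    assert val[at] == pytest.approx(2.0 * np.exp(-0.5), rel=1e-9)
    assert np.all(inp["chr1"][1] == 0.0)


def test_signal_no_sites_is_zero_and_linear_in_amplitude():
    cfg0 = _cfg(noise_sd=0.0)
    ip0, _ = simulate_signal(_truth_with_sites([]), cfg0, "haltere", "Ubx")
    assert np.all(ip0["chr1"][1] == 0.0)

    truth = _truth_with_sites([5000, 40000, 90000])
    ip1, _ = simulate_signal(truth, _cfg(noise_sd=0.0, peak_amplitude=1.5), "haltere", "Ubx")
    ip2, _ = simulate_signal(truth, _cfg(noise_sd=0.0, peak_amplitude=3.0), "haltere", "Ubx")
    assert np.allclose(2.0 * ip1["chr1"][1], ip2["chr1"][1])


class TestMotifPlanting:
    def _pwm(self):
        m = np.full((6, 4), 0.02)
        for i, b in enumerate([3, 0, 0, 3, 3, 2]):  # TAATTG
            m[i, b] = 0.94
        return PWM("planted", m / m.sum(axis=1, keepdims=True))

    def test_certain_planting_puts_scorable_word_at_center(self):
        # zero-entropy PWM: every sampled word is the consensus, so the
        # planted word must be recoverable and high-scoring at the center
        cfg = _cfg()
        genome = make_genome(cfg)
        truth = plant_sites(cfg, genome)
        m = np.zeros((6, 4))
        for i, b in enumerate([3, 0, 0, 3, 3, 2]):  # TAATTG
            m[i, b] = 1.0
        pwm = PWM("consensus_only", m)
        plant_motif_instances(truth, genome, pwm, hit_probability=1.0,
                              positional_sd_bp=0.0, cfg=cfg)
        w = pwm.width
        for ch, ctr in truth.sites[("haltere", "Ubx")]:
            word = genome.fetch(ch, ctr - w // 2, ctr - w // 2 + w)
            rc = word[::-1].translate(str.maketrans("ACGT", "TGCA"))
            assert max(score_site(pwm, word), score_site(pwm, rc)) > 3.0

    def test_zero_probability_leaves_genome_unchanged(self):
        cfg = _cfg()
        genome = make_genome(cfg)
        truth = plant_sites(cfg, genome)
        before = genome.seqs["chr1"].copy()
        plant_motif_instances(truth, genome, self._pwm(), hit_probability=0.0, cfg=cfg)
        assert np.array_equal(genome.seqs["chr1"], before)

    def test_binomial_band_on_planted_count(self):
        cfg = _cfg(n_sites={("haltere", "Ubx"): 200, ("leg", "Ubx"): 0,
                            ("haltere", "Hth"): 0, ("leg", "Hth"): 0},
                   tissue_shared_fraction=0.0)
        genome = make_genome(cfg)
        truth = plant_sites(cfg, genome)
        plant_motif_instances(truth, genome, self._pwm(), hit_probability=0.5, cfg=cfg)
        n_planted = sum(truth.motif_planted.values())
        assert 80 <= n_planted <= 120  # 95% binomial band at n=200, p=0.5


class TestExpression:
    def test_zero_effect_gives_empty_responsive_list(self, small_experiment):
        cfg, genome, truth = small_experiment
        _, responsive = simulate_expression(truth, genome, cfg, effect_log2=0.0)
        assert responsive == []

    def test_noise_free_effect_magnitude(self, small_experiment):
        cfg, genome, truth = small_experiment
        df, responsive = simulate_expression(truth, genome, cfg, effect_log2=2.0, noise_sd=0.0)
        resp = df[df.responsive]
        assert set(resp.gene) == set(responsive)
        assert np.allclose(resp.log2_haltere_vs_wing.abs(), 2.0)
        assert np.allclose(resp.log2_cbx1wing_vs_wing.abs(), 2.0)

    def test_planted_effects_recoverable_by_auc(self):
        cfg = _cfg(n_genes=300, n_sites={
            ("haltere", "Ubx"): 150, ("leg", "Ubx"): 0,
            ("haltere", "Hth"): 0, ("leg", "Hth"): 0},
            chrom_length_bp=4_000_000, tissue_shared_fraction=0.0)
        genome = make_genome(cfg)
        truth = plant_sites(cfg, genome)
        df, responsive = simulate_expression(truth, genome, cfg, effect_log2=2.0, noise_sd=0.5)
        if len(responsive) < 10 or len(responsive) > len(df) - 10:
            pytest.skip("degenerate planting for this layout")
        score = df.log2_haltere_vs_wing.abs().to_numpy()
        y = df.responsive.to_numpy()
        # rank-based AUC of |log-ratio| separating responsive vs not
        from scipy.stats import rankdata

        r = rankdata(score)
        auc = (r[y].sum() - y.sum() * (y.sum() + 1) / 2) / (y.sum() * (~y).sum())
        assert auc > 0.95
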