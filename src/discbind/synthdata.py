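"""Synthetic tiling-array ChIP experiments with planted ground truth.

Emulates the structure of a two-tissue x two-factor imaginal-disc ChIP-chip
study: a random genome with non-overlapping gene models, binding sites
planted per (tissue, factor) with controlled tissue-sharing and
factor-co-binding fractions, probe-level IP/input log-ratio tracks whose
peaks are Gaussian bumps at fragment scale (sd 250 bp, matching ~500 bp
sonication fragments), motif words written near site centers, and a
two-contrast expression table in which genes near sites bound in the
"haltere" condition carry a planted effect.

Everything is driven by a single seed: identical (config, seed) yields
byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genetargets import GeneAnnotation, GeneModel
from .intervals import FACTORS, TISSUES, Peak, PeakSet
from .tracks import ProbeTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {65: 84, 67: 71, 71: 67, 84: 65, 78: 78}

#: Minimum center-to-center spacing between distinct planted loci, chosen
#: so the 500 bp center-distance overlap rule is unambiguous.
MIN_SITE_SPACING_BP = 2000


@dataclass
class Genome:
    """Chromosome sequences (uint8 ASCII arrays) plus gene models."""

    seqs: dict[str, np.ndarray]
    genes: list[GeneModel]

    @property
    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(self.genes)

    def sequence(self, chrom: str) -> str:
        return self.seqs[chrom].tobytes().decode("ascii")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        L = self.seqs[chrom].size
        s, e = max(0, start), min(L, end)
        out = self.seqs[chrom][s:e].tobytes().decode("ascii")
        return "N" * (s - start) + out + "N" * (end - e)


@dataclass(frozen=True)
class TruthConfig:
    """Study-design parameters for one synthetic experiment.

    ``n_sites`` maps (tissue, factor) to the number of bound regions
    planted for that condition; defaults are scaled-down but keep the
    study's qualitative structure (many more Ubx sites in the haltere
    than the leg, Hth the other way around).
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    gc_fraction: float = 0.43  # fly-like euchromatin composition
    n_genes: int = 200
    n_sites: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("haltere", "Ubx"): 90,
            ("leg", "Ubx"): 30,
            ("haltere", "Hth"): 20,
            ("leg", "Hth"): 40,
        }
    )
    tissue_shared_fraction: float = 0.3
    factor_cobound_fraction: float = 0.2
    peak_amplitude: float = 2.0  # log2 units (~4-fold IP enrichment)
    peak_sd_bp: int = 250  # spatial sd of the bump; ~500 bp fragments
    noise_sd: float = 0.4  # per-probe log2 noise
    probe_spacing_bp: int = 36
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tissue_shared_fraction", "factor_cobound_fraction", "gc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        for name in ("n_chromosomes", "chrom_length_bp", "probe_spacing_bp", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if any(n < 0 for n in self.n_sites.values()):
            raise ValueError("site counts must be non-negative")
        max_n = max(self.n_sites.values(), default=0)
        if max_n and self.n_chromosomes * self.chrom_length_bp < 10 * self.peak_sd_bp * max_n:
            raise ValueError(
                "genome too short for the requested site density "
                f"(need >= 10 * {self.peak_sd_bp} * {max_n} bp)"
            )


@dataclass
class PlantedTruth:
    """Ground truth of one synthetic experiment."""

    sites: dict[tuple[str, str], list[tuple[str, int]]]  # (tissue,factor) -> [(chrom, center)]
    gene_targets: dict[str, bool]  # gene id -> has a haltere-condition site within 2 kb
    motif_planted: dict[tuple[str, int], bool] = field(default_factory=dict)
    motif_skipped: int = 0

    def peak_set(self, tissue: str, factor: str, half_width: int = 250) -> PeakSet:
        peaks = [
            Peak(c, max(0, x - half_width), x + half_width, x)
            for c, x in self.sites[(tissue, factor)]
        ]
        return PeakSet((tissue, factor), peaks)

    def shared_fraction(self, factor: str, tissue: str = TISSUES[0]) -> float:
        """Fraction of `tissue`'s sites for `factor` present in the other tissue."""
        other = TISSUES[1] if tissue == TISSUES[0] else TISSUES[0]
        a = set(self.sites[(tissue, factor)])
        b = set(self.sites[(other, factor)])
        return len(a & b) / len(a) if a else float("nan")


def _rng(cfg: TruthConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, salt])


def make_genome(cfg: TruthConfig) -> Genome:
    """Random genome with the configured GC content and non-overlapping genes.

    Genes (2–8 kb, random strand) are placed on disjoint slots; raises if
    the requested count cannot be placed without overlap.
    """
    rng = _rng(cfg, 1)
    p = np.array(
        [(1 - cfg.gc_fraction) / 2, cfg.gc_fraction / 2, cfg.gc_fraction / 2, (1 - cfg.gc_fraction) / 2]
    )
    seqs = {}
    for i in range(cfg.n_chromosomes):
        seqs[f"chr{i + 1}"] = _BASES[rng.choice(4, size=cfg.chrom_length_bp, p=p)]

    genes: list[GeneModel] = []
    if cfg.n_genes:
        slot = 10_000  # gene max 8 kb + spacing
        slots_per_chrom = cfg.chrom_length_bp // slot
        total_slots = slots_per_chrom * cfg.n_chromosomes
        if cfg.n_genes > total_slots:
            raise ValueError(
                f"cannot place {cfg.n_genes} non-overlapping genes: only {total_slots} slots"
            )
        chosen = np.sort(rng.choice(total_slots, size=cfg.n_genes, replace=False))
        for k, s in enumerate(chosen):
            chrom = f"chr{int(s) // slots_per_chrom + 1}"
            base = (int(s) % slots_per_chrom) * slot
            length = int(rng.integers(2_000, 8_001))
            start = base + int(rng.integers(0, slot - length))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{k:04d}", chrom, start, start + length, strand))
    return Genome(seqs=seqs, genes=genes)


def _draw_loci(rng, cfg: TruthConfig, n: int, used: set) -> list[tuple[str, int]]:
    """Draw n loci on the spacing grid, disjoint from `used` slots."""
    spacing = MIN_SITE_SPACING_BP
    slots_per_chrom = (cfg.chrom_length_bp - spacing) // spacing
    total = slots_per_chrom * cfg.n_chromosomes
    free = [s for s in range(total) if s not in used]
    if n > len(free):
        raise ValueError(
            f"cannot plant {n} more sites with {spacing} bp minimum spacing: "
            f"only {len(free)} free slots"
        )
    picks = rng.choice(len(free), size=n, replace=False)
    out = []
    for s in (free[int(i)] for i in picks):
        used.add(s)
        chrom = f"chr{s // slots_per_chrom + 1}"
        center = (s % slots_per_chrom) * spacing + spacing // 2
        out.append((chrom, center))
    return out


def plant_sites(cfg: TruthConfig, genome: Genome) -> PlantedTruth:
    """Plant per-condition binding sites honouring the sharing fractions exactly.

    Per factor, round(tissue_shared_fraction * n) loci are identical in
    both tissues; per tissue, round(factor_cobound_fraction * min(n_Ubx,
    n_Hth)) loci carry both factors. The number of loci co-bound in both
    tissues is the independence expectation of the two fractions; the
    remaining co-bound loci come from tissue-specific pools. Distinct loci
    keep >= 2 kb spacing so overlap calls are unambiguous.
    """
    rng = _rng(cfg, 2)
    nU = {t: cfg.n_sites[(t, "Ubx")] for t in TISSUES}
    nH = {t: cfg.n_sites[(t, "Hth")] for t in TISSUES}

    def shared_count(n_by_tissue):
        return round(cfg.tissue_shared_fraction * min(n_by_tissue.values()))

    sU, sH = shared_count(nU), shared_count(nH)
    c = {t: round(cfg.factor_cobound_fraction * min(nU[t], nH[t])) for t in TISSUES}
    # loci bound by both factors in both tissues
    x = round(cfg.tissue_shared_fraction * cfg.factor_cobound_fraction * min(min(nU.values()), min(nH.values())))
    x = min(x, sU, sH, *(c[t] for t in TISSUES))
    y = {t: c[t] - x for t in TISSUES}
    for t in TISSUES:
        if nU[t] - sU - y[t] < 0 or nH[t] - sH - y[t] < 0:
            raise ValueError(
                "infeasible sharing/co-binding fractions: co-bound count "
                f"{c[t]} exceeds the tissue-specific pool in {t!r}"
            )

    used: set[int] = set()
    both_all = _draw_loci(rng, cfg, x, used)  # both factors, both tissues
    sharedU = _draw_loci(rng, cfg, sU - x, used)  # Ubx only, both tissues
    sharedH = _draw_loci(rng, cfg, sH - x, used)
    sites = {(t, f): [] for t in TISSUES for f in FACTORS}
    for t in TISSUES:
        both_t = _draw_loci(rng, cfg, y[t], used)  # both factors, this tissue
        onlyU = _draw_loci(rng, cfg, nU[t] - sU - y[t], used)
        onlyH = _draw_loci(rng, cfg, nH[t] - sH - y[t], used)
        sites[(t, "Ubx")] = sorted(both_all + sharedU + both_t + onlyU)
        sites[(t, "Hth")] = sorted(both_all + sharedH + both_t + onlyH)

    ann = genome.annotation
    gene_targets = {}
    halt = sites[("haltere", "Ubx")] + sites[("haltere", "Hth")]
    by_chrom: dict[str, list[int]] = {}
    for ch, ctr in halt:
        by_chrom.setdefault(ch, []).append(ctr)
    for ch in by_chrom:
        by_chrom[ch] = sorted(by_chrom[ch])
    for g in genome.genes:
        centers = by_chrom.get(g.chrom, [])
        i = int(np.searchsorted(centers, g.tss))
        near = any(
            abs(centers[j] - g.tss) <= 2000
            for j in (i - 1, i)
            if 0 <= j < len(centers)
        )
        gene_targets[g.gene_id] = near
    return PlantedTruth(sites=sites, gene_targets=gene_targets)


def simulate_signal(
    truth: PlantedTruth, cfg: TruthConfig, tissue: str, factor: str, replicate: int = 0
) -> tuple[ProbeTrack, ProbeTrack]:
    """(IP, input) probe tracks for one condition and replicate.

    IP probe values are the sum of Gaussian bumps (amplitude
    ``peak_amplitude``, sd ``peak_sd_bp``) over the condition's true sites
    plus N(0, noise_sd) noise; input tracks are noise only.
    """
    rng = _rng(cfg, 1000 + 17 * replicate + 3 * TISSUES.index(tissue) + FACTORS.index(factor))
    ip, inp = ProbeTrack(), ProbeTrack()
    centers_by_chrom: dict[str, list[int]] = {}
    for ch, ctr in truth.sites[(tissue, factor)]:
        centers_by_chrom.setdefault(ch, []).append(ctr)
    for i in range(cfg.n_chromosomes):
        chrom = f"chr{i + 1}"
        pos = np.arange(0, cfg.chrom_length_bp, cfg.probe_spacing_bp, dtype=np.int64)
        sig = np.zeros(pos.size)
        sd = float(cfg.peak_sd_bp)
        for ctr in centers_by_chrom.get(chrom, []):
            lo = int(np.searchsorted(pos, ctr - 5 * sd))
            hi = int(np.searchsorted(pos, ctr + 5 * sd))
            d = pos[lo:hi] - ctr
            sig[lo:hi] += cfg.peak_amplitude * np.exp(-0.5 * (d / sd) ** 2)
        ip.add(chrom, pos, sig + rng.normal(0.0, cfg.noise_sd, size=pos.size))
        inp.add(chrom, pos, rng.normal(0.0, cfg.noise_sd, size=pos.size))
    return ip, inp


def plant_motif_instances(
    truth: PlantedTruth,
    genome: Genome,
    pwm,
    hit_probability: float = 1.0,
    positional_sd_bp: float = 50.0,
    tissue: str = "haltere",
    factor: str = "Ubx",
    seed_salt: int = 3,
    cfg: TruthConfig | None = None,
) -> Genome:
    """Write PWM-sampled words near true site centers, in place.

    With probability ``hit_probability`` per site, a word sampled from the
    PWM's column frequencies (random strand) replaces the genome sequence
    at center + Normal(0, positional_sd_bp). Edits that would run past a
    chromosome end are skipped and counted in ``truth.motif_skipped``.
    """
    rng = np.random.default_rng([cfg.seed if cfg else 0, seed_salt])
    w = pwm.width
    for ch, ctr in truth.sites[(tissue, factor)]:
        key = (ch, ctr)
        if rng.random() >= hit_probability:
            truth.motif_planted[key] = False
            continue
        offset = int(round(rng.normal(0.0, positional_sd_bp))) if positional_sd_bp else 0
        start = ctr + offset - w // 2
        seq = genome.seqs[ch]
        if start < 0 or start + w > seq.size:
            truth.motif_skipped += 1
            truth.motif_planted[key] = False
            continue
        word = np.array(
            [_BASES[rng.choice(4, p=pwm.matrix[i])] for i in range(w)], dtype=np.uint8
        )
        if rng.random() < 0.5:  # plant on the reverse strand half the time
            word = np.array([_COMPLEMENT[int(b)] for b in word[::-1]], dtype=np.uint8)
        seq[start : start + w] = word
        truth.motif_planted[key] = True
    return genome


def simulate_expression(
    truth: PlantedTruth,
    genome: Genome,
    cfg: TruthConfig,
    effect_log2: float = 2.0,
    noise_sd: float = 0.5,
    sign_agreement: float = 0.9,
) -> tuple[pd.DataFrame, list[str]]:
    """Two-contrast expression table with planted effects at bound genes.

    Genes whose TSS lies within 2 kb of a haltere-condition site receive a
    +/-effect_log2 shift (sign randomised per gene); the second contrast
    repeats the sign with probability ``sign_agreement`` (0.9 gives the
    two planted-effect columns a correlation of about 0.8). All genes get
    independent N(0, noise_sd) noise per contrast. Returns the table and
    the responsive-gene list (genes with a planted effect).
    """
    rng = _rng(cfg, 4)
    rows = []
    responsive = []
    for g in genome.genes:
        planted = truth.gene_targets.get(g.gene_id, False) and effect_log2 != 0
        sign1 = 1.0 if rng.random() < 0.5 else -1.0
        sign2 = sign1 if rng.random() < sign_agreement else -sign1
        e1 = sign1 * effect_log2 if planted else 0.0
        e2 = sign2 * effect_log2 if planted else 0.0
        rows.append(
            {
                "gene": g.gene_id,
                "log2_haltere_vs_wing": e1 + rng.normal(0.0, noise_sd),
                "log2_cbx1wing_vs_wing": e2 + rng.normal(0.0, noise_sd),
                "responsive": planted,
            }
        )
        if planted:
            responsive.append(g.gene_id)
    return pd.DataFrame(rows), responsive
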