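"""End-to-end synthetic-mode pipeline.

``run_pipeline`` composes the whole analysis on one synthetic experiment:
simulate genome/signal with planted truth, score both callers, apply the
dual-threshold consensus per (tissue, factor), then emit the occupancy
overview, Venn counts, nearest-TSS target calls, the co-occupancy
significance matrix with its clustering, windowed track correlations, the
motif table, the binding x expression enrichment, and a JSON run log. All
outputs are plain text and byte-identical across runs with equal config.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compstats import (
    cluster_significance_matrix,
    linkage_to_newick,
    pairwise_overlap_fisher,
    windowed_correlation,
)
from .fileio import write_bed, write_gff3
from .genetargets import call_targets, calls_to_frame, target_gene_counts
from .integrate import binding_expression_enrichment
from .intervals import FACTORS, TISSUES, binding_summary, venn_counts
from .motifscan import PWM, hit_fraction, select_cutoff
from .params import AnalysisParameters, DEFAULT_PARAMS
from .peakcall import CallerParams, call_regions, consensus_peaks, score_mat_like, score_tas_like
from .synthdata import (
    Genome,
    PlantedTruth,
    TruthConfig,
    make_genome,
    plant_motif_instances,
    plant_sites,
    simulate_expression,
    simulate_signal,
)

def default_pwm() -> PWM:
    """An 8-column Hox-monomer-like PWM around a TAAT core."""
    counts = np.array(
        [
            # A   C   G   T
            [5, 5, 5, 85],    # T
            [85, 5, 5, 5],    # A
            [85, 5, 5, 5],    # A
            [5, 5, 5, 85],    # T
            [5, 5, 42, 48],   # t/g
            [5, 5, 85, 5],    # G
            [30, 20, 20, 30],
            [30, 20, 20, 30],
        ],
        dtype=float,
    )
    return PWM.from_counts("HoxMonomerLike", counts)


def call_condition(
    truth: PlantedTruth,
    cfg: TruthConfig,
    tissue: str,
    factor: str,
    caller_params: CallerParams,
):
    """simulate -> score (both callers) -> consensus for one condition."""
    ip, inp = simulate_signal(truth, cfg, tissue, factor)
    pvals = score_tas_like(ip, inp, caller_params)
    tas = call_regions(pvals, "top_fraction", caller_params)
    scores, fdr_map = score_mat_like(ip, inp, caller_params)
    mat = call_regions(scores, "fdr", caller_params, fdr_map=fdr_map)
    cons = consensus_peaks(tas, mat, caller_params, label=(tissue, factor))
    return {"ip": ip, "input": inp, "tas": tas, "mat": mat, "consensus": cons}


def peak_window_sequences(genome: Genome, peaks, half_bp: int) -> list[str]:
    return [genome.fetch(p.chrom, p.center - half_bp, p.center + half_bp) for p in peaks]


def run_pipeline(
    cfg: TruthConfig,
    outdir,
    params: AnalysisParameters = DEFAULT_PARAMS,
    caller_params: CallerParams | None = None,
    plant_motifs: bool = True,
) -> dict:
    """Run the full synthetic analysis; write the report bundle to outdir.

    Returns a dict of the main in-memory results (peak sets, summary,
    correlations, motif and enrichment results).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cp = caller_params or CallerParams(
        top_fraction=params.tas_top_fraction,
        fdr=params.mat_fdr,
        consensus_dist_bp=params.consensus_dist_bp,
    )
    stages = []

    genome = make_genome(cfg)
    truth = plant_sites(cfg, genome)
    pwm = default_pwm()
    if plant_motifs:
        plant_motif_instances(truth, genome, pwm, hit_probability=0.8,
                              positional_sd_bp=50.0, cfg=cfg)
    write_gff3(genome.annotation, outdir / "genes.gff3")
    stages.append("simulate")

    consensus = {}
    tracks = {}
    for t in TISSUES:
        for f in FACTORS:
            res = call_condition(truth, cfg, t, f, cp)
            consensus[(t, f)] = res["consensus"]
            tracks[(t, f)] = res["ip"]
            write_bed(res["consensus"], outdir / f"consensus_{t}_{f}.bed")
    stages.append("callpeaks+consensus")

    summary = binding_summary(consensus, params.overlap_center_dist_bp)
    summary.to_tsv(outdir / "binding_summary.tsv")
    venn = venn_counts(
        [consensus[(TISSUES[0], "Ubx")], consensus[(TISSUES[1], "Ubx")]],
        params.overlap_center_dist_bp,
    )
    with open(outdir / "venn_ubx.json", "w") as fh:
        json.dump({f"{i}|{'+'.join(map(str, sorted(m)))}": c for (i, m), c in sorted(
            venn.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1])))}, fh, indent=1, sort_keys=True)
    stages.append("compare")

    ann = genome.annotation
    target_counts = {}
    for (t, f), ps in consensus.items():
        calls = call_targets(ps, ann) if len(ann) else []
        calls_to_frame(calls).to_csv(outdir / f"targets_{t}_{f}.tsv", sep="\t", index=False)
        target_counts[f"{t}_{f}"] = target_gene_counts(calls) if calls else (0, 0)
    stages.append("annotate")

    fisher = pairwise_overlap_fisher(list(consensus.values()), params.overlap_center_dist_bp)
    fisher.to_csv(outdir / "cooccupancy_neglog10p.tsv", sep="\t", float_format="%.4f")
    leaves, Z = cluster_significance_matrix(fisher)
    (outdir / "cooccupancy_tree.nwk").write_text(linkage_to_newick(Z, list(fisher.index)) + "\n")
    correlations = {
        "Ubx_haltere_vs_leg": windowed_correlation(
            tracks[(TISSUES[0], "Ubx")], tracks[(TISSUES[1], "Ubx")], params.correlation_window_bp
        ),
        "Hth_haltere_vs_leg": windowed_correlation(
            tracks[(TISSUES[0], "Hth")], tracks[(TISSUES[1], "Hth")], params.correlation_window_bp
        ),
    }
    pd.Series(correlations, name="pearson_r").rename_axis("comparison").to_csv(
        outdir / "correlations.tsv", sep="\t", float_format="%.4f"
    )
    stages.append("costats")

    motif_rows = []
    hu = consensus[(TISSUES[0], "Ubx")]
    if plant_motifs and len(hu):
        seqs = peak_window_sequences(genome, hu, params.motif_scan_half_bp)
        rng = np.random.default_rng([cfg.seed, 99])
        sel = select_cutoff(pwm, seqs, params.motif_min_cutoff_bits, rng=rng)
        frac = hit_fraction(pwm, seqs, sel.cutoff, params.motif_hit_half_bp)
        motif_rows.append(
            {"motif": pwm.name, "cutoff_bits": sel.cutoff, "bias_p": sel.bias_p,
             "n_hits": sel.n_hits, "pct_peaks_hit_250bp": round(frac, 1),
             "grid_size": len(sel.grid)}
        )
        stages.append("motif")
    pd.DataFrame(motif_rows).to_csv(outdir / "motif_table.tsv", sep="\t", index=False)

    expr, responsive = simulate_expression(truth, genome, cfg)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False, float_format="%.4f")
    enrich = None
    if len(genome.genes):
        bound = set()
        for f in FACTORS:
            ps = consensus[(TISSUES[0], f)]
            if len(ps) and len(ann):
                bound |= {c.gene_id for c in call_targets(ps, ann)}
        enrich = binding_expression_enrichment(bound, set(responsive), len(genome.genes))
        pd.DataFrame([asdict(enrich)]).to_csv(
            outdir / "binding_expression_enrichment.tsv", sep="\t", index=False
        )
        stages.append("integrate")

    log = {
        "package": "discbind",
        "version": __version__,
        "seed": cfg.seed,
        "stages": stages,
        "parameters": params.to_dict(),
        "caller_params": asdict(cp),
        "truth_config": {k: (dict((f"{a}/{b}", v) for (a, b), v in val.items()) if k == "n_sites" else val)
                          for k, val in asdict(cfg).items()},
        "target_gene_counts": {k: list(v) for k, v in target_counts.items()},
        "cluster_leaves": list(leaves),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)

    return {
        "genome": genome,
        "truth": truth,
        "consensus": consensus,
        "summary": summary,
        "correlations": correlations,
        "motif_table": pd.DataFrame(motif_rows),
        "enrichment": enrich,
        "stages": stages,
    }
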