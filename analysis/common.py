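"""Shared study configuration for the numbered analysis scripts.

One synthetic two-tissue x two-factor experiment, scaled for the desk:
many more Ubx sites in the haltere than the leg (mirroring the study
system's ~5-fold asymmetry), Hth the other way around, with moderate
tissue sharing and factor co-binding. Every script re-derives what it
needs from this config, so the whole analysis is reproducible from the
seed alone.
"""

from pathlib import Path

from discbind.peakcall import (
    CallerParams,
    call_regions,
    consensus_peaks,
    score_mat_like,
    score_tas_like,
)
from discbind.synthdata import TruthConfig, make_genome, plant_sites, simulate_signal

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY = TruthConfig(
    seed=2026,
    n_chromosomes=2,
    chrom_length_bp=1_500_000,
    n_genes=250,
    n_sites={
        ("haltere", "Ubx"): 150,
        ("leg", "Ubx"): 30,
        ("haltere", "Hth"): 20,
        ("leg", "Hth"): 35,
    },
    tissue_shared_fraction=0.3,
    factor_cobound_fraction=0.2,
)

CALLER = CallerParams()


def experiment():
    genome = make_genome(STUDY)
    truth = plant_sites(STUDY, genome)
    return genome, truth


def call_condition(truth, tissue, factor):
    """Score both callers and return (tas, mat, consensus, ip_track)."""
    ip, inp = simulate_signal(truth, STUDY, tissue, factor)
    tas = call_regions(score_tas_like(ip, inp, CALLER), "top_fraction", CALLER)
    scores, fdr_map = score_mat_like(ip, inp, CALLER)
    mat = call_regions(scores, "fdr", CALLER, fdr_map=fdr_map)
    cons = consensus_peaks(tas, mat, CALLER, label=(tissue, factor))
    return tas, mat, cons, ip


def all_consensus(truth):
    out = {}
    tracks = {}
    for t in ("haltere", "leg"):
        for f in ("Ubx", "Hth"):
            *_, cons, ip = call_condition(truth, t, f)
            out[(t, f)] = cons
            tracks[(t, f)] = ip
    return out, tracks
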