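"""Co-occupancy significance, clustering, and genome-wide correlations.

Tests every pair of the four consensus sets for overlap enrichment
(one-sided Fisher on the merged-region universe), clusters the -log10 p
matrix, and computes 500 bp windowed Pearson correlations between the
tissues' IP tracks. Writes results/cooccupancy_*.{tsv,nwk} and
results/correlations.tsv.
"""

import pandas as pd

from common import RESULTS, all_consensus, experiment

from discbind.compstats import (
    cluster_significance_matrix,
    linkage_to_newick,
    pairwise_overlap_fisher,
    windowed_correlation,
)


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    _, truth = experiment()
    consensus, tracks = all_consensus(truth)

    mat = pairwise_overlap_fisher(list(consensus.values()))
    mat.to_csv(RESULTS / "cooccupancy_neglog10p.tsv", sep="\t", float_format="%.3f")
    leaves, Z = cluster_significance_matrix(mat)
    (RESULTS / "cooccupancy_tree.nwk").write_text(
        linkage_to_newick(Z, list(mat.index)) + "\n"
    )
    print("co-occupancy -log10 p matrix:")
    print(mat.round(2).to_string())
    print("cluster leaf order:", leaves)

    rows = {}
    for f in ("Ubx", "Hth"):
        rows[f"{f}_haltere_vs_leg"] = windowed_correlation(
            tracks[("haltere", f)], tracks[("leg", f)]
        )
    for t in ("haltere", "leg"):
        rows[f"Ubx_vs_Hth_{t}"] = windowed_correlation(
            tracks[(t, "Ubx")], tracks[(t, "Hth")]
        )
    s = pd.Series(rows, name="pearson_r").rename_axis("comparison")
    s.to_csv(RESULTS / "correlations.tsv", sep="\t", float_format="%.4f")
    print("\nwindowed correlations (500 bp):")
    print(s.round(3).to_string())


if __name__ == "__main__":
    main()
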