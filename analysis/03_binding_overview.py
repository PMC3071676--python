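"""Tissue/factor set algebra: the occupancy-overview table and Venn counts.

Builds the four consensus peak sets, then summarizes totals, cross-tissue
and cross-factor overlap percents (500 bp center rule, each set counted
from its own side), tissue-specific counts, and co-bound sets. Writes
results/binding_summary.tsv and results/venn_ubx.json.
"""

import json

from common import RESULTS, all_consensus, experiment

from discbind.intervals import binding_summary, venn_counts


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    _, truth = experiment()
    consensus, _ = all_consensus(truth)

    summary = binding_summary(consensus)
    summary.to_tsv(RESULTS / "binding_summary.tsv")
    print(summary.rows.to_string(index=False))

    venn = venn_counts([consensus[("haltere", "Ubx")], consensus[("leg", "Ubx")]])
    pretty = {
        f"set{i}_overlapping_{sorted(m) if m else 'none'}": c
        for (i, m), c in sorted(venn.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1])))
    }
    with open(RESULTS / "venn_ubx.json", "w") as fh:
        json.dump(pretty, fh, indent=1)
    print("\nUbx haltere-vs-leg Venn (per-side):", pretty)


if __name__ == "__main__":
    main()
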