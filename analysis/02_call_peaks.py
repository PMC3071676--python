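"""Dual-threshold consensus peak calling on the synthetic experiment.

For each (tissue, factor) condition: score the probe tracks with the
rank-sum caller (thresholded at the top 5% of p-values) and the
trimmed-mean caller (thresholded at 5% FDR from a sign-flip null), then
keep rank-sum peaks whose center lies within 250 bp of an FDR region.
The lenient single-caller lists shrink to a consensus list close to the
planted truth — the same reduction the dual threshold is designed for.
Writes consensus BEDs under results/peaks/.
"""

from common import RESULTS, call_condition, experiment

from discbind.fileio import write_bed


def main():
    out = RESULTS / "peaks"
    out.mkdir(parents=True, exist_ok=True)
    _, truth = experiment()

    print(f"{'condition':18s} {'tas':>5s} {'mat':>5s} {'consensus':>9s} {'planted':>8s}")
    for t in ("haltere", "leg"):
        for f in ("Ubx", "Hth"):
            tas, mat, cons, _ = call_condition(truth, t, f)
            write_bed(cons, out / f"consensus_{t}_{f}.bed")
            n_true = len(truth.sites[(t, f)])
            print(f"{t + '/' + f:18s} {len(tas):5d} {len(mat):5d} {len(cons):9d} {n_true:8d}")
    print(f"wrote consensus BEDs to {out}")


if __name__ == "__main__":
    main()
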