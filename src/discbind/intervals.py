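"""Center-distance peak overlap predicate and tissue/factor set algebra.

Two called regions are considered the same binding event when their
center-to-center distance is under 500 bp (strictly), roughly the scale of
a sonication fragment. All cross-tissue / cross-factor comparisons reduce
to this predicate. Because the relation is many-to-many, shared counts are
reported from each set's own side: |a overlapping b| need not equal
|b overlapping a|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import DEFAULT_PARAMS, round_percent

TISSUES = ("haltere", "leg")
FACTORS = ("Ubx", "Hth")


@dataclass(frozen=True)
class Peak:
    """A called binding region with a defined center (summit)."""

    chrom: str
    start: int
    end: int
    center: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start},{self.end})")
        if not self.start <= self.center < self.end:
            raise ValueError("center outside interval")


class PeakSet:
    """A labelled set of peaks, sorted by (chrom, center), centers deduped."""

    def __init__(self, label, peaks: Iterable[Peak]):
        self.label = label
        seen = set()
        uniq = []
        for p in sorted(peaks, key=lambda p: (p.chrom, p.center, p.start)):
            key = (p.chrom, p.center)
            if key in seen:
                continue
            seen.add(key)
            uniq.append(p)
        self.peaks: list[Peak] = uniq
        self._by_chrom: dict[str, np.ndarray] = {}
        for p in uniq:
            self._by_chrom.setdefault(p.chrom, []).append(p.center)
        self._by_chrom = {c: np.asarray(v, dtype=np.int64) for c, v in self._by_chrom.items()}

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def centers(self, chrom: str) -> np.ndarray:
        return self._by_chrom.get(chrom, np.empty(0, dtype=np.int64))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def has_partner(self, peak: Peak, max_dist: int) -> bool:
        """True iff some peak of this set lies strictly within max_dist of `peak`'s center."""
        centers = self.centers(peak.chrom)
        if centers.size == 0:
            return False
        i = int(np.searchsorted(centers, peak.center))
        for j in (i - 1, i):
            if 0 <= j < centers.size and abs(int(centers[j]) - peak.center) < max_dist:
                return True
        return False


def overlaps(a: Peak, b: Peak, max_dist: int = DEFAULT_PARAMS.overlap_center_dist_bp) -> bool:
    """Center-distance overlap: same chromosome and |center difference| < max_dist."""
    return a.chrom == b.chrom and abs(a.center - b.center) < max_dist


def partition(
    a: PeakSet, b: PeakSet, max_dist: int = DEFAULT_PARAMS.overlap_center_dist_bp
) -> tuple[PeakSet, PeakSet]:
    """Split `a` into (peaks with >=1 partner in `b`, the remainder).

    Counts are from `a`'s side; the relation is asymmetric.
    """
    shared, specific = [], []
    for p in a:
        (shared if b.has_partner(p, max_dist) else specific).append(p)
    return (
        PeakSet((a.label, "shared"), shared),
        PeakSet((a.label, "specific"), specific),
    )


def _pct(k: int, n: int) -> float:
    return round_percent(100.0 * k / n) if n else 0.0


@dataclass
class BindingSummary:
    """Occupancy-overview table: totals, cross-tissue / cross-factor percents,
    tissue-specific counts, and co-bound set statistics, per (tissue, factor)."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    cobound: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.1f")


def summary_row(total: int, shared_other_tissue: int, shared_other_factor: int) -> dict:
    """Derived quantities for one summary row, from that set's own side.

    Given the row's total and its shared counts, emit the percents (one
    decimal, half away from zero) and the tissue-specific count. This is
    the worked-example arithmetic of the overview table: e.g. a total of
    4590 with 732 shared across tissues gives 15.9%.
    """
    if shared_other_tissue > total or shared_other_factor > total:
        raise ValueError("shared count exceeds total")
    return {
        "total": total,
        "pct_other_tissue": _pct(shared_other_tissue, total),
        "pct_other_factor": _pct(shared_other_factor, total),
        "specific_count": total - shared_other_tissue,
    }


def binding_summary(
    sets: Mapping[tuple[str, str], PeakSet],
    max_dist: int = DEFAULT_PARAMS.overlap_center_dist_bp,
) -> BindingSummary:
    """Build the occupancy overview from four (tissue x factor) peak sets.

    For each (tissue, factor): the total, the percent with a partner in the
    other tissue (same factor), the percent with a partner of the other
    factor (same tissue), and the tissue-specific count. Co-bound sets
    (peaks of one factor overlapping the other factor in the same tissue,
    counted from the first factor's side) get their own rows with
    cross-tissue percents. Because the stated derivation of "co-bound,
    tissue-specific" from these predicates is ambiguous, both fully
    specific and co-bound-shared counts are reported.
    """
    for t in TISSUES:
        for f in FACTORS:
            if (t, f) not in sets:
                raise KeyError(f"missing peak set for label {(t, f)!r}")

    other_t = {TISSUES[0]: TISSUES[1], TISSUES[1]: TISSUES[0]}
    other_f = {FACTORS[0]: FACTORS[1], FACTORS[1]: FACTORS[0]}

    records = []
    cobound: dict[str, PeakSet] = {}
    for t in TISSUES:
        for f in FACTORS:
            s = sets[(t, f)]
            sh_t, _ = partition(s, sets[(other_t[t], f)], max_dist)
            sh_f, _ = partition(s, sets[(t, other_f[f])], max_dist)
            rec = {"tissue": t, "factor": f}
            rec.update(summary_row(len(s), len(sh_t), len(sh_f)))
            records.append(rec)
        # co-bound: Ubx peaks with an Hth partner in the same tissue
        co, _ = partition(sets[(t, FACTORS[0])], sets[(t, FACTORS[1])], max_dist)
        cobound[t] = co
    for t in TISSUES:
        co = cobound[t]
        co_other = cobound[other_t[t]]
        sh, _ = partition(co, co_other, max_dist)
        records.append(
            {
                "tissue": t,
                "factor": "+".join(FACTORS),
                "total": len(co),
                "pct_other_tissue": _pct(len(sh), len(co)),
                "pct_other_factor": float("nan"),
                "specific_count": len(co) - len(sh),
            }
        )
    return BindingSummary(rows=pd.DataFrame.from_records(records), cobound=cobound)


def venn_counts(
    sets: Sequence[PeakSet],
    max_dist: int = DEFAULT_PARAMS.overlap_center_dist_bp,
) -> dict:
    """Exclusive-region counts of the 2- or 3-way Venn partition.

    Each set is counted from its own side: a peak of set i is assigned to
    the membership pattern of the other sets it overlaps. Because the
    center-distance relation is many-to-many, per-side counts for the same
    nominal Venn region may differ; they are reported separately keyed
    ``(set_index, frozenset(other set indices overlapped))``.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts accepts 2 or 3 peak sets")
    counts: dict[tuple[int, frozenset], int] = {}
    for i, s in enumerate(sets):
        for p in s:
            partners = frozenset(
                j for j, o in enumerate(sets) if j != i and o.has_partner(p, max_dist)
            )
            key = (i, partners)
            counts[key] = counts.get(key, 0) + 1
    return counts
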