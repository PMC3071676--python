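"""Nearest-TSS target assignment and peak location classification.

Each called peak is assigned the gene whose TSS is nearest (either strand)
to the peak center; the gene's strand then orients the signed distance
(negative = upstream of the TSS). Peaks are also classified as promoter
(within 1 kb upstream of a TSS), genic (inside a gene body), or
intergenic, with promoter taking precedence over genic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import DEFAULT_PARAMS


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, TSS and body extent (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError("empty gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class GeneAnnotation:
    """Sorted per-chromosome TSS index over a gene set; one TSS per gene."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id))
        self._tss: dict[str, np.ndarray] = {}
        self._idx: dict[str, list[int]] = {}
        for i, g in enumerate(self.genes):
            self._idx.setdefault(g.chrom, []).append(i)
        for c, idx in self._idx.items():
            self._tss[c] = np.array([self.genes[i].tss for i in idx], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._idx)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [self.genes[i] for i in self._idx.get(chrom, [])]


@dataclass(frozen=True)
class TargetCall:
    peak_id: str
    gene_id: str
    distance: int  # signed; negative = upstream of TSS per gene strand
    feature_class: str  # promoter | genic | intergenic


def nearest_tss(peak_center: int, chrom: str, annotation: GeneAnnotation) -> tuple[GeneModel, int]:
    """Gene with minimal |TSS - center| on either strand, plus signed distance.

    Ties (equidistant TSSs) go to the lower TSS coordinate, then the
    lexically smaller gene id. Sign convention: on the plus strand a
    center left of the TSS is upstream (negative); on the minus strand a
    center right of the TSS is upstream (negative).
    """
    tss = annotation._tss.get(chrom)
    if tss is None or tss.size == 0:
        raise ValueError(f"no genes annotated on chromosome {chrom!r}")
    i = int(np.searchsorted(tss, peak_center))
    # candidates around the insertion point; TSS values may repeat, and the
    # gene list is sorted by (tss, gene_id) so the first hit at the winning
    # |distance| realises the tie-break.
    best = None
    for j in range(max(0, i - 1), min(tss.size, i + 1) + 1):
        if j >= tss.size:
            continue
        d = abs(int(tss[j]) - peak_center)
        key = (d, int(tss[j]))
        if best is None or key < best[0]:
            best = (key, j)
    # expand to all genes sharing the winning (distance, tss) to apply the
    # lexical-id tie-break deterministically
    (dist_abs, tss_win), j = best
    genes = annotation.genes_on(chrom)
    cands = [g for g in genes if g.tss == tss_win]
    gene = min(cands, key=lambda g: g.gene_id)
    signed = (peak_center - gene.tss) if gene.strand == "+" else (gene.tss - peak_center)
    return gene, signed


def classify_location(
    peak_center: int,
    chrom: str,
    annotation: GeneAnnotation,
    promoter_upstream_bp: int = DEFAULT_PARAMS.promoter_upstream_bp,
) -> str:
    """promoter > genic > intergenic, promoter = 1 kb upstream of a TSS in gene orientation."""
    for g in annotation.genes_on(chrom):
        if g.strand == "+":
            if g.tss - promoter_upstream_bp <= peak_center < g.tss:
                return "promoter"
        else:
            if g.tss < peak_center <= g.tss + promoter_upstream_bp:
                return "promoter"
    for g in annotation.genes_on(chrom):
        if g.start <= peak_center < g.end:
            return "genic"
    return "intergenic"


def call_targets(peaks, annotation: GeneAnnotation) -> list[TargetCall]:
    """Assign every peak of a PeakSet to its nearest-TSS gene."""
    calls = []
    for p in peaks:
        gene, d = nearest_tss(p.center, p.chrom, annotation)
        cls = classify_location(p.center, p.chrom, annotation)
        # centers are unique within a PeakSet, so the coordinate is a stable id
        calls.append(TargetCall(f"{p.chrom}:{p.center}", gene.gene_id, d, cls))
    return calls


def target_gene_counts(calls: Sequence[TargetCall]) -> tuple[int, int]:
    """(peak-level call count, deduplicated target-gene count)."""
    return len(calls), len({c.gene_id for c in calls})


def tss_distance_histogram(calls: Sequence[TargetCall], bin_width_bp: int = 500) -> pd.Series:
    """Counts of signed TSS distances in half-open bins aligned to bin_width.

    The bin covering distance d is [k*w, (k+1)*w) with k = floor(d/w);
    bin labels are the left edges. The counts sum to len(calls).
    """
    if not calls:
        raise ValueError("no target calls to histogram")
    d = np.array([c.distance for c in calls])
    left = np.floor_divide(d, bin_width_bp) * bin_width_bp
    vc = pd.Series(left).value_counts().sort_index()
    vc.index.name = "bin_left_bp"
    vc.name = "count"
    return vc


def calls_to_frame(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.peak_id, c.gene_id, c.distance, c.feature_class) for c in calls],
        columns=["peak", "gene", "distance", "class"],
    )
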