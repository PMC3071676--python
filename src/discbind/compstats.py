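"""Co-occupancy significance, signal correlation, and conservation scoring.

Pairwise factor co-occupancy is tested with a one-sided Fisher's exact
test on a universe of merged binding regions; the -log10 p matrix is then
hierarchically clustered (average linkage, Euclidean) to group factors by
binding similarity. Genome-wide similarity of two signal tracks is the
Pearson correlation of 500 bp window means, and per-peak conservation is
the mean score over a 1 kb window centered on the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom, mannwhitneyu, pearsonr

from .intervals import PeakSet
from .params import DEFAULT_PARAMS
from .tracks import IntervalTrack, ProbeTrack

NEG_LOG10_P_CAP = 300.0


@dataclass(frozen=True)
class OverlapTestResult:
    pair: tuple[str, str]
    n_i: int
    n_j: int
    k: int
    N: int
    p: float

    def __post_init__(self) -> None:
        if self.k > min(self.n_i, self.n_j):
            raise ValueError("overlap exceeds a set size")
        if not 0 < self.p <= 1:
            raise ValueError("p outside (0,1]")

    @property
    def neg_log10_p(self) -> float:
        # + 0.0 normalizes the sign of a -0.0 arising from p == 1
        return float(min(max(-np.log10(self.p), 0.0), NEG_LOG10_P_CAP) + 0.0)


def merge_regions(
    sets: list[PeakSet], max_dist: int = DEFAULT_PARAMS.overlap_center_dist_bp
) -> tuple[int, list[set[int]]]:
    """Single-linkage merge of all sets' peak centers under the center rule.

    Returns the number of distinct merged regions N (the Fisher universe)
    and, per merged region, the set of input-set indices with a peak in
    it. Merging the union avoids inflating N when the same event appears
    in several sets.
    """
    events = []  # (chrom, center, set_index)
    for i, s in enumerate(sets):
        for p in s:
            events.append((p.chrom, p.center, i))
    events.sort()
    membership: list[set[int]] = []
    prev = None
    for chrom, center, i in events:
        if prev is None or chrom != prev[0] or center - prev[1] >= max_dist:
            membership.append(set())
        membership[-1].add(i)
        prev = (chrom, center)
    return len(membership), membership


def overlap_fisher(n_i: int, n_j: int, k: int, N: int, pair=("i", "j")) -> OverlapTestResult:
    """One-sided (enrichment) exact test of co-occupancy.

    2x2 table [[k, n_i-k], [n_j-k, N-n_i-n_j+k]]; the one-sided Fisher p
    equals the hypergeometric upper tail P(X >= k | N, n_i, n_j).
    """
    if min(k, n_i - k, n_j - k, N - n_i - n_j + k) < 0:
        raise ValueError(f"inconsistent 2x2 table for pair {pair}")
    p = float(hypergeom.sf(k - 1, N, n_i, n_j))
    return OverlapTestResult(pair=tuple(pair), n_i=n_i, n_j=n_j, k=k, N=N, p=max(p, 1e-323))


def pairwise_overlap_fisher(
    sets: list[PeakSet], max_dist: int = DEFAULT_PARAMS.overlap_center_dist_bp
) -> pd.DataFrame:
    """Matrix of -log10 co-occupancy p-values over all set pairs.

    The universe N is the number of distinct merged regions across all
    input sets; per-set counts and pairwise overlaps are counted on that
    merged-region universe, which keeps every 2x2 table consistent.
    Diagonal entries are the self-pair test (k = n_i).
    """
    if len(sets) < 2:
        raise ValueError("need at least two peak sets")
    N, membership = merge_regions(sets, max_dist)
    labels = ["/".join(map(str, s.label)) if isinstance(s.label, tuple) else str(s.label) for s in sets]
    n = [sum(1 for m in membership if i in m) for i in range(len(sets))]
    mat = np.zeros((len(sets), len(sets)))
    for i in range(len(sets)):
        for j in range(len(sets)):
            k = sum(1 for m in membership if i in m and j in m)
            res = overlap_fisher(n[i], n[j], k, N, pair=(labels[i], labels[j]))
            mat[i, j] = res.neg_log10_p
    return pd.DataFrame(mat, index=labels, columns=labels)


def cluster_significance_matrix(matrix: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage clustering of the -log10 p matrix rows.

    Euclidean distance between rows; returns (leaf labels in dendrogram
    order, scipy linkage matrix). Non-finite entries are rejected — cap
    p-values before clustering.
    """
    vals = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite entries; cap -log10 p before clustering")
    if vals.shape[0] != vals.shape[1] or not np.allclose(vals, vals.T):
        raise ValueError("expected a square symmetric matrix")
    with warnings.catch_warnings():
        # rows of the significance matrix are the observations by design,
        # even though the matrix is square and symmetric
        warnings.simplefilter("ignore")
        Z = linkage(vals, method="average", metric="euclidean")
    order = leaves_list(Z)
    return [matrix.index[i] for i in order], Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch heights."""
    n = len(labels)
    nodes = {i: (labels[i], 0.0) for i in range(n)}
    for idx, (a, b, h, _) in enumerate(Z):
        sa, ha = nodes.pop(int(a))
        sb, hb = nodes.pop(int(b))
        nodes[n + idx] = (f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})", float(h))
    (tree, _), = nodes.values()
    return tree + ";"


def windowed_correlation(
    track_a: ProbeTrack,
    track_b: ProbeTrack,
    window_bp: int = DEFAULT_PARAMS.correlation_window_bp,
) -> float:
    """Pearson correlation of per-window mean signal of two tracks.

    Windows are non-overlapping ``window_bp`` bins of the probe grid
    (step = window). Requires the two tracks to share the probe grid and
    at least 3 windows.
    """
    if not track_a.same_grid(track_b):
        raise ValueError("tracks are on different probe grids")
    means_a, means_b = [], []
    for chrom in track_a.chroms:
        pos, va = track_a[chrom]
        _, vb = track_b[chrom]
        bins = pos // window_bp
        _, inv, counts = np.unique(bins, return_inverse=True, return_counts=True)
        means_a.append(np.bincount(inv, weights=va) / counts)
        means_b.append(np.bincount(inv, weights=vb) / counts)
    a = np.concatenate(means_a) if means_a else np.empty(0)
    b = np.concatenate(means_b) if means_b else np.empty(0)
    if a.size < 3:
        raise ValueError("fewer than 3 windows; cannot correlate")
    return float(pearsonr(a, b)[0])


def conservation_window_mean(
    peaks: PeakSet,
    conservation: IntervalTrack,
    half_bp: int = DEFAULT_PARAMS.conservation_half_bp,
) -> pd.Series:
    """Per-peak mean conservation over [center - half, center + half).

    The mean is over covered bases only; a fully uncovered window yields
    NaN (flagged missing, excluded from downstream tests).
    """
    out = {}
    for i, p in enumerate(peaks):
        lo, hi = p.center - half_bp, p.center + half_bp
        if p.chrom not in conservation:
            out[i] = np.nan
            continue
        starts, ends, vals = conservation[p.chrom]
        j0 = int(np.searchsorted(ends, lo, side="right"))
        j1 = int(np.searchsorted(starts, hi, side="left"))
        covered, weighted = 0, 0.0
        for j in range(j0, j1):
            ov = min(hi, int(ends[j])) - max(lo, int(starts[j]))
            if ov > 0:
                covered += ov
                weighted += ov * float(vals[j])
        out[i] = weighted / covered if covered else np.nan
    return pd.Series(out, name="mean_conservation")


def compare_conservation(means_a: pd.Series, means_b: pd.Series) -> float:
    """One-sided rank-sum p for 'class A more conserved than class B'.

    Missing (NaN) window means are excluded.
    """
    a = means_a.dropna().to_numpy()
    b = means_b.dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("a class has no covered peaks")
    return float(mannwhitneyu(a, b, alternative="greater").pvalue)
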