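"""Dual-threshold consensus peak calling.

Two deliberately simple, interface-compatible caller analogues score the
probe tracks:

* a windowed one-sided Wilcoxon rank-sum caller (``score_tas_like``) that
  tests IP vs input probe values in a centered bandwidth window and is
  thresholded at the top fraction of p-values;
* a windowed trimmed-mean caller (``score_mat_like``) on standardized
  log-ratios, thresholded at a false-discovery rate estimated from a
  sign-flip null.

The contribution this module exists for is the consensus rule: keep
exactly those rank-sum regions whose center lies within 250 bp of an
FDR-passing trimmed-mean region. Consensus output is always a subset of
the rank-sum peaks.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

from .intervals import Peak, PeakSet
from .tracks import ProbeTrack


@dataclass(frozen=True)
class CallerParams:
    bandwidth_bp: int = 500
    top_fraction: float = 0.05
    fdr: float = 0.05
    max_gap_bp: int = 300
    min_probes: int = 4
    trim_fraction: float = 0.1
    consensus_dist_bp: int = 250

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1 or not 0 < self.fdr < 1:
            raise ValueError("top_fraction and fdr must lie in (0,1)")
        if self.bandwidth_bp <= 0 or self.max_gap_bp < 0 or self.min_probes < 1:
            raise ValueError("bad window parameters")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")


@dataclass(frozen=True)
class ScoredRegion:
    chrom: str
    start: int
    end: int
    center: int
    score: float
    pvalue: float
    caller: Literal["tas_like", "mat_like", "consensus"]
    n_probes: int = 0


@functools.lru_cache(maxsize=64)
def rank_sum_null_sf(n1: int, n2: int) -> np.ndarray:
    """Exact null survival function of the Mann-Whitney U statistic.

    ``sf[u] = P(U >= u)`` for samples of sizes (n1, n2) with no ties,
    computed by the classical partition-counting recurrence. Used to map
    every window's U to an exact one-sided p in one vectorised lookup.
    """
    counts = _u_counts(n1, n2)
    total = counts.sum()
    sf = counts[::-1].cumsum()[::-1] / total
    return sf


@functools.lru_cache(maxsize=64)
def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements yielding each U value (no ties)."""
    # recurrence: c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u)
    table: dict[tuple[int, int], np.ndarray] = {}
    for a in range(n1 + 1):
        for b in range(n2 + 1):
            if a == 0 or b == 0:
                table[(a, b)] = np.ones(1, dtype=np.float64)
                continue
            left = table[(a - 1, b)]
            up = table[(a, b - 1)]
            size = a * b + 1
            c = np.zeros(size, dtype=np.float64)
            c[b : b + left.size] += left
            c[: up.size] += up
            table[(a, b)] = c
    return table[(n1, n2)]


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided exact rank-sum p for H1: values of x tend larger than y.

    Midranks are used under ties, with the tie-free null distribution; the
    p is exact in the continuous case.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r = rankdata(np.concatenate([x, y]))
    u = r[: x.size].sum() - x.size * (x.size + 1) / 2
    sf = rank_sum_null_sf(x.size, y.size)
    return float(sf[min(int(math.floor(u)), x.size * y.size)])


def _window_size(params: CallerParams, spacing: int) -> int:
    """Number of probes within +/- bandwidth/2 of a probe (odd, >= 1)."""
    if params.bandwidth_bp <= spacing:
        raise ValueError("bandwidth must exceed probe spacing")
    half = (params.bandwidth_bp // 2) // spacing
    return 2 * half + 1


def score_tas_like(ip: ProbeTrack, inp: ProbeTrack, params: CallerParams) -> ProbeTrack:
    """Per-probe one-sided rank-sum p-values of IP vs input in a centered window.

    Probes whose window holds fewer than ``min_probes`` probes per arm
    (track edges) are recorded with p = 1. A display track in
    -10*log10(p) units is available via :func:`display_track`.
    """
    if not ip.same_grid(inp):
        raise ValueError("IP and input tracks are on different probe grids")
    out = ProbeTrack()
    for chrom in ip.chroms:
        pos, v_ip = ip[chrom]
        _, v_in = inp[chrom]
        n = pos.size
        p = np.ones(n)
        if n >= 2:
            spacing = int(np.min(np.diff(pos)))
            w = min(_window_size(params, spacing), n)
            if w >= params.min_probes:
                wi = sliding_window_view(v_ip, w)
                wn = sliding_window_view(v_in, w)
                both = np.concatenate([wi, wn], axis=1)
                r = rankdata(both, axis=1)
                u = r[:, :w].sum(axis=1) - w * (w + 1) / 2
                sf = rank_sum_null_sf(w, w)
                idx = np.clip(np.floor(u).astype(np.int64), 0, w * w)
                half = (w - 1) // 2
                p[half : half + u.size] = sf[idx]
        out.add(chrom, pos, p)
    return out


def display_track(pvalues: ProbeTrack) -> ProbeTrack:
    """-10*log10(p) display version of a p-value track."""
    return pvalues.map_values(lambda v: -10.0 * np.log10(np.clip(v, 1e-300, None)))


class ScoreFdrMap:
    """Empirical score -> FDR mapping from a sign-flip null.

    ``fdr(s)`` = (# null window scores >= s) / (# observed scores >= s),
    clipped to [0, 1] and monotonized from the top score downwards.
    """

    def __init__(self, observed: np.ndarray, null: np.ndarray):
        self._obs_sorted = np.sort(observed)
        self._null_sorted = np.sort(null)

    def fdr(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        n_obs = self._obs_sorted.size - np.searchsorted(self._obs_sorted, s, side="left")
        n_null = self._null_sorted.size - np.searchsorted(self._null_sorted, s, side="left")
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(n_obs > 0, n_null / np.maximum(n_obs, 1), 1.0)
        return np.clip(q, 0.0, 1.0)

    def threshold(self, alpha: float) -> float:
        """Smallest observed score whose (monotonized) FDR is <= alpha."""
        scores = self._obs_sorted[::-1]  # descending
        q = self.fdr(scores)
        # q-value: best FDR among rejection regions containing each score,
        # i.e. running min over lower thresholds — monotone non-decreasing
        # down the sorted list.
        q = np.minimum.accumulate(q[::-1])[::-1]
        ok = np.nonzero(q <= alpha)[0]
        if ok.size == 0:
            return float("inf")
        return float(scores[ok[-1]])


def score_mat_like(
    ip: ProbeTrack, inp: ProbeTrack, params: CallerParams
) -> tuple[ProbeTrack, ScoreFdrMap]:
    """Windowed trimmed-mean score of standardized log-ratios, plus FDR map.

    The log-ratio (IP - input) is standardized over the whole track; the
    per-probe score is the trimmed mean (``trim_fraction`` per tail) over
    the centered bandwidth window. The null is the same computation on the
    sign-flipped log-ratios.
    """
    if not ip.same_grid(inp):
        raise ValueError("IP and input tracks are on different probe grids")
    all_lr = np.concatenate([ip[c][1] - inp[c][1] for c in ip.chroms]) if ip.chroms else np.empty(0)
    sd = float(np.std(all_lr))
    if all_lr.size and sd == 0.0:
        if np.all(all_lr == 0):
            # all-zero log-ratios score 0 everywhere by convention
            out = ProbeTrack()
            for c in ip.chroms:
                pos, _ = ip[c]
                out.add(c, pos, np.zeros(pos.size))
            return out, ScoreFdrMap(np.zeros(1), np.zeros(1))
        raise ValueError("standardization failed: zero-variance log-ratio track")
    mean = float(np.mean(all_lr)) if all_lr.size else 0.0

    out = ProbeTrack()
    obs_all, null_all = [], []
    for chrom in ip.chroms:
        pos, v_ip = ip[chrom]
        _, v_in = inp[chrom]
        z = ((v_ip - v_in) - mean) / sd if sd else np.zeros(pos.size)
        n = pos.size
        score = np.zeros(n)
        null = np.zeros(n)
        if n >= 2:
            spacing = int(np.min(np.diff(pos)))
            w = min(_window_size(params, spacing), n)
            k = int(math.floor(params.trim_fraction * w))
            half = (w - 1) // 2
            win = np.sort(sliding_window_view(z, w), axis=1)
            core = win[:, k : w - k] if k else win
            tm = core.mean(axis=1)
            score[half : half + tm.size] = tm
            null[half : half + tm.size] = -tm  # sign-flipped null windows
        out.add(chrom, pos, score)
        obs_all.append(score)
        null_all.append(null)
    fdr_map = ScoreFdrMap(np.concatenate(obs_all), np.concatenate(null_all))
    return out, fdr_map


def call_regions(
    track: ProbeTrack,
    threshold_rule: Literal["top_fraction", "fdr"],
    params: CallerParams,
    fdr_map: ScoreFdrMap | None = None,
) -> list[ScoredRegion]:
    """Maximal runs of threshold-passing probes, gap-merged and size-filtered.

    ``top_fraction`` thresholds a p-value track at its own top-5% quantile
    (smallest p-values pass); ``fdr`` thresholds a score track at the
    sign-flip-null FDR level. Runs separated by <= max_gap_bp merge; runs
    with fewer than min_probes probes are dropped. A region's center is
    its best-scoring probe (lowest coordinate on ties).
    """
    values = track.all_values()
    if values.size == 0:
        return []
    if threshold_rule == "top_fraction":
        thr = np.quantile(values, params.top_fraction)
        passes = lambda v: v <= thr
        better = lambda v: -v  # smaller p is better
        caller = "tas_like"
    elif threshold_rule == "fdr":
        if fdr_map is None:
            raise ValueError("fdr rule requires the score->FDR mapping")
        thr = fdr_map.threshold(params.fdr)
        passes = lambda v: v >= thr
        better = lambda v: v
        caller = "mat_like"
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")

    regions: list[ScoredRegion] = []
    for chrom in track.chroms:
        pos, val = track[chrom]
        mask = passes(val)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        # maximal runs of index-adjacent passing probes ...
        runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
        for i in idx[1:]:
            if int(i) == runs[-1][1] + 1:
                runs[-1][1] = int(i)
            else:
                runs.append([int(i), int(i)])
        # ... then merge runs whose bp separation is <= max_gap_bp
        merged: list[list[int]] = [runs[0]]
        for a, b in runs[1:]:
            if pos[a] - pos[merged[-1][1]] <= params.max_gap_bp:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            members = idx[(idx >= a) & (idx <= b)]
            if members.size < params.min_probes:
                continue
            scores = better(val[members])
            # a saturated statistic (e.g. the exact rank-sum p at its floor)
            # produces a plateau of tied best probes; the plateau midpoint
            # is the deterministic center choice that stays on the summit
            tied = members[scores == scores.max()]
            best = tied[(tied.size - 1) // 2]
            regions.append(
                ScoredRegion(
                    chrom=chrom,
                    start=int(pos[a]),
                    end=int(pos[b]) + 1,
                    center=int(pos[best]),
                    score=float(val[best]),
                    pvalue=float(val[best]) if caller == "tas_like" else float("nan"),
                    caller=caller,
                    n_probes=int(members.size),
                )
            )
    return regions


def consensus_peaks(
    tas_regions: list[ScoredRegion],
    mat_regions: list[ScoredRegion],
    params: CallerParams,
    label=("na", "na"),
) -> PeakSet:
    """The dual-threshold consensus: rank-sum regions whose center lies
    within ``consensus_dist_bp`` (inclusive) of a trimmed-mean region.

    Distance is from the rank-sum region's center to the interval of the
    nearest trimmed-mean region (0 if inside); coordinates and center of a
    kept peak come from the rank-sum region.
    """
    mat_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in mat_regions}:
        rs = sorted((r for r in mat_regions if r.chrom == chrom), key=lambda r: r.start)
        mat_by_chrom[chrom] = (
            np.array([r.start for r in rs], dtype=np.int64),
            np.array([r.end for r in rs], dtype=np.int64),
        )
    kept = []
    for r in tas_regions:
        if r.chrom not in mat_by_chrom:
            continue
        starts, ends = mat_by_chrom[r.chrom]
        i = int(np.searchsorted(starts, r.center, side="right"))
        d = np.inf
        for j in (i - 1, i):
            if 0 <= j < starts.size:
                gap = max(int(starts[j]) - r.center, r.center - int(ends[j]), 0)
                d = min(d, gap)
        if d <= params.consensus_dist_bp:
            kept.append(
                Peak(r.chrom, r.start, r.end, r.center, score=r.score, name="consensus")
            )
    return PeakSet(label, kept)
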