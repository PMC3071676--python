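"""Shared analysis parameter registry.

Every numeric threshold used anywhere in the pipeline resolves to exactly
one field of :class:`AnalysisParameters`, so a run log that echoes this
object fully documents the analysis settings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass(frozen=True)
class AnalysisParameters:
    """Single source of truth for pipeline-wide constants.

    Attributes
    ----------
    tas_top_fraction
        Fraction of most-significant probe p-values retained by the
        rank-sum (TAS-like) caller.
    mat_fdr
        False-discovery-rate threshold for the trimmed-mean (MAT-like)
        caller, estimated from a sign-flip null.
    consensus_dist_bp
        Maximum distance (inclusive) from a rank-sum peak center to a
        trimmed-mean peak interval for the dual-threshold consensus call.
    overlap_center_dist_bp
        Two peaks overlap iff their center-to-center distance is strictly
        below this value.
    motif_hit_half_bp
        Half-width around the peak center in which motif hits are counted
        for the percent-of-peaks report.
    motif_scan_half_bp
        Half-width of the sequence window extracted around each peak
        center for motif scanning.
    conservation_half_bp
        Half-width of the window over which conservation scores are
        averaged per peak.
    promoter_upstream_bp
        Extent of the promoter upstream of the TSS for feature
        classification.
    correlation_window_bp
        Window size for genome-wide windowed signal correlation.
    bonferroni_alpha
        Corrected-p threshold for reporting a top enriched term.
    motif_min_cutoff_bits
        Lowest log-odds cutoff (bits) on the cutoff-selection grid.
    seed
        Master seed; every random draw in the pipeline derives from it.
    """

    tas_top_fraction: float = 0.05
    mat_fdr: float = 0.05
    consensus_dist_bp: int = 250
    overlap_center_dist_bp: int = 500
    motif_hit_half_bp: int = 250
    motif_scan_half_bp: int = 500
    conservation_half_bp: int = 500
    promoter_upstream_bp: int = 1000
    correlation_window_bp: int = 500
    bonferroni_alpha: float = 0.001
    motif_min_cutoff_bits: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "consensus_dist_bp",
            "overlap_center_dist_bp",
            "motif_hit_half_bp",
            "motif_scan_half_bp",
            "conservation_half_bp",
            "promoter_upstream_bp",
            "correlation_window_bp",
        ):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("tas_top_fraction", "mat_fdr", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_PARAMS = AnalysisParameters()


def round_percent(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of the summary tables.

    Python's built-in ``round`` is banker's rounding; published percentage
    tables round 0.05 up.
    """
    import math

    q = 10**ndigits
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)
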