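"""Per-probe genomic signal tracks.

A :class:`ProbeTrack` holds, per chromosome, the ordered probe positions
and one value per probe — the in-memory form of a tiling-array log-ratio
or p-value track (bedGraph on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ProbeTrack:
    """Ordered per-chromosome (probe position, value) arrays."""

    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add(self, chrom: str, positions: np.ndarray, values: np.ndarray) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if positions.shape != values.shape:
            raise ValueError("positions and values differ in length")
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        self.data[chrom] = (positions, values)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    def __getitem__(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self.data[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.data

    def n_probes(self) -> int:
        return sum(pos.size for pos, _ in self.data.values())

    def same_grid(self, other: "ProbeTrack") -> bool:
        if set(self.data) != set(other.data):
            return False
        return all(
            np.array_equal(self.data[c][0], other.data[c][0]) for c in self.data
        )

    def map_values(self, fn) -> "ProbeTrack":
        out = ProbeTrack()
        for c, (pos, val) in self.data.items():
            out.add(c, pos, fn(val))
        return out

    def all_values(self) -> np.ndarray:
        if not self.data:
            return np.empty(0)
        return np.concatenate([pv[1] for _, pv in sorted(self.data.items())])


@dataclass
class IntervalTrack:
    """Per-chromosome (start, end, value) intervals, e.g. a conservation track."""

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if not (starts.shape == ends.shape == values.shape):
            raise ValueError("starts/ends/values differ in length")
        if np.any(ends <= starts):
            raise ValueError("empty or inverted interval")
        order = np.argsort(starts, kind="stable")
        self.data[chrom] = (starts[order], ends[order], values[order])

    def __getitem__(self, chrom: str):
        return self.data[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.data
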