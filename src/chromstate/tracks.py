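"""Fixed-width binned coverage tracks.

A :class:`BinnedTrack` holds, per scaffold, one non-negative count (or real
value) per consecutive ``bin_width``-base bin — the resolution at which all
enrichment scoring and chromatin-state work happens (200 bp by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BinnedTrack"]


@dataclass
class BinnedTrack:
    """Per-scaffold vectors of per-bin values for one mark or input sample."""

    data: dict[str, np.ndarray] = field(default_factory=dict)
    bin_width: int = 200

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.data = {k: np.asarray(v) for k, v in self.data.items()}
        for name, v in self.data.items():
            if v.ndim != 1:
                raise ValueError(f"track for {name} must be 1-D")
            if np.any(v < 0):
                raise ValueError(f"negative counts on scaffold {name}")

    @property
    def total_count(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    @property
    def n_bins(self) -> int:
        return int(sum(v.size for v in self.data.values()))

    def scaffolds(self) -> list[str]:
        return sorted(self.data)

    def same_binning(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and set(self.data) == set(other.data)
            and all(self.data[s].size == other.data[s].size for s in self.data)
        )

    def require_same_binning(self, other: "BinnedTrack") -> None:
        if not self.same_binning(other):
            raise ValueError("tracks have mismatched scaffolds or binning")

    def concatenated(self) -> np.ndarray:
        """All scaffold vectors stacked in sorted scaffold order."""
        if not self.data:
            return np.empty(0)
        return np.concatenate([self.data[s] for s in self.scaffolds()])

    def map_bins(self, fn) -> "BinnedTrack":
        return BinnedTrack(
            {s: fn(v) for s, v in self.data.items()}, bin_width=self.bin_width
        )

    def __add__(self, other: "BinnedTrack") -> "BinnedTrack":
        self.require_same_binning(other)
        return BinnedTrack(
            {s: self.data[s] + other.data[s] for s in self.data},
            bin_width=self.bin_width,
        )

    def bin_index(self, scaffold: str, pos: int) -> int:
        return pos // self.bin_width

    def value_at(self, scaffold: str, pos: int) -> float:
        """Value of the bin containing base ``pos``; NaN outside the track."""
        v = self.data.get(scaffold)
        if v is None:
            return float("nan")
        i = pos // self.bin_width
        if pos < 0 or i >= v.size:
            return float("nan")
        return float(v[i])
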