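"""Genome-interval primitives shared by every pipeline stage.

All interval arithmetic in this package uses 0-based, half-open
``[start, end)`` coordinates (the BED convention).  Variant positions are
1-based (the VCF convention).  The *only* place a 1-based position is turned
into an interval is :func:`variant_base`; every overlap test for a variant
goes through it, so the off-by-one convention lives in exactly one function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["GenomicInterval", "variant_base", "merge_peaks", "BaseLookup"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_base(self, chrom: str, pos0: int) -> bool:
        """Whether the single base ``[pos0, pos0+1)`` lies inside this interval."""
        return self.chrom == chrom and self.start <= pos0 < self.end


def variant_base(chrom: str, pos: int) -> GenomicInterval:
    """Convert a 1-based variant position to its single-base interval.

    This is the package's sole 1-based -> 0-based conversion point:
    ``pos`` (1-based) maps to ``[pos - 1, pos)``.
    """
    if pos < 1:
        raise ValueError(f"variant positions are 1-based; got {pos}")
    return GenomicInterval(chrom, pos - 1, pos)


def merge_peaks(
    intervals: Iterable[tuple[GenomicInterval, Optional[float]]],
) -> list[tuple[GenomicInterval, Optional[float]]]:
    """Sort intervals by (chrom, start) and merge overlapping ones.

    Adjacent-but-not-overlapping intervals (end == next start) stay separate,
    consistent with half-open semantics.  When merged intervals carry signal
    values the merged peak keeps the maximum; a merge of scored and unscored
    peaks keeps the score that exists.
    """
    items = sorted(intervals, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    merged: list[tuple[GenomicInterval, Optional[float]]] = []
    for iv, sig in items:
        if merged:
            prev, prev_sig = merged[-1]
            if prev.chrom == iv.chrom and iv.start < prev.end:
                new_end = max(prev.end, iv.end)
                sigs = [s for s in (prev_sig, sig) if s is not None]
                merged[-1] = (
                    GenomicInterval(prev.chrom, prev.start, new_end),
                    max(sigs) if sigs else None,
                )
                continue
        merged.append((iv, sig))
    return merged


class BaseLookup:
    """Vectorised membership test of single bases against sorted, merged intervals.

    Built once per peak track; used heavily by the permutation engine, so
    lookups are numpy ``searchsorted`` calls rather than tree walks.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda i: i.start)
            self._starts[chrom] = np.array([i.start for i in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([i.end for i in ivs], dtype=np.int64)

    def hit(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Boolean array: does base ``[pos0, pos0+1)`` fall inside any interval?"""
        starts = self._starts.get(chrom)
        if starts is None:
            return np.zeros(np.shape(pos0), dtype=bool)
        ends = self._ends[chrom]
        pos0 = np.asarray(pos0, dtype=np.int64)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        return ok & (pos0 < ends[np.clip(idx, 0, None)])
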