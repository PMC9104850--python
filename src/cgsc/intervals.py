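"""Genomic interval primitives: BED-convention intervals, merging,
pairwise intersection and the triple-consensus binding-site operation.

Intervals follow the BED convention: 0-based, half-open [start, end).
The consensus operation reproduces an intersect-intervals workflow: the
maximal set of intervals covered by at least one peak from each of the
three input collections, computed as ((O n S) n N) with sweep-line
interval semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Anchor reference point: floor of (start + end) / 2."""
        return (self.start + self.end) // 2


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of maximal non-overlapping
    intervals (touching intervals are merged)."""
    out: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        ivs = sorted(_by_chrom(intervals)[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of the genomic regions covered by ``a`` and ``b``.

    Inputs are merged first, so overlapping intervals within one set do
    not produce duplicate output; the result is sorted, non-overlapping.
    """
    a_merged = _by_chrom(merge_intervals(a))
    b_merged = _by_chrom(merge_intervals(b))
    out: list[GenomicInterval] = []
    for chrom in sorted(set(a_merged) & set(b_merged)):
        xs, ys = a_merged[chrom], b_merged[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            start = max(xs[i].start, ys[j].start)
            end = min(xs[i].end, ys[j].end)
            if start < end:
                out.append(GenomicInterval(chrom, start, end))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def consensus_binding_sites(
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
    peaks_c: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Triple-consensus binding sites: the regions covered by at least
    one peak from each of the three collections."""
    return intersect_intervals(intersect_intervals(peaks_a, peaks_b), peaks_c)


def total_covered_length(intervals: Sequence[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_intervals(intervals))
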