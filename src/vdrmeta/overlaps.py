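"""Pairwise peak-set comparison and cell-type specificity counting.

Two peaks are considered to be at the same location when more than 50%
(configurable) of the narrower peak is covered by the wider peak. Overlap
percentages are reported in reference to the set with fewer peaks, and
symmetrically from the larger set's side.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from intervaltree import IntervalTree

from .io import PeakCall, SampleSet

__all__ = [
    "OverlapResult",
    "PartitionCounts",
    "CategoryCounts",
    "peaks_overlap",
    "pairwise_overlap_stats",
    "percentage",
    "stim_unstim_partition",
    "specificity_categories",
]


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_common: int
    pct_smaller: float
    pct_larger: float


@dataclass(frozen=True)
class PartitionCounts:
    unique_stim: int
    unique_unstim: int
    common: int

    @property
    def total(self) -> int:
        return self.unique_stim + self.unique_unstim + self.common


@dataclass(frozen=True)
class CategoryCounts:
    """Histogram of consensus peaks by the number of cell types sharing them."""

    counts: dict

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def percentage(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be between 0 and denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def peaks_overlap(a: PeakCall, b: PeakCall, fraction: float = 0.5) -> bool:
    """True when more than ``fraction`` of the narrower peak overlaps the wider.

    Peaks on different chromosomes never overlap; equal widths treat ``a``
    as the narrower peak (the outcome is identical either way). The
    comparison is strict: exactly 50% coverage does not qualify.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ov = a.interval.overlap_width(b.interval)
    if ov <= 0:
        return False
    narrower = min(a.interval.width(), b.interval.width())
    return ov > fraction * narrower


def _peak_list(peaks) -> list[PeakCall]:
    return list(peaks.peaks) if isinstance(peaks, SampleSet) else list(peaks)


def _trees_by_chrom(peaks: Sequence[PeakCall]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, i
        )
    return trees


def _n_with_partner(
    query: Sequence[PeakCall], target: Sequence[PeakCall], fraction: float
) -> int:
    trees = _trees_by_chrom(target)
    n = 0
    for p in query:
        tree = trees.get(p.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.interval.start, p.interval.end):
            if peaks_overlap(p, target[hit.data], fraction):
                n += 1
                break
    return n


def pairwise_overlap_stats(A, B, fraction: float = 0.5) -> OverlapResult:
    """Overlap statistics between two peak sets.

    ``n_common`` is the number of peaks of the smaller set with at least
    one qualifying partner in the larger set; ``pct_smaller`` references
    the smaller set, ``pct_larger`` the larger (counting its peaks with a
    partner in the smaller set). Ties in size treat A as the smaller set.
    """
    a, b = _peak_list(A), _peak_list(B)
    if not a or not b:
        raise ValueError("both peak sets must be non-empty")
    smaller, larger = (a, b) if len(a) <= len(b) else (b, a)
    n_common = _n_with_partner(smaller, larger, fraction)
    n_larger_with_partner = _n_with_partner(larger, smaller, fraction)
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_common=n_common,
        pct_smaller=percentage(n_common, len(smaller)),
        pct_larger=percentage(n_larger_with_partner, len(larger)),
    )


def stim_unstim_partition(stim, unstim, fraction: float = 0.5) -> PartitionCounts:
    """Partition stimulated/unstimulated peaks into unique and common loci.

    A qualifying stim/unstim peak pair defines one common locus; each peak
    participates in at most one locus, matched 1:1 greedily in genomic
    order. Inputs are expected to be pre-filtered to the FDR presence
    criterion (-log10 q > 2).
    """
    stim_peaks = sorted(
        _peak_list(stim), key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    )
    unstim_peaks = sorted(
        _peak_list(unstim), key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    )
    trees = _trees_by_chrom(unstim_peaks)
    matched: set[int] = set()
    common = 0
    for p in stim_peaks:
        tree = trees.get(p.interval.chrom)
        if tree is None:
            continue
        partners = sorted(
            hit.data
            for hit in tree.overlap(p.interval.start, p.interval.end)
            if hit.data not in matched and peaks_overlap(p, unstim_peaks[hit.data], fraction)
        )
        if partners:
            matched.add(partners[0])
            common += 1
    return PartitionCounts(
        unique_stim=len(stim_peaks) - common,
        unique_unstim=len(unstim_peaks) - common,
        common=common,
    )


def specificity_categories(consensus, K: int) -> CategoryCounts:
    """Histogram of ``n_cell_types`` over 1..K for consensus peaks."""
    counts = {k: 0 for k in range(1, K + 1)}
    for cp in consensus:
        if cp.n_cell_types not in counts:
            raise ValueError(
                f"n_cell_types {cp.n_cell_types} outside 1..{K} "
                f"at {cp.interval.chrom}:{cp.summit}"
            )
        counts[cp.n_cell_types] += 1
    return CategoryCounts(counts=counts)
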