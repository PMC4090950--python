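"""Genomic interval primitives: coordinate conventions, set algebra, occupancy
densities, and local-background sampling.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers basepairs ``start .. end-1``. Overlap is computed
strand-agnostically throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Annotation",
    "GenomeLayout",
    "IntervalError",
    "BackgroundSamplingError",
    "merge_intervals",
    "total_length",
    "intersect_total",
    "occupied_fraction",
    "count_density",
    "sample_background",
    "normalized_local_enrichment",
]


class IntervalError(ValueError):
    """Malformed interval or inconsistent interval/layout input."""


class BackgroundSamplingError(RuntimeError):
    """No valid background placement exists for a locus."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise IntervalError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise IntervalError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        """Half-open containment: start <= pos < end."""
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Annotation:
    """A labeled genomic feature, e.g. one RepeatMasker repeat or one gene."""

    interval: GenomicInterval
    family: str
    id: str

    def __post_init__(self) -> None:
        if not self.family:
            raise IntervalError(f"annotation {self.id!r} has empty family label")


@dataclass
class GenomeLayout:
    """Chromosome name -> length (bp) mapping shared by all analysis stages."""

    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise IntervalError(f"chromosome {name!r} has non-positive length")

    @property
    def total_length(self) -> int:
        return sum(self.sizes.values())

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def validate(self, intervals: Iterable[GenomicInterval]) -> None:
        """Check every interval fits on a known chromosome."""
        for iv in intervals:
            if iv.chrom not in self.sizes:
                raise IntervalError(f"unknown chromosome {iv.chrom!r}")
            if iv.end > self.sizes[iv.chrom]:
                raise IntervalError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {self.sizes[iv.chrom]}"
                )


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals.

    Adjacent intervals ([0,5), [5,10)) are merged; the result covers exactly
    the union of input basepairs. Idempotent and order-invariant.
    """
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        ivs = sorted(_by_chrom(intervals)[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


def intersect_total(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    """Total bp shared between the unions of two interval sets."""
    am = _by_chrom(merge_intervals(a))
    bm = _by_chrom(merge_intervals(b))
    total = 0
    for chrom in set(am) & set(bm):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if hi > lo:
                total += hi - lo
            if xs[i].end < ys[j].end:
                i += 1
            else:
                j += 1
    return total


def occupied_fraction(
    regions: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> float:
    """Fraction of region basepairs occupied by features.

    Both sets are merged first; features overlapping a region boundary
    contribute only their overlapping basepairs, so the result is in [0, 1].
    """
    merged_regions = merge_intervals(regions)
    denom = total_length(merged_regions)
    if denom == 0:
        raise IntervalError("occupied_fraction requires non-empty regions")
    if not features:
        return 0.0
    return intersect_total(merged_regions, features) / denom


def count_density(
    regions: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> float:
    """Features overlapping the regions (>=1 bp, each counted once) per region bp."""
    merged_regions = merge_intervals(regions)
    denom = total_length(merged_regions)
    if denom == 0:
        raise IntervalError("count_density requires non-empty regions")
    by_chrom = _by_chrom(merged_regions)
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in by_chrom.items()}
    ends = {c: np.array([iv.end for iv in ivs]) for c, ivs in by_chrom.items()}
    n = 0
    for f in features:
        if f.chrom not in starts:
            continue
        # merged regions are disjoint & sorted: overlap iff some start < f.end
        # and the corresponding end > f.start
        i = int(np.searchsorted(ends[f.chrom], f.start, side="right"))
        if i < len(starts[f.chrom]) and starts[f.chrom][i] < f.end:
            n += 1
    return n / denom


def sample_background(
    locus: GenomicInterval,
    layout: GenomeLayout,
    offset_bp: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> GenomicInterval:
    """Draw a same-length local-background window for a locus.

    The window start is uniform over the downstream envelope
    ``[locus.end + offset_bp, locus.end + 2*offset_bp - length]``; when that
    envelope runs off the chromosome the placement mirrors upstream of
    ``locus.start``. Deterministic given an integer seed or Generator.

    Raises
    ------
    BackgroundSamplingError
        If the chromosome is too short for either placement.
    """
    rng = np.random.default_rng(rng)
    if locus.chrom not in layout:
        raise IntervalError(f"unknown chromosome {locus.chrom!r}")
    clen = layout[locus.chrom]
    length = locus.length

    down_lo = locus.end + offset_bp
    down_hi = locus.end + 2 * offset_bp - length  # inclusive latest start
    if down_hi >= down_lo and down_hi + length <= clen:
        start = int(rng.integers(down_lo, down_hi + 1))
        return GenomicInterval(locus.chrom, start, start + length)

    up_lo = locus.start - 2 * offset_bp
    up_hi = locus.start - offset_bp - length
    if up_hi >= up_lo and up_lo >= 0:
        start = int(rng.integers(up_lo, up_hi + 1))
        return GenomicInterval(locus.chrom, start, start + length)

    raise BackgroundSamplingError(
        f"no background placement for {locus.chrom}:{locus.start}-{locus.end} "
        f"(chromosome length {clen}, offset {offset_bp})"
    )


def normalized_local_enrichment(
    regions: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    layout: GenomeLayout,
    rng: np.random.Generator | int | None = None,
    offset_bp: int = 100_000,
    n_backgrounds: int = 1,
    zero_background: str = "raise",
) -> float:
    """Feature density in regions over density in locally sampled backgrounds.

    Density is bp occupancy (:func:`occupied_fraction`). One background window
    (or ``n_backgrounds``) is sampled per region ~``offset_bp`` downstream;
    loci with no valid placement are skipped with a warning. A fold of 1
    signals no local enrichment. ``zero_background`` chooses between raising
    and returning ``inf`` when the background density is zero.
    """
    rng = np.random.default_rng(rng)
    if zero_background not in ("raise", "inf"):
        raise ValueError("zero_background must be 'raise' or 'inf'")
    region_density = occupied_fraction(regions, features)
    backgrounds: list[GenomicInterval] = []
    skipped = 0
    for region in regions:
        for _ in range(n_backgrounds):
            try:
                backgrounds.append(sample_background(region, layout, offset_bp, rng))
            except BackgroundSamplingError:
                skipped += 1
    if skipped:
        logger.warning("skipped %d background placements (chromosome too short)", skipped)
    if not backgrounds:
        raise BackgroundSamplingError("no background window could be placed")
    background_density = occupied_fraction(backgrounds, features)
    if background_density == 0.0:
        if zero_background == "raise":
            raise ZeroDivisionError(
                "background feature density is zero; enrichment fold undefined "
                "(set zero_background='inf' for a sentinel)"
            )
        return float("inf")
    return region_density / background_density
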