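"""Classification of repeats relative to chromatin-predicted enhancers.

An enhancer is anchored at a single predicted core basepair; its span is the
±4 kb region around the anchor and its core the central 200 bp. A repeat that
contains an anchor provides the enhancer core itself (a *repeat-enhancer*,
label ``MIR_ENHANCER`` for the repeat family of interest); a repeat merely
overlapping a span is *enhancer-linked* (``ENHANCER_MIR``); everything else
is ``NON_ENHANCER_MIR``. Observed counts are compared to analytic or
simulated expectations with a one-cell chi-square statistic (O−E)²/E on 1 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import Annotation, GenomeLayout, GenomicInterval, IntervalError, merge_intervals, total_length

logger = logging.getLogger(__name__)

__all__ = [
    "Enhancer",
    "MirClass",
    "EnrichmentReport",
    "MIR_ENHANCER",
    "ENHANCER_MIR",
    "NON_ENHANCER_MIR",
    "classify_repeats",
    "expected_core_count",
    "expected_enhancers_with_repeats",
    "enhancers_with_feature",
    "one_cell_chi_sq",
]

MIR_ENHANCER = "MIR_ENHANCER"
ENHANCER_MIR = "ENHANCER_MIR"
NON_ENHANCER_MIR = "NON_ENHANCER_MIR"

HALF_SPAN = 4_000
HALF_CORE = 100


@dataclass(frozen=True)
class Enhancer:
    """An enhancer anchored at one basepair, with derived span and core windows."""

    id: str
    chrom: str
    anchor: int
    span: GenomicInterval
    core200: GenomicInterval
    clipped: bool = False

    @classmethod
    def from_anchor(
        cls,
        chrom: str,
        anchor: int,
        id: str | None = None,
        layout: GenomeLayout | None = None,
        half_span: int = HALF_SPAN,
        half_core: int = HALF_CORE,
    ) -> "Enhancer":
        """Build an enhancer from its anchor, clipping the span at chromosome
        ends when a layout is supplied (clipping is recorded and logged)."""
        span_start, span_end = anchor - half_span, anchor + half_span
        core_start, core_end = anchor - half_core, anchor + half_core
        clipped = False
        if layout is not None:
            clen = layout[chrom]
            if span_start < 0 or span_end > clen:
                clipped = True
            span_start, span_end = max(0, span_start), min(clen, span_end)
            core_start, core_end = max(0, core_start), min(clen, core_end)
        elif span_start < 0:
            clipped = True
            span_start = max(0, span_start)
            core_start = max(0, core_start)
        if clipped:
            logger.debug("enhancer %s span clipped at chromosome end", id)
        return cls(
            id=id or f"enh_{chrom}_{anchor}",
            chrom=chrom,
            anchor=anchor,
            span=GenomicInterval(chrom, span_start, span_end),
            core200=GenomicInterval(chrom, core_start, core_end),
            clipped=clipped,
        )


@dataclass
class MirClass:
    """Classification of one repeat relative to the enhancer set."""

    annotation_id: str
    label: str
    linked_enhancers: list[str] = field(default_factory=list)


@dataclass
class EnrichmentReport:
    """Observed vs expected count with a one-cell chi-square statistic."""

    observed: float
    expected: float
    chi_sq: float
    p_value: float
    method: str = "analytic"

    def summary(self) -> str:
        return (
            f"observed={self.observed:g} expected={self.expected:g} "
            f"chi_sq={self.chi_sq:.1f} p={self.p_value:.3g} ({self.method})"
        )


def build_enhancers(
    anchors: Sequence[tuple[str, int]],
    layout: GenomeLayout | None = None,
    half_span: int = HALF_SPAN,
    half_core: int = HALF_CORE,
) -> list[Enhancer]:
    """Vector of :class:`Enhancer` from (chrom, anchor) pairs."""
    return [
        Enhancer.from_anchor(c, a, id=f"enh{i:06d}", layout=layout,
                             half_span=half_span, half_core=half_core)
        for i, (c, a) in enumerate(anchors)
    ]


def classify_repeats(
    enhancers: Sequence[Enhancer], repeats: Sequence[Annotation]
) -> list[MirClass]:
    """Label every repeat exactly once.

    A repeat containing any enhancer anchor (half-open: start <= anchor < end)
    is ``MIR_ENHANCER``; otherwise >=1 bp overlap with any span makes it
    ``ENHANCER_MIR``; otherwise ``NON_ENHANCER_MIR``. Linked enhancer ids are
    de-duplicated; a repeat overlapping several spans is still counted once.
    """
    by_chrom: dict[str, dict] = {}
    for e in enhancers:
        d = by_chrom.setdefault(e.chrom, {"anchors": [], "spans": []})
        d["anchors"].append((e.anchor, e.id))
        d["spans"].append((e.span.start, e.span.end, e.id))
    for d in by_chrom.values():
        d["anchors"].sort()
        d["anchor_pos"] = np.array([a for a, _ in d["anchors"]], dtype=np.int64)
        d["spans"].sort()
        d["span_starts"] = np.array([s for s, _, _ in d["spans"]], dtype=np.int64)
        d["max_span_len"] = max((e - s) for s, e, _ in d["spans"])

    out: list[MirClass] = []
    for rep in repeats:
        iv = rep.interval
        d = by_chrom.get(iv.chrom)
        if d is None:
            out.append(MirClass(rep.id, NON_ENHANCER_MIR))
            continue
        lo = int(np.searchsorted(d["anchor_pos"], iv.start, side="left"))
        hi = int(np.searchsorted(d["anchor_pos"], iv.end - 1, side="right"))
        if hi > lo:
            linked = sorted({d["anchors"][k][1] for k in range(lo, hi)})
            out.append(MirClass(rep.id, MIR_ENHANCER, linked))
            continue
        lo = int(np.searchsorted(d["span_starts"], iv.start - d["max_span_len"], side="left"))
        hi = int(np.searchsorted(d["span_starts"], iv.end, side="left"))
        linked = sorted(
            {eid for s, e, eid in d["spans"][lo:hi] if e > iv.start and s < iv.end}
        )
        if linked:
            out.append(MirClass(rep.id, ENHANCER_MIR, linked))
        else:
            out.append(MirClass(rep.id, NON_ENHANCER_MIR))
    return out


def expected_core_count(
    enhancers: Sequence[Enhancer],
    repeats: Sequence[Annotation],
    layout: GenomeLayout,
) -> float:
    """Expected repeat-enhancer count if anchors were uniform over the genome:
    genome-wide enhancer density (enhancers/bp) times the merged repeat bp."""
    genome = layout.total_length
    if genome <= 0:
        raise IntervalError("layout has zero total length")
    if not repeats:
        return 0.0
    repeat_bp = total_length(merge_intervals([r.interval for r in repeats]))
    return len(enhancers) / genome * repeat_bp


def enhancers_with_feature(
    enhancers: Sequence[Enhancer], features: Sequence[GenomicInterval]
) -> int:
    """Number of enhancers whose span is overlapped by >=1 feature (each
    enhancer counted once, however many features hit it)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    prepared = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts = np.array([s for s, _ in pairs], dtype=np.int64)
        ends = np.array([e for _, e in pairs], dtype=np.int64)
        prepared[chrom] = (starts, np.maximum.accumulate(ends))
    n = 0
    for e in enhancers:
        if e.chrom not in prepared:
            continue
        starts, maxends = prepared[e.chrom]
        # features with start < span.end; any of those ending past span.start?
        hi = int(np.searchsorted(starts, e.span.end, side="left"))
        if hi > 0 and maxends[hi - 1] > e.span.start:
            n += 1
    return n


def expected_enhancers_with_repeats(
    enhancers: Sequence[Enhancer],
    repeats: Sequence[Annotation],
    layout: GenomeLayout,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    return_replicates: bool = False,
):
    """Simulated expectation: random sites matching the repeats in number and
    length are placed uniformly (chromosome weighted by length, sites may
    overlap each other) and the enhancers overlapped by >=1 site are counted;
    the mean over ``n_reps`` replicates is returned."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng)
    if not repeats:
        zeros = np.zeros(n_reps)
        return (0.0, zeros) if return_replicates else 0.0
    lengths = np.array([r.interval.length for r in repeats], dtype=np.int64)
    chroms = layout.chroms
    clens = np.array([layout[c] for c in chroms], dtype=np.int64)
    if lengths.max() > clens.max():
        raise IntervalError("a repeat is longer than every chromosome")
    weights = clens / clens.sum()

    counts = np.empty(n_reps)
    for rep_i in range(n_reps):
        chrom_idx = rng.choice(len(chroms), size=lengths.size, p=weights)
        # redraw sites that do not fit their chromosome
        for _ in range(100):
            bad = lengths > clens[chrom_idx]
            if not bad.any():
                break
            chrom_idx[bad] = rng.choice(len(chroms), size=int(bad.sum()), p=weights)
        starts = (rng.random(lengths.size) * (clens[chrom_idx] - lengths + 1)).astype(np.int64)
        sites = [
            GenomicInterval(chroms[ci], int(s), int(s + L))
            for ci, s, L in zip(chrom_idx, starts, lengths)
        ]
        counts[rep_i] = enhancers_with_feature(enhancers, sites)
    mean = float(counts.mean())
    return (mean, counts) if return_replicates else mean


def one_cell_chi_sq(observed: float, expected: float, method: str = "analytic") -> EnrichmentReport:
    """One-cell chi-square: (O−E)²/E referred to chi-square with 1 df (upper tail)."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    chi = (observed - expected) ** 2 / expected
    # extreme statistics underflow the survival function; report the smallest
    # positive normal float rather than 0 so p stays in (0, 1]
    p = max(float(stats.chi2.sf(chi, df=1)), float(np.finfo(float).tiny))
    return EnrichmentReport(observed=float(observed), expected=float(expected),
                            chi_sq=float(chi), p_value=p, method=method)
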