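"""Seeded synthetic genomes with the statistical structure the analyses assume.

The generator emulates four features of real enhancer/repeat data so every
pipeline stage can be exercised and calibrated without downloads:

* repeats planted at an elevated density (configurable fold f) inside
  enhancer spans, placed without mutual overlap the way RepeatMasker-style
  annotations are;
* enhancer-centered unimodal tag bumps for active chromatin marks and a
  multiplicative dip for a repressive mark, with Poisson tag sampling;
* a motif string planted at a higher per-sequence rate in enhancer-associated
  repeat sequences than elsewhere;
* a genes-by-tissues expression matrix whose tissue-specificity is coupled,
  with configurable strength beta, to local enhancer-repeat density via a
  Dirichlet concentration that decreases with density.

All outputs are pure functions of the configuration (byte-identical per seed).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import classify as _classify
from .expression import gene_feature_density
from .intervals import Annotation, GenomeLayout, GenomicInterval, merge_intervals, total_length
from .profiles import SignalTrack

__all__ = [
    "SyntheticConfig",
    "generate_annotations",
    "generate_tracks",
    "generate_expression",
    "generate_sequences",
    "generate_background_pool",
    "generate_all",
    "SimulatedDataset",
    "expected_profile_fold",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    The default toy genome (2 chromosomes x 5 Mb, 200 enhancers, 5,000
    repeats, 500 genes, 6 tissues) is sized so the full pipeline runs in
    well under two minutes on one CPU.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_enhancers: int = 200
    min_anchor_spacing: int = 8_000
    n_repeats: int = 5_000
    repeat_length_median: int = 350
    repeat_length_sigma: float = 0.4
    repeat_family: str = "MIR"
    enhancer_repeat_fold: float = 3.0  # planted density ratio inside spans
    active_marks: dict = field(default_factory=lambda: {"H3K4me1": 5.0, "H3K27ac": 4.0})
    repressive_marks: dict = field(default_factory=lambda: {"H3K27me3": 0.2})
    bump_sigma: float = 1_000.0
    tag_depth: int = 1_000_000  # background tags per mark
    n_genes: int = 500
    gene_length_median: int = 15_000
    gene_length_sigma: float = 0.4
    n_tissues: int = 6
    ts_density_beta: float = 0.8
    tissue_concentration: float = 5.0  # Dirichlet concentration at zero density
    expression_scale: float = 100.0
    motif: str = "TGACTCA"  # AP-1/C-JUN consensus
    motif_plant_rate_target: float = 0.5
    motif_plant_rate_background: float = 0.05
    gc_content: float = 0.41

    def __post_init__(self) -> None:
        if self.enhancer_repeat_fold < 1:
            raise ValueError("enhancer_repeat_fold must be >= 1")
        for name, value in (
            ("motif_plant_rate_target", self.motif_plant_rate_target),
            ("motif_plant_rate_background", self.motif_plant_rate_background),
            ("gc_content", self.gc_content),
        ):
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_chroms, self.n_enhancers, self.n_repeats, self.n_genes) < 0:
            raise ValueError("counts must be non-negative")

    def layout(self) -> GenomeLayout:
        return GenomeLayout({f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)})


def _allocate(rng: np.random.Generator, n: int, weights: np.ndarray) -> np.ndarray:
    return rng.multinomial(n, weights / weights.sum())


def _spaced_positions(
    rng: np.random.Generator, k: int, low: int, high: int, spacing: int
) -> np.ndarray:
    """k sorted positions in [low, high) with pairwise gaps >= spacing."""
    if k == 0:
        return np.array([], dtype=np.int64)
    effective = (high - low) - (k - 1) * spacing
    if effective <= 0:
        raise ValueError(
            f"infeasible packing: {k} features with spacing {spacing} "
            f"do not fit in {high - low} bp"
        )
    u = np.sort(rng.integers(0, effective, size=k))
    return low + u + np.arange(k) * spacing


class _NonOverlapPlacer:
    """Incremental non-overlapping interval placement on one chromosome."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def try_place(self, start: int, end: int) -> bool:
        i = bisect.bisect_right(self.ends, start)
        if i < len(self.starts) and self.starts[i] < end:
            return False
        self.starts.insert(i, start)
        self.ends.insert(i, end)
        return True


def _sample_in_intervals(
    rng: np.random.Generator, intervals: list[tuple[str, int, int]], n: int
) -> list[tuple[str, int]]:
    """n positions uniform over the union bp of (chrom, start, end) intervals."""
    lengths = np.array([e - s for _, s, e in intervals], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    offsets = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, offsets, side="right") - 1
    return [
        (intervals[i][0], int(intervals[i][1] + offsets[j] - cum[i]))
        for j, i in enumerate(idx)
    ]


def generate_annotations(
    config: SyntheticConfig, rng: np.random.Generator | int | None = None
):
    """Genome layout, enhancers, repeats and genes for the configured conditions.

    Enhancer anchors are uniform with a minimum spacing (default 8 kb, so
    spans never overlap) and stay half a span away from chromosome ends.
    Repeat midpoints are placed with probability density proportional to the
    configured fold inside enhancer spans and 1 outside, lengths log-normal,
    and repeats never overlap one another (rejected placements are resampled).
    Genes are non-overlapping with log-normal lengths.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    layout = config.layout()
    chroms = layout.chroms
    clens = np.array([layout[c] for c in chroms], dtype=np.int64)

    # --- enhancers -------------------------------------------------------
    half_span = _classify.HALF_SPAN
    alloc = _allocate(rng, config.n_enhancers, clens.astype(float))
    anchors: list[tuple[str, int]] = []
    for chrom, clen, k in zip(chroms, clens, alloc):
        pos = _spaced_positions(rng, int(k), half_span, int(clen) - half_span,
                                config.min_anchor_spacing)
        anchors.extend((chrom, int(p)) for p in pos)
    enhancers = _classify.build_enhancers(anchors, layout)

    # --- repeats ---------------------------------------------------------
    span_ivs = merge_intervals([e.span for e in enhancers]) if enhancers else []
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for iv in span_ivs:
        spans_by_chrom[iv.chrom].append((iv.start, iv.end))
    inside = [(iv.chrom, iv.start, iv.end) for iv in span_ivs]
    outside: list[tuple[str, int, int]] = []
    for chrom, clen in zip(chroms, clens):
        prev = 0
        for s, e in spans_by_chrom[chrom]:
            if s > prev:
                outside.append((chrom, prev, s))
            prev = e
        if prev < clen:
            outside.append((chrom, prev, int(clen)))

    S = sum(e - s for _, s, e in inside)
    T = int(clens.sum())
    f = config.enhancer_repeat_fold
    inside_frac = f * S / (f * S + (T - S)) if S else 0.0

    lengths = np.maximum(
        30,
        np.round(
            rng.lognormal(math.log(config.repeat_length_median),
                          config.repeat_length_sigma, size=config.n_repeats)
        ).astype(np.int64),
    )
    is_inside = rng.random(config.n_repeats) < inside_frac

    placers = {c: _NonOverlapPlacer() for c in chroms}
    clen_of = dict(zip(chroms, (int(c) for c in clens)))
    placed: list[tuple[str, int, int]] = [None] * config.n_repeats  # type: ignore
    pending = list(range(config.n_repeats))
    for _round in range(200):
        if not pending:
            break
        n_in = sum(1 for i in pending if is_inside[i])
        mids_in = iter(_sample_in_intervals(rng, inside, n_in) if n_in else [])
        mids_out = iter(
            _sample_in_intervals(rng, outside, len(pending) - n_in)
            if len(pending) - n_in
            else []
        )
        still: list[int] = []
        for i in pending:
            chrom, mid = next(mids_in) if is_inside[i] else next(mids_out)
            L = int(lengths[i])
            start = min(max(0, mid - L // 2), clen_of[chrom] - L)
            if placers[chrom].try_place(start, start + L):
                placed[i] = (chrom, start, start + L)
            else:
                still.append(i)
        pending = still
    if pending:
        raise RuntimeError(
            f"could not place {len(pending)} repeats without overlap; "
            "reduce n_repeats or repeat lengths"
        )
    repeats = [
        Annotation(GenomicInterval(c, s, e), config.repeat_family, f"r{i:06d}")
        for i, (c, s, e) in enumerate(placed)
    ]

    # --- genes -----------------------------------------------------------
    gene_alloc = _allocate(rng, config.n_genes, clens.astype(float))
    genes: list[Annotation] = []
    gi = 0
    for chrom, clen, k in zip(chroms, clens, gene_alloc):
        k = int(k)
        if k == 0:
            continue
        glens = np.maximum(
            500,
            np.round(
                rng.lognormal(math.log(config.gene_length_median),
                              config.gene_length_sigma, size=k)
            ).astype(np.int64),
        )
        gap = 2_000
        budget = int(clen) - int(glens.sum()) - (k - 1) * gap - 2_000
        if budget <= 0:
            raise ValueError("infeasible packing: genes do not fit the chromosome")
        u = np.sort(rng.integers(0, budget, size=k))
        cursor = np.concatenate([[0], np.cumsum(glens[:-1] + gap)])
        starts = 1_000 + u + cursor
        for s, L in zip(starts, glens):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Annotation(GenomicInterval(chrom, int(s), int(s + L), strand),
                           "gene", f"g{gi:05d}")
            )
            gi += 1
    return layout, enhancers, repeats, genes


def _bump_amplitude(height: float, c: float) -> float:
    """Gaussian amplitude such that the peak fold AFTER genome-average
    normalization equals ``height`` (c = n_anchors*sqrt(2pi)*sigma/G, the
    surplus share of the total tag count per unit amplitude)."""
    if height <= 1.0:
        return 0.0
    if height * c >= 1.0:
        raise ValueError("bump height infeasible for this genome/anchor density")
    return (height - 1.0) / (1.0 - height * c)


def _dip_depth(depth: float, c: float) -> float:
    """Multiplier u in rate = r0*(1 - u*gauss) giving a post-normalization
    central fold of ``depth``."""
    if depth >= 1.0:
        return 0.0
    return (1.0 - depth) / (1.0 - depth * c)


def generate_tracks(
    config: SyntheticConfig,
    layout: GenomeLayout,
    enhancers: Sequence,
    rng: np.random.Generator | int | None = None,
    repressive_deleted: Sequence[GenomicInterval] = (),
) -> dict[str, SignalTrack]:
    """Per-mark tag tracks: uniform Poisson background plus anchor-centered
    Gaussian surpluses (active marks) or multiplicative dips (repressive).

    Configured heights/depths are fold enrichments on the metaprofile scale,
    i.e. relative to the genome-average tag rate of the finished track; the
    Gaussian amplitude is solved accordingly. Heights <= 1 give a flat track.

    ``repressive_deleted`` intervals model the broad loss of the repressive
    mark around repeat-derived enhancers: within them repressive-mark tags
    are thinned uniformly to the depletion depth (a flat deletion rather
    than a centered dip), so profile congruence with canonical enhancers is
    destroyed for that mark, as observed for repressive chromatin at
    repeat-hosted enhancers.
    """
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    chroms = layout.chroms
    G = layout.total_length
    sigma = config.bump_sigma
    anchors_by_chrom = {c: np.array(sorted(e.anchor for e in enhancers if e.chrom == c),
                                    dtype=np.int64) for c in chroms}
    n_anchors = sum(len(v) for v in anchors_by_chrom.values())
    c_share = n_anchors * math.sqrt(2 * math.pi) * sigma / G
    r0 = config.tag_depth / G

    tracks: dict[str, SignalTrack] = {}
    for mark, height in config.active_marks.items():
        amp = _bump_amplitude(float(height), c_share)
        positions = {}
        for chrom in chroms:
            clen = layout[chrom]
            bg = rng.integers(0, clen, size=rng.poisson(r0 * clen))
            extra = []
            per_anchor = r0 * amp * math.sqrt(2 * math.pi) * sigma
            for a in anchors_by_chrom[chrom]:
                k = rng.poisson(per_anchor)
                if k:
                    pts = np.round(rng.normal(a, sigma, size=k)).astype(np.int64)
                    extra.append(pts[(pts >= 0) & (pts < clen)])
            parts = [bg] + extra
            positions[chrom] = np.sort(np.concatenate(parts))
        tracks[mark] = SignalTrack(positions, layout, name=mark)

    deleted_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for iv in merge_intervals(list(repressive_deleted)) if repressive_deleted else []:
        deleted_by_chrom[iv.chrom].append((iv.start, iv.end))

    for mark, depth in config.repressive_marks.items():
        u = _dip_depth(float(depth), c_share)
        positions = {}
        for chrom in chroms:
            clen = layout[chrom]
            bg = np.sort(rng.integers(0, clen, size=rng.poisson(r0 * clen)))
            keep_p = np.ones(bg.size)
            anchors = anchors_by_chrom[chrom]
            if anchors.size and u > 0:
                idx = np.clip(np.searchsorted(anchors, bg), 0, anchors.size - 1)
                d_right = np.abs(anchors[idx] - bg)
                d_left = np.abs(anchors[np.maximum(idx - 1, 0)] - bg)
                dist = np.minimum(d_right, d_left)
                keep_p = 1.0 - u * np.exp(-(dist.astype(float) ** 2) / (2 * sigma**2))
            for s, e in deleted_by_chrom[chrom]:
                inside = (bg >= s) & (bg < e)
                keep_p[inside] = np.minimum(keep_p[inside], float(depth))
            bg = bg[rng.random(bg.size) < keep_p]
            positions[chrom] = bg
        tracks[mark] = SignalTrack(positions, layout, name=mark)
    return tracks


def expected_profile_fold(
    config: SyntheticConfig,
    layout: GenomeLayout,
    mark: str,
    offsets: np.ndarray,
    window: int = 500,
) -> np.ndarray:
    """Closed-form expected metaprofile of a generated track, window-averaged
    at the given window-center offsets (bp from the anchor).

    Valid for offsets well inside the minimum anchor spacing: it models the
    conditioned anchor's own bump or dip plus uniform background, ignoring
    neighboring anchors, whose surpluses restore the far field toward 1.
    """
    sigma = config.bump_sigma
    G = layout.total_length
    c_share = config.n_enhancers * math.sqrt(2 * math.pi) * sigma / G
    offsets = np.asarray(offsets, dtype=float)
    lo, hi = offsets - window / 2, offsets + window / 2
    gauss_win = (
        math.sqrt(2 * math.pi) * sigma / window * (norm.cdf(hi / sigma) - norm.cdf(lo / sigma))
    )
    if mark in config.active_marks:
        amp = _bump_amplitude(float(config.active_marks[mark]), c_share)
        return (1.0 + amp * gauss_win) / (1.0 + c_share * amp)
    if mark in config.repressive_marks:
        u = _dip_depth(float(config.repressive_marks[mark]), c_share)
        return (1.0 - u * gauss_win) / (1.0 - c_share * u)
    raise KeyError(mark)


def generate_expression(
    config: SyntheticConfig,
    genes: Sequence[Annotation],
    densities: Sequence[float],
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Genes-by-tissues intensity matrix with density-coupled specificity.

    Each gene's tissue profile is Dirichlet with concentration
    k0 * exp(-beta * density/mean positive density): beta = 0 makes
    specificity independent of density; larger beta concentrates expression
    of repeat-dense genes into fewer tissues (higher TS, lower entropy).
    """
    rng = np.random.default_rng(config.seed + 2 if rng is None else rng)
    d = np.asarray(densities, dtype=float)
    if d.shape != (len(genes),):
        raise ValueError("densities must align with genes")
    positive = d[d > 0]
    dbar = positive.mean() if positive.size else 1.0
    conc = np.clip(
        config.tissue_concentration * np.exp(-config.ts_density_beta * d / dbar),
        0.05,
        50.0,
    )
    T = config.n_tissues
    rows = np.empty((len(genes), T))
    for i, k in enumerate(conc):
        p = rng.dirichlet(np.full(T, k))
        magnitude = rng.lognormal(math.log(config.expression_scale), 0.5)
        rows[i] = magnitude * T * p
    return pd.DataFrame(rows, index=[g.id for g in genes],
                        columns=[f"tissue{i + 1}" for i in range(T)])


def generate_sequences(
    config: SyntheticConfig,
    repeats: Sequence[Annotation],
    labels: Mapping[str, str],
    rng: np.random.Generator | int | None = None,
) -> dict[str, str]:
    """I.i.d. nucleotide sequences per repeat with the configured GC content,
    with the motif string planted (overwriting in place at a random offset)
    at the target rate in enhancer-associated repeats and at the background
    rate elsewhere. Repeats shorter than the motif are never planted."""
    rng = np.random.default_rng(config.seed + 3 if rng is None else rng)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    motif = config.motif.upper()
    target_labels = {_classify.MIR_ENHANCER, _classify.ENHANCER_MIR}
    out: dict[str, str] = {}
    for rep in repeats:
        L = rep.interval.length
        seq = rng.choice(bases, size=L, p=probs)
        rate = (
            config.motif_plant_rate_target
            if labels.get(rep.id) in target_labels
            else config.motif_plant_rate_background
        )
        if L >= len(motif) and rng.random() < rate:
            pos = int(rng.integers(0, L - len(motif) + 1))
            seq[pos : pos + len(motif)] = list(motif)
        out[rep.id] = "".join(seq)
    return out


def generate_background_pool(
    config: SyntheticConfig,
    n_seqs: int = 500,
    length: int = 4_000,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Background genomic-sequence pool for the empirical motif null.

    I.i.d. nucleotides at the configured GC content, with the motif planted
    at a Poisson rate whose per-bp intensity matches the background
    per-repeat plant rate (rate/median repeat length), so substring draws
    from the pool look like random genomic sites that may contain ordinary
    non-enhancer repeat motifs.
    """
    rng = np.random.default_rng(config.seed + 4 if rng is None else rng)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    motif = config.motif.upper()
    per_seq = config.motif_plant_rate_background * length / config.repeat_length_median
    out = []
    for _ in range(n_seqs):
        seq = rng.choice(bases, size=length, p=probs)
        for _k in range(rng.poisson(per_seq)):
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq[pos : pos + len(motif)] = list(motif)
        out.append("".join(seq))
    return out


@dataclass
class SimulatedDataset:
    """Everything one seeded run of the generator produces."""

    config: SyntheticConfig
    layout: GenomeLayout
    enhancers: list
    repeats: list[Annotation]
    genes: list[Annotation]
    labels: dict[str, str]
    tracks: dict[str, SignalTrack]
    sequences: dict[str, str]
    densities: np.ndarray  # enhancer-associated repeat density per gene flank
    expression: pd.DataFrame


def generate_all(config: SyntheticConfig) -> SimulatedDataset:
    """Run the full generator: annotations, classification labels, tracks,
    sequences, gene-flank densities and the coupled expression matrix."""
    layout, enhancers, repeats, genes = generate_annotations(config)
    classes = _classify.classify_repeats(enhancers, repeats)
    labels = {c.annotation_id: c.label for c in classes}
    hosted = {eid for c in classes if c.label == _classify.MIR_ENHANCER
              for eid in c.linked_enhancers}
    deleted = [
        GenomicInterval(e.chrom, max(0, e.anchor - 10_000),
                        min(layout[e.chrom], e.anchor + 10_000))
        for e in enhancers
        if e.id in hosted
    ]
    tracks = generate_tracks(config, layout, enhancers, repressive_deleted=deleted)
    sequences = generate_sequences(config, repeats, labels)
    associated = [
        r.interval
        for r in repeats
        if labels[r.id] in (_classify.MIR_ENHANCER, _classify.ENHANCER_MIR)
    ]
    records = gene_feature_density(genes, associated, layout)
    densities = np.array([rec.density for rec in records])
    expression = generate_expression(config, genes, densities)
    return SimulatedDataset(config, layout, enhancers, repeats, genes, labels,
                            tracks, sequences, densities, expression)
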