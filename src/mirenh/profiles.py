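"""Windowed chromatin-signal metaprofiles and profile-shape congruence.

A metaprofile averages tag counts in fixed windows (default 500 bp across a
20 kb span) centered on a feature set and expresses each window as fold
enrichment over the genome-average count per window. Two profiles are
compared by a congruence score: Spearman rank correlation of paired window
values weighted by the least-squares slope of the test profile regressed on
the canonical one, so scores above 1 mean the test set carries the mark more
strongly than the canonical set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomeLayout, GenomicInterval, merge_intervals, total_length

logger = logging.getLogger(__name__)

__all__ = [
    "SignalTrack",
    "MetaProfile",
    "CongruenceScore",
    "metaprofile",
    "congruence",
    "rank_marks",
    "occupancy_enrichment",
    "plot_metaprofiles",
]


class SignalTrack:
    """Per-chromosome tag positions (point model: a tag lives at its start
    coordinate) with optional per-tag weights, tied to a genome layout."""

    def __init__(
        self,
        positions: Mapping[str, np.ndarray],
        layout: GenomeLayout,
        weights: Mapping[str, np.ndarray] | None = None,
        name: str = "track",
    ):
        self.layout = layout
        self.name = name
        self._pos: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        total = 0.0
        for chrom, pos in positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            w = (
                np.asarray(weights[chrom], dtype=float)
                if weights is not None
                else np.ones(pos.size)
            )
            order = np.argsort(pos, kind="stable")
            pos, w = pos[order], w[order]
            if pos.size and (pos[0] < 0 or pos[-1] >= layout[chrom]):
                raise ValueError(f"tag positions outside chromosome {chrom}")
            self._pos[chrom] = pos
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(w)])
            total += float(w.sum())
        self.total = total

    @classmethod
    def from_bedgraph(cls, data, layout: GenomeLayout, name: str = "track") -> "SignalTrack":
        """Build from :func:`mirenh.io.read_bedgraph` output (starts, values)."""
        positions = {c: p for c, (p, _v) in data.items()}
        weights = {c: v for c, (_p, v) in data.items()}
        return cls(positions, layout, weights, name=name)

    def count(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Weighted tag counts in consecutive windows given bin edges."""
        if chrom not in self._pos:
            return np.zeros(len(edges) - 1)
        idx = np.searchsorted(self._pos[chrom], edges, side="left")
        c = self._cum[chrom][idx]
        return np.diff(c)

    def count_interval(self, iv: GenomicInterval) -> float:
        return float(self.count(iv.chrom, np.array([iv.start, iv.end]))[0])


@dataclass
class MetaProfile:
    mark: str
    window: int
    span: int
    folds: np.ndarray  # one fold-enrichment value per window
    n_features: int

    def __post_init__(self) -> None:
        assert len(self.folds) * self.window == self.span

    @property
    def offsets(self) -> np.ndarray:
        """Window-center offsets relative to the feature anchor (bp)."""
        return (np.arange(len(self.folds)) + 0.5) * self.window - self.span / 2


@dataclass
class CongruenceScore:
    rho: float
    slope: float

    @property
    def score(self) -> float:
        """Rank correlation weighted by the slope magnitude; the sign of the
        congruence is carried by rho (anti-correlated profiles score < 0)."""
        return self.rho * abs(self.slope)


def _centers(features, default_chrom=None) -> list[tuple[str, int]]:
    out = []
    for f in features:
        if isinstance(f, GenomicInterval):
            out.append((f.chrom, f.midpoint))
        elif isinstance(f, tuple):
            out.append((f[0], int(f[1])))
        else:  # objects exposing chrom/anchor, e.g. Enhancer
            out.append((f.chrom, int(f.anchor)))
    return out


def metaprofile(
    features: Sequence,
    track: SignalTrack,
    span: int = 20_000,
    window: int = 500,
    mark: str | None = None,
) -> MetaProfile:
    """Fold-enrichment profile of a track around feature centers.

    Features are reduced to center points (interval midpoints, (chrom, pos)
    tuples, or objects with an ``anchor``). Features whose full span does not
    fit the chromosome are dropped with a log message. Fold is the mean tag
    count per window across features divided by the genome-average tag count
    per ``window`` bp.
    """
    if span % window != 0:
        raise ValueError("span must be a multiple of window")
    if track.total <= 0:
        raise ValueError("empty track: fold enrichment undefined")
    centers = _centers(features)
    if not centers:
        raise ValueError("no features supplied")
    n_win = span // window
    half = span // 2
    sums = np.zeros(n_win)
    used = 0
    for chrom, center in centers:
        if chrom not in track.layout:
            continue
        if center - half < 0 or center + half > track.layout[chrom]:
            continue
        edges = center - half + window * np.arange(n_win + 1)
        sums += track.count(chrom, edges)
        used += 1
    dropped = len(centers) - used
    if dropped:
        logger.info("metaprofile: dropped %d features with partial windows", dropped)
    if used == 0:
        raise ValueError("all features dropped (partial windows at chromosome edges)")
    genome_avg = track.total / (track.layout.total_length / window)
    folds = (sums / used) / genome_avg
    return MetaProfile(mark=mark or track.name, window=window, span=span,
                       folds=folds, n_features=used)


def congruence(profile_a: MetaProfile, profile_b: MetaProfile) -> CongruenceScore:
    """Rank congruence of two profiles: Spearman rho (average ranks on ties)
    times the OLS slope of b regressed on a (a = canonical, b = test)."""
    a, b = np.asarray(profile_a.folds, float), np.asarray(profile_b.folds, float)
    if a.shape != b.shape:
        raise ValueError("profiles have different window counts")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a profile; congruence undefined")
    rho = float(stats.spearmanr(a, b).statistic)
    slope = float(np.polyfit(a, b, 1)[0])
    return CongruenceScore(rho=rho, slope=slope)


def rank_marks(
    canonical_profiles: Mapping[str, MetaProfile],
    test_profiles: Mapping[str, MetaProfile],
) -> list[tuple[str, CongruenceScore]]:
    """Marks ordered by descending congruence score between the canonical and
    test feature sets."""
    if set(canonical_profiles) != set(test_profiles):
        raise ValueError("mark sets differ between canonical and test profiles")
    scored = [
        (mark, congruence(canonical_profiles[mark], test_profiles[mark]))
        for mark in canonical_profiles
    ]
    return sorted(scored, key=lambda item: item[1].score, reverse=True)


def occupancy_enrichment(
    target: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    track: SignalTrack,
) -> float:
    """Tag density (tags per bp) in target intervals over reference intervals,
    e.g. TF occupancy at enhancer-linked repeats vs non-enhancer repeats."""
    if track.total <= 0:
        raise ValueError("empty track")
    if not target or not reference:
        raise ValueError("target and reference interval sets must be non-empty")

    def density(intervals: Sequence[GenomicInterval]) -> float:
        merged = merge_intervals(intervals)
        tags = sum(track.count_interval(iv) for iv in merged)
        return tags / total_length(merged)

    ref_density = density(reference)
    if ref_density == 0:
        raise ZeroDivisionError("zero tag density in reference intervals")
    return density(target) / ref_density


def plot_metaprofiles(profiles: Sequence[MetaProfile], path: str) -> None:
    """Write a simple overlay plot of fold-enrichment profiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.plot(p.offsets / 1000.0, p.folds, label=p.mark)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("distance from anchor (kb)")
    ax.set_ylabel("fold enrichment")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
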