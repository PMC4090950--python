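"""Tissue-specificity indices and the binned density-vs-expression regression.

Two specificity measures over a nonnegative genes-by-tissues intensity
matrix: the max-normalized index TS = Σ(1−x_i)/(N−1) (0 = uniform across all
N tissues, 1 = expressed in a single tissue) and Shannon entropy of the
normalized expression distribution (high entropy = broad expression). Gene
flanks (gene body ± 10 kb by default) are scored for enhancer-associated
repeat density, and binned means of density are regressed against binned
means of an expression response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Annotation, GenomeLayout, GenomicInterval

__all__ = [
    "ts_index",
    "entropy_specificity",
    "ts_table",
    "GeneDensityRecord",
    "gene_feature_density",
    "BinnedRegression",
    "binned_regression",
]


def ts_index(values: Sequence[float]) -> float:
    """Tissue-specificity index TS = Σ(1 − x_i)/(N − 1), x_i max-normalized.

    Returns NaN for an all-zero profile (undefined; callers should exclude).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("TS requires at least 2 tissues")
    if (v < 0).any():
        raise ValueError("negative intensities")
    m = v.max()
    if m == 0:
        return float("nan")
    x = v / m
    return float((1.0 - x).sum() / (v.size - 1))


def entropy_specificity(values: Sequence[float]) -> float:
    """Shannon entropy (bits) of the across-tissue expression distribution.

    Low entropy means tissue-specific expression; a uniform profile over N
    tissues gives log2(N). NaN for an all-zero profile.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("negative intensities")
    s = v.sum()
    if s == 0:
        return float("nan")
    p = v / s
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def ts_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene TS, entropy, mean and max level; all-zero genes get NaN indices."""
    vals = matrix.values.astype(float)
    out = pd.DataFrame(index=matrix.index)
    out["ts"] = [ts_index(row) for row in vals]
    out["entropy"] = [entropy_specificity(row) for row in vals]
    out["mean_level"] = vals.mean(axis=1)
    out["max_level"] = vals.max(axis=1)
    return out


@dataclass
class GeneDensityRecord:
    gene_id: str
    flank_interval: GenomicInterval
    count: int

    @property
    def density(self) -> float:
        return self.count / self.flank_interval.length


def gene_feature_density(
    genes: Sequence[Annotation],
    features: Sequence[GenomicInterval],
    layout: GenomeLayout | None = None,
    flank: int = 10_000,
) -> list[GeneDensityRecord]:
    """Count features overlapping each flanked gene interval (>=1 bp overlap,
    whole features counted) and divide by the flanked length in bp. Flanks
    are clipped at chromosome ends when a layout is given; the clipped length
    is the denominator."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    prepared = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts = np.array([s for s, _ in pairs], dtype=np.int64)
        ends = np.array([e for _, e in pairs], dtype=np.int64)
        prepared[chrom] = (starts, ends)
    records = []
    for g in genes:
        iv = g.interval
        lo = max(0, iv.start - flank)
        hi = iv.end + flank
        if layout is not None:
            hi = min(hi, layout[iv.chrom])
        flank_iv = GenomicInterval(iv.chrom, lo, hi)
        count = 0
        if iv.chrom in prepared:
            starts, ends = prepared[iv.chrom]
            first = int(np.searchsorted(starts, hi, side="left"))
            count = int(np.count_nonzero(ends[:first] > lo))
        records.append(GeneDensityRecord(g.id, flank_iv, count))
    return records


@dataclass
class BinnedRegression:
    n_bins: int
    bin_density: np.ndarray
    bin_response: np.ndarray
    r: float
    p_value: float

    @property
    def degenerate(self) -> bool:
        return np.isnan(self.r)

    def summary(self) -> str:
        if self.degenerate:
            return f"binned regression over {self.n_bins} bins: degenerate (constant response)"
        return f"binned regression over {self.n_bins} bins: r={self.r:.3f}, P={self.p_value:.3g}"


def binned_regression(
    densities: Sequence[float],
    responses: Sequence[float],
    n_bins: int = 100,
) -> BinnedRegression:
    """Sort genes by density, split into ``n_bins`` equal-count bins (stable
    order on ties), and correlate per-bin mean density with per-bin mean
    response (Pearson r, two-sided p over the bin pairs).

    Genes with undefined (NaN) responses are excluded first. A constant
    response yields a degenerate result (r = NaN) rather than an error.
    """
    d = np.asarray(densities, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise ValueError("densities and responses differ in length")
    keep = ~np.isnan(y) & ~np.isnan(d)
    d, y = d[keep], y[keep]
    if d.size < n_bins:
        raise ValueError(
            f"only {d.size} genes with defined responses for {n_bins} bins; "
            "reduce n_bins"
        )
    order = np.argsort(d, kind="stable")
    bin_d = np.array([b.mean() for b in np.array_split(d[order], n_bins)])
    bin_y = np.array([b.mean() for b in np.array_split(y[order], n_bins)])
    if np.ptp(bin_y) == 0 or np.ptp(bin_d) == 0:
        return BinnedRegression(n_bins, bin_d, bin_y, float("nan"), float("nan"))
    res = stats.pearsonr(bin_d, bin_y)
    return BinnedRegression(n_bins, bin_d, bin_y, float(res.statistic), float(res.pvalue))
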