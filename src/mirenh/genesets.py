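"""Cell-type-specific feature selection, gene linkage, and hypergeometric
gene-set enrichment.

Features specific to one cell type are those present in its annotation set
and absent (by exact coordinate) from a second set. Genes within a distance
cutoff of such features form the "associated" draw; overlap with curated
gene sets (GMT) is scored with the upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Annotation

__all__ = [
    "HypergeomResult",
    "cell_specific_features",
    "link_genes",
    "hypergeom_test",
    "geneset_enrichment_table",
]


@dataclass
class HypergeomResult:
    """Upper-tail hypergeometric test: universe N, set size K, draws n, overlap k."""

    universe: int
    set_size: int
    draws: int
    overlap: int
    p_value: float

    def summary(self) -> str:
        return (
            f"N={self.universe} K={self.set_size} n={self.draws} "
            f"k={self.overlap} P={self.p_value:.3g}"
        )


def cell_specific_features(
    set_a: Sequence[Annotation], set_b: Sequence[Annotation]
) -> list[Annotation]:
    """Members of set_a whose (chrom, start, end) key does not occur in set_b."""
    keys_b = {(a.interval.chrom, a.interval.start, a.interval.end) for a in set_b}
    return [
        a
        for a in set_a
        if (a.interval.chrom, a.interval.start, a.interval.end) not in keys_b
    ]


def link_genes(
    features: Sequence[Annotation],
    genes: Sequence[Annotation],
    max_distance: int = 100_000,
    anchor: str = "body",
) -> set[str]:
    """Gene ids within ``max_distance`` bp of >= 1 feature.

    Distance is edge-to-edge between the gene body and the feature interval
    (overlap = distance 0); ``anchor='tss'`` measures from the gene start
    (strand-aware 5' end) instead. Invariant to feature order/duplication.
    """
    if anchor not in ("body", "tss"):
        raise ValueError("anchor must be 'body' or 'tss'")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_chrom.setdefault(f.interval.chrom, []).append((f.interval.start, f.interval.end))
    prepared = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts = np.array([s for s, _ in pairs], dtype=np.int64)
        ends = np.array([e for _, e in pairs], dtype=np.int64)
        prepared[chrom] = (starts, np.maximum.accumulate(ends))
    linked: set[str] = set()
    for g in genes:
        iv = g.interval
        if iv.chrom not in prepared:
            continue
        if anchor == "tss":
            tss = iv.end - 1 if iv.strand == "-" else iv.start
            lo, hi = tss, tss + 1
        else:
            lo, hi = iv.start, iv.end
        starts, maxends = prepared[iv.chrom]
        # inclusive: a feature exactly max_distance away still links
        first = int(np.searchsorted(starts, hi + max_distance, side="right"))
        if first > 0 and maxends[first - 1] >= lo - max_distance:
            linked.add(g.id)
    return linked


def hypergeom_test(N: int, K: int, n: int, k: int) -> HypergeomResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed stably.

    The upper tail includes the observed overlap, the standard enrichment
    convention; k = 0 therefore gives p = 1.
    """
    if not (0 <= k <= min(K, n) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return HypergeomResult(N, K, n, k, min(p, 1.0))


def geneset_enrichment_table(
    associated_genes: set[str],
    gene_sets: Mapping[str, Mapping],
    universe: int | Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of the associated genes in each gene set,
    with Benjamini-Hochberg q-values across the tested sets.

    ``universe`` is either the universe size or the universe gene list; when
    a list is given, set members and associated genes are intersected with it.
    """
    if isinstance(universe, int):
        N = universe
        universe_genes = None
    else:
        universe_genes = set(universe)
        N = len(universe_genes)
        associated_genes = associated_genes & universe_genes
    rows = []
    for name, rec in gene_sets.items():
        members = set(rec["genes"])
        if universe_genes is not None:
            members &= universe_genes
        k = len(members & associated_genes)
        res = hypergeom_test(N, len(members), len(associated_genes), k)
        rows.append(
            {
                "set": name,
                "universe": N,
                "set_size": len(members),
                "associated": len(associated_genes),
                "overlap": k,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows).set_index("set")
    if len(df):
        df["q_value"] = stats.false_discovery_control(df["p_value"].values, method="bh")
    return df.sort_values("p_value")
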