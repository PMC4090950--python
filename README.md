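# mirenh

Analysis of repeat-derived enhancers: do transposable-element annotations
(such as MIR, the ancient tRNA-derived SINE family conserved across mammals)
concentrate inside chromatin-predicted enhancers, acquire enhancer-like
chromatin and transcription-factor binding motifs, and track the
tissue-specificity of nearby genes?

The package is aimed at regulatory-genomics analysts working with BED-style
annotation tracks, tag-position ChIP-seq tracks, genes × tissues expression
matrices and GMT gene sets. Every stage is also exercisable on seeded
synthetic genomes, so the whole pipeline is testable without downloads.

## The statistics at its core

An enhancer is represented by a single anchored basepair; its *span* is the
±4 kb window around the anchor and its *core* the central 200 bp. Repeats
are classified exactly once:

* **repeat-enhancer** (`MIR_ENHANCER`) — the repeat contains an enhancer
  anchor (half-open containment, start ≤ anchor < end);
* **enhancer-linked repeat** (`ENHANCER_MIR`) — ≥ 1 bp overlap with a span
  but no anchor;
* **non-enhancer repeat** otherwise.

Observed counts *O* are compared with expectations *E* by the one-cell
chi-square statistic

> χ² = (O − E)² / E,  1 df, upper tail,

where *E* is either analytic (genome-wide enhancer density × total repeat bp)
or simulated (random sites matched to the repeats in number and size).
Around feature sets, chromatin marks are summarized as metaprofiles — mean
tag counts in 500 bp windows across 20 kb, as fold over the genome-average
count per window — and two profiles are compared by a congruence score
ρ·|b|, Spearman's ρ weighted by the magnitude of the least-squares slope *b*
of the test profile on the canonical one. Motif enrichment uses PWM
log-odds or IUPAC-regex counting against an empirical null of 1,000
length-matched random samples, with Z = (χ − μ)/σ where μ is the null
*median*. Tissue-specificity uses TS = Σᵢ(1 − xᵢ)/(N − 1) with xᵢ the
max-normalized intensity (0 = uniform, 1 = single-tissue), or Shannon
entropy; gene-flank repeat densities are regressed against expression
responses over 100 equal-count bins (Pearson r). Gene-set enrichment is the
upper-tail hypergeometric test with Benjamini–Hochberg correction.

## Worked example

One command generates the default synthetic genome (2 × 5 Mb, 200 enhancers,
5,000 repeats planted at threefold density inside enhancer spans, 500 genes,
6 tissues, a planted AP-1 motif and a density-coupled expression matrix) and
runs all four analyses:

```text
$ mirenh reproduce-synthetic --seed 0 --out demo/
repeat_enrichment_in_enhancers: PASS
congruence_active_above_repressive: PASS
motif_enrichment: PASS
density_specificity_positive: PASS
core_chi_sq = 58.86
core_p = 1.694e-14
motif_z = 62.73
density_ts_r = 0.8098
summary written to demo/summary.json
```

Reading the numbers: 85 repeats contain an enhancer anchor against ~38
expected under a uniform null, giving χ² ≈ 59 (p ≈ 2 × 10⁻¹⁴) — the planted
threefold concentration is detected. Active marks (H3K4me1, H3K27ac) score
near 1 in profile congruence between canonical enhancers and
repeat-enhancers while the repressive mark (H3K27me3) scores near 0; the
planted motif is ~63 null standard deviations above the resampled median;
and binned repeat density correlates with tissue-specificity at r ≈ 0.81.

The same stages are available individually (`simulate`, `classify`,
`profile`, `motifscan`, `expression`, `geneset`) on files you supply, and
everything is importable as a library (`mirenh.classify_repeats`,
`mirenh.metaprofile`, `mirenh.empirical_motif_test`, ...).

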