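# Methods

This note documents the models, conventions and numerical choices behind
`mirenh`, and what the synthetic-data generator does and does not emulate.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); readers convert on
ingestion. Overlap is strand-agnostic throughout. `occupied_fraction` merges
both interval sets first and counts only overlapping basepairs, so the
fraction is always in [0, 1]. The local genomic background of a locus is a
same-length window whose start is drawn uniformly from the envelope
[locus end + 100 kb, locus end + 200 kb − length]; when the envelope runs
off the chromosome the placement mirrors upstream, and loci with no valid
placement are skipped with a warning. "~100 kb downstream" fixes the
distance scale; the uniform envelope makes the sampling well-defined and
seedable. One background window per locus is the default (configurable).

## Enhancer geometry and classification

An enhancer is an anchored basepair with a derived ±4 kb span and a central
200 bp core; spans are clipped at chromosome ends (clipping recorded, the
clipped length used in densities). Anchor containment is half-open
(start ≤ anchor < end). A repeat overlapping several spans is classified
once and all linked enhancer ids are kept; an enhancer with several linked
repeats counts once toward "enhancers with repeats".

The enrichment statistic is deliberately the one-cell χ² = (O − E)²/E on
1 df, not a two-cell Pearson test: the one-cell form reproduces the
published worked examples exactly ((934 − 669)²/669 = 105.0, etc.), which a
two-cell computation does not. The analytic expectation is genome-wide
enhancer density (enhancers/bp) × merged repeat bp. The simulated
expectation places random sites matched to the repeats in number and length,
uniformly per chromosome weighted by chromosome length, sites free to
overlap one another — the simplest null consistent with "equivalent in
number and size". The survival function underflows for the largest printed
statistics; p-values are floored at the smallest positive normal float so
they stay in (0, 1].

## Metaprofiles and congruence

Tags follow a point model (a tag lives at its start coordinate; bedGraph
values are weights at interval starts — a coverage-interval model was
considered and left as a possible extension). Profiles average tag counts
in 500 bp windows across 20 kb around feature centers; features whose
windows would leave the chromosome are dropped and logged. Fold is relative
to total tags ÷ (genome length / window size). The congruence score is
Spearman's ρ (average ranks on ties) weighted by |slope| of the ordinary
least-squares regression of the test profile on the canonical profile. The
test profile is the dependent variable so that scores above 1 mean the test
set carries the mark more strongly than the canonical set; the sign is
carried by ρ so anti-correlated profiles score negative. Raw slope
magnitude is used as the weight; a symmetric slope transform would be an
alternative and is noted, not implemented.

## Motif scanning and the empirical null

PWM scoring is log((p + 0.01)/(1 + 0.04)/0.25) per position against a
uniform background, with a hit threshold of 0.8 × the maximum attainable
score by default (both pseudocount and threshold are explicit, logged
configuration — published threshold conventions vary). Ambiguous bases
score 0 (the background). Both strands are scanned and summed, except that
reverse-complement-symmetric motifs (regex or matrix) yield identical start
positions on both strands and are counted once.

The empirical null draws, `n_reps` times (default 1,000), a random sample
matched to the target set in number and length. Two schemes: whole-sequence
draws without replacement within a replicate (pool members paired to
targets longest-to-longest) for pools of comparably sized features, and
substring draws (an eligible pool sequence chosen uniformly, a uniform
substring cut to the exact target length) emulating random genomic sites.
The null center is the *median*; the spread is the sample standard
deviation — the only dispersion the resampling procedure yields — giving
Z = (observed − median)/sd and a one-sided normal p. A zero spread flags
the result degenerate rather than emitting a p-value. Pool hit counts are
cached per motif so repeated nulls do not rescan the pool.

## Expression association

TS = Σ(1 − xᵢ)/(N − 1) with xᵢ max-normalized; Shannon entropy uses the
across-tissue distribution in bits. All-zero genes are flagged NaN and
excluded from regressions. Gene-flank density counts whole features with
≥ 1 bp overlap of the gene ± 10 kb (clipped flank length as denominator) —
a count per bp, not bp occupancy, matching how the index is defined. The
"100 equal bins" are equal-count (quantile) bins after a stable sort by
density: with most genes at density zero, equal-width bins would leave most
bins empty, while equal-count bins keep every bin mean defined. Pearson r
and its two-sided p are computed on the 100 bin pairs (the literal reading
of the procedure); computing p over all genes instead would be stricter and
is not done.

## Gene sets

Cell-type-specific features are exact-coordinate set differences. Gene
linkage is edge-to-edge distance between gene body and feature, inclusive
at the cutoff (a TSS-anchored mode is available). The hypergeometric test
is upper-tail including the observed overlap; Benjamini–Hochberg q-values
are reported across the tested sets. The gene universe is a configurable
input, defaulting to the supplied gene model file.

## The synthetic-data generator

Defaults define the study conditions: 2 chromosomes × 5 Mb, 200 enhancers
(anchors uniform with ≥ 8 kb spacing, half a span clear of chromosome
ends), 5,000 repeats (log-normal lengths, median 350 bp, σ = 0.4 — sized so
the toy genome carries realistic repeat coverage while leaving the
classification statistics well-powered), planted fold f = 3 inside enhancer
spans, two active marks (5× and 4× bumps, σ = 1 kb) and one repressive mark
(0.2× dip), 10⁶ background tags per mark, 500 genes, 6 tissues,
density–specificity coupling β = 0.8, and an AP-1 consensus (TGACTCA)
planted in 50% of enhancer-associated repeat sequences vs 5% elsewhere at
GC 0.41. The full pipeline on these defaults runs in well under two
minutes on one CPU.

Design choices worth knowing:

* **Repeats never overlap one another** (random sequential placement with
  resampling), as RepeatMasker-style annotations never overlap within a
  class. This also keeps the planted density ratio linear in f — with free
  overlap, coverage saturates and the measured fold shrinks.
* **Span fraction matters for O/E.** The analytic expectation uses the
  genome-wide repeat density, which itself includes the planted surplus, so
  the expected observed/expected ratio is f/(1 + s(f − 1)) with s the span
  fraction of the genome. On the default toy genome s ≈ 0.16; recovery
  tests that ask for the ratio to approximate f therefore use a genome with
  s = 0.02, where the attenuation is 4%.
* **Configured bump heights are fold enrichments on the metaprofile
  scale.** The Gaussian amplitude is solved so that the post-normalization
  central fold equals the configured height — a naive amplitude of h would
  be partly renormalized away by its own contribution to the genome
  average. `expected_profile_fold` gives the closed-form window-averaged
  profile; it is valid inside the anchor-exclusion zone (neighboring
  enhancers' bumps restore the far field toward 1, and slightly above 1
  near the minimum spacing).
* **The repressive mark is deleted, not just dipped, at repeat-hosted
  enhancers**: within ±10 kb of anchors that lie inside repeats, repressive
  tags are thinned uniformly to the depletion depth. This emulates the
  observed broad loss of repressive chromatin at repeat-derived enhancers
  and is what makes the congruence ranking informative — with identical
  dip shapes everywhere, canonical and test profiles would be congruent
  for every mark and the ranking would be noise.
* **Expression coupling** draws each gene's tissue profile from a Dirichlet
  whose concentration is k₀·exp(−β · density/mean positive density)
  (clipped to [0.05, 50]); β = 0 gives exact independence, larger β
  concentrates repeat-dense genes into fewer tissues. Any generator
  satisfying the same β contracts would do; the Dirichlet gives valid
  TS/entropy values with a single knob.
* Tag bumps at higher level than real ChIP-seq depth, an 8 kb minimum
  anchor spacing, i.i.d. background sequence and per-sequence motif
  planting are simplifications: passing tests demonstrate the estimators
  recover planted structure under clean conditions, not that real data are
  free of confounders (GC content, mappability, replicate noise are not
  modeled).

## Numerical and testing choices

Seeds control every random draw; generators are pure functions of their
configuration. The flat-profile invariant is checked with a family-wise
calibrated bound (≈3.7 Monte-Carlo standard errors per window, Bonferroni
over 40 windows) rather than a per-window 3σ rule, which would reject a
correct implementation in roughly one run in ten by chance. The simulated
overlap expectation's closed-form check uses the linear-chromosome
placement probability (S + L − 1)/(G − L + 1) for an interior span. The
type-I calibration of the motif null uses a pool of 3,000 × 800 bp
sequences (≈18 expected hits per sample — enough for the normal
approximation of the Z-test to hold at the tail being tested).

## Known limitations

No liftover, assembly gaps, peak calling, input subtraction, microarray
normalization, GC-content covariate control or homolog-aware gene-set
expansion. The enhancer predictions themselves are inputs, never derived.
Real-data headline counts depend on specific genome assemblies and consortium
tracks and are outside what the synthetic conditions can or should
reproduce; the package reproduces the statistics, estimators and their
qualitative behavior.
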