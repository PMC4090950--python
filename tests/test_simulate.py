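"""Construction guarantees of the synthetic-data generator."""

import io as stdio

import numpy as np
import pytest

from mirenh import classify as clf
from mirenh import io as mio
from mirenh.intervals import merge_intervals, total_length
from mirenh.motifs import RegexMotif, empirical_motif_test, scan_regex
from mirenh.profiles import metaprofile
from mirenh.expression import binned_regression, ts_table
from mirenh.simulate import (
    SyntheticConfig,
    expected_profile_fold,
    generate_all,
    generate_annotations,
    generate_background_pool,
    generate_expression,
    generate_sequences,
    generate_tracks,
)


def span_density_ratio(layout, enhancers, repeats):
    """Repeat-midpoint count density inside enhancer spans vs outside."""
    spans = merge_intervals([e.span for e in enhancers])
    S = total_length(spans)
    T = layout.total_length
    by = {}
    for iv in spans:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    starts = {c: np.array([s for s, _ in sorted(v)]) for c, v in by.items()}
    ends = {c: np.array([e for _, e in sorted(v)]) for c, v in by.items()}
    n_in = 0
    for r in repeats:
        m, c = r.interval.midpoint, r.interval.chrom
        if c in starts:
            i = np.searchsorted(starts[c], m, side="right") - 1
            if i >= 0 and m < ends[c][i]:
                n_in += 1
    return (n_in / S) / ((len(repeats) - n_in) / (T - S))


class TestGenerateAnnotations:
    def test_same_seed_gives_byte_identical_bed(self):
        cfg = SyntheticConfig(seed=5, n_repeats=500, n_genes=50)
        outputs = []
        for _ in range(2):
            _, _, repeats, genes = generate_annotations(cfg)
            buf = stdio.StringIO()
            for a in repeats + genes:
                buf.write(f"{a.interval.chrom}\t{a.interval.start}\t{a.interval.end}\t{a.id}\n")
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_repeats_never_overlap(self):
        cfg = SyntheticConfig(seed=3, n_repeats=3_000, n_genes=0)
        _, _, repeats, _ = generate_annotations(cfg)
        per_chrom = {}
        for r in repeats:
            per_chrom.setdefault(r.interval.chrom, []).append((r.interval.start, r.interval.end))
        for spans in per_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_anchor_spacing_respected(self):
        cfg = SyntheticConfig(seed=1, n_repeats=0, n_genes=0)
        _, enhancers, _, _ = generate_annotations(cfg)
        per_chrom = {}
        for e in enhancers:
            per_chrom.setdefault(e.chrom, []).append(e.anchor)
        for anchors in per_chrom.values():
            anchors.sort()
            assert min(np.diff(anchors)) >= cfg.min_anchor_spacing

    def test_unplanted_fold_is_flat(self):
        cfg = SyntheticConfig(
            seed=11, n_chroms=2, chrom_length=25_000_000, n_repeats=50_000,
            repeat_length_median=250, enhancer_repeat_fold=1.0, n_genes=0,
        )
        layout, enhancers, repeats, _ = generate_annotations(cfg)
        assert span_density_ratio(layout, enhancers, repeats) == pytest.approx(1.0, rel=0.05)

    def test_planted_threefold_recovered(self):
        cfg = SyntheticConfig(
            seed=11, n_chroms=2, chrom_length=25_000_000, n_repeats=20_000,
            repeat_length_median=250, enhancer_repeat_fold=3.0, n_genes=0,
        )
        layout, enhancers, repeats, _ = generate_annotations(cfg)
        assert span_density_ratio(layout, enhancers, repeats) == pytest.approx(3.0, rel=0.10)

    def test_infeasible_packing_rejected(self):
        cfg = SyntheticConfig(seed=0, n_chroms=1, chrom_length=100_000,
                              n_enhancers=50, n_repeats=0, n_genes=0)
        with pytest.raises(ValueError, match="packing"):
            generate_annotations(cfg)


class TestGenerateTracks:
    cfg = SyntheticConfig(seed=9, n_chroms=1, chrom_length=5_000_000,
                          n_enhancers=100, n_repeats=0, n_genes=0,
                          tag_depth=500_000)

    def _tracks(self, config):
        layout, enhancers, _, _ = generate_annotations(config)
        return layout, enhancers, generate_tracks(config, layout, enhancers)

    def test_flat_when_bump_height_absent(self):
        cfg = SyntheticConfig(**{**self.cfg.__dict__,
                                 "active_marks": {"flat": 0.0},
                                 "repressive_marks": {}})
        layout, enhancers, tracks = self._tracks(cfg)
        prof = metaprofile(enhancers, tracks["flat"])
        assert np.all(np.abs(prof.folds - 1.0) < 0.1)

    def test_bump_and_dip_match_closed_form_profile(self):
        cfg = SyntheticConfig(**{**self.cfg.__dict__,
                                 "active_marks": {"act": 5.0},
                                 "repressive_marks": {"rep": 0.2}})
        layout, enhancers, tracks = self._tracks(cfg)
        for mark in ("act", "rep"):
            prof = metaprofile(enhancers, tracks[mark], mark=mark)
            expected = expected_profile_fold(cfg, layout, mark, prof.offsets)
            # Monte-Carlo error: Poisson counts per window across features
            per_window = cfg.tag_depth / (layout.total_length / 500) * prof.n_features
            se = np.sqrt(np.maximum(expected, 1e-9) / per_window)
            # the closed form holds inside the anchor-exclusion zone, where
            # neighboring enhancers contribute no signal
            central = np.abs(prof.offsets) <= 4_000
            assert np.all(
                np.abs(prof.folds[central] - expected[central]) < 5 * se[central]
            )

    def test_central_windows_near_configured_height_and_depth(self):
        cfg = SyntheticConfig(**{**self.cfg.__dict__,
                                 "active_marks": {"act": 5.0},
                                 "repressive_marks": {"rep": 0.2}})
        layout, enhancers, tracks = self._tracks(cfg)
        act = metaprofile(enhancers, tracks["act"])
        rep = metaprofile(enhancers, tracks["rep"])
        mid = len(act.folds) // 2
        assert max(act.folds[mid - 1], act.folds[mid]) == pytest.approx(5.0, rel=0.06)
        assert min(rep.folds[mid - 1], rep.folds[mid]) == pytest.approx(0.2, abs=0.06)


class TestGenerateExpression:
    def _densities(self, rng, n, sparsity=0.5):
        d = rng.gamma(1.0, 1e-4, size=n)
        d[rng.random(n) < sparsity] = 0.0
        return d

    def test_zero_beta_uncouples_specificity_from_density(self):
        null_ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cfg = SyntheticConfig(seed=seed, ts_density_beta=0.0)
            genes = [None] * 400
            d = self._densities(rng, 400)
            from mirenh.intervals import Annotation, GenomicInterval
            genes = [Annotation(GenomicInterval("chr1", i * 10, i * 10 + 5), "gene", f"g{i}")
                     for i in range(400)]
            expr = generate_expression(cfg, genes, d, rng=rng)
            ts = ts_table(expr)["ts"].values
            if abs(binned_regression(d, ts, 100).r) < 0.3:
                null_ok += 1
        assert null_ok >= 19

    def test_strong_beta_yields_strong_positive_regression(self):
        from mirenh.intervals import Annotation, GenomicInterval
        rng = np.random.default_rng(1)
        cfg = SyntheticConfig(seed=1, ts_density_beta=2.0)
        genes = [Annotation(GenomicInterval("chr1", i * 10, i * 10 + 5), "gene", f"g{i}")
                 for i in range(600)]
        d = self._densities(rng, 600, sparsity=0.3)
        expr = generate_expression(cfg, genes, d, rng=rng)
        reg = binned_regression(d, ts_table(expr)["ts"].values, 100)
        assert reg.r > 0.8
        assert reg.p_value < 1e-6

    def test_matrix_nonnegative_with_positive_max(self):
        from mirenh.intervals import Annotation, GenomicInterval
        cfg = SyntheticConfig(seed=2)
        genes = [Annotation(GenomicInterval("chr1", i * 10, i * 10 + 5), "gene", f"g{i}")
                 for i in range(50)]
        expr = generate_expression(cfg, genes, np.zeros(50), rng=0)
        assert (expr.values >= 0).all()
        assert (expr.values.max(axis=1) > 0).all()


class TestGenerateSequences:
    def _setup(self, seed=0, n=400):
        cfg = SyntheticConfig(seed=seed)
        from mirenh.intervals import Annotation, GenomicInterval
        repeats = [Annotation(GenomicInterval("chr1", i * 500, i * 500 + 300), "MIR", f"r{i}")
                   for i in range(n)]
        labels = {r.id: (clf.ENHANCER_MIR if i < n // 2 else clf.NON_ENHANCER_MIR)
                  for i, r in enumerate(repeats)}
        return cfg, repeats, labels

    def test_same_seed_identical_fasta(self, tmp_path):
        cfg, repeats, labels = self._setup()
        a = generate_sequences(cfg, repeats, labels, rng=4)
        b = generate_sequences(cfg, repeats, labels, rng=4)
        assert a == b

    def test_plant_rates_differ_between_classes(self):
        cfg, repeats, labels = self._setup(seed=3)
        seqs = generate_sequences(cfg, repeats, labels, rng=3)
        motif = RegexMotif("m", cfg.motif)
        target_hits = np.mean([scan_regex(seqs[r.id], motif) > 0
                               for r in repeats if labels[r.id] == clf.ENHANCER_MIR])
        bg_hits = np.mean([scan_regex(seqs[r.id], motif) > 0
                           for r in repeats if labels[r.id] == clf.NON_ENHANCER_MIR])
        assert target_hits > 0.4
        assert bg_hits < 0.2

    def test_equal_rates_give_null_z(self):
        cfg, repeats, labels = self._setup(seed=5)
        cfg.motif_plant_rate_target = cfg.motif_plant_rate_background = 0.1
        seqs = generate_sequences(cfg, repeats, labels, rng=5)
        targets = [seqs[r.id] for r in repeats[:100]]
        pool = [seqs[r.id] for r in repeats]
        res = empirical_motif_test(targets, pool, RegexMotif("m", cfg.motif),
                                   n_reps=200, rng=5)
        assert abs(res.z) < 3

    def test_planted_signal_detected_with_high_power(self):
        detections = 0
        for seed in range(10):
            cfg, repeats, labels = self._setup(seed=100 + seed, n=400)
            seqs = generate_sequences(cfg, repeats, labels, rng=100 + seed)
            targets = [seqs[r.id] for r in repeats if labels[r.id] == clf.ENHANCER_MIR]
            pool = generate_background_pool(cfg, n_seqs=300, length=2_000, rng=seed)
            res = empirical_motif_test(targets, pool, RegexMotif("m", cfg.motif),
                                       n_reps=100, rng=seed, sampling="substring")
            if res.z is not None and res.z > 3:
                detections += 1
        assert detections >= 9


def test_generate_all_is_consistent(tmp_path):
    cfg = SyntheticConfig(seed=4, n_chroms=1, chrom_length=2_000_000, n_enhancers=40,
                          n_repeats=800, n_genes=120, gene_length_median=5_000,
                          tag_depth=100_000)
    ds = generate_all(cfg)
    assert set(ds.labels) == {r.id for r in ds.repeats}
    assert set(ds.sequences) == {r.id for r in ds.repeats}
    assert ds.expression.shape == (120, cfg.n_tissues)
    assert ds.densities.shape == (120,)
    assert set(ds.tracks) == set(cfg.active_marks) | set(cfg.repressive_marks)
    # writers accept everything the generator produces
    mio.write_annotations(tmp_path / "r.bed", ds.repeats)
    mio.write_expression_tsv(tmp_path / "e.tsv", ds.expression)
    mio.write_fasta(tmp_path / "s.fa", ds.sequences)
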