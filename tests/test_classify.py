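"""Repeat-vs-enhancer classification, expected counts, and the one-cell
chi-square statistic."""

import numpy as np
import pytest

from mirenh import classify as clf
from mirenh.intervals import Annotation, GenomeLayout, GenomicInterval
from mirenh.simulate import SyntheticConfig, generate_annotations


def ann(start, end, id, chrom="chr1"):
    return Annotation(GenomicInterval(chrom, start, end), "MIR", id)


LAYOUT = GenomeLayout({"chr1": 1_000_000})


def enhancer(anchor, chrom="chr1", layout=LAYOUT):
    return clf.Enhancer.from_anchor(chrom, anchor, layout=layout)


class TestEnhancerGeometry:
    def test_span_and_core_derived_from_anchor(self):
        e = enhancer(50_000)
        assert (e.span.start, e.span.end) == (46_000, 54_000)
        assert (e.core200.start, e.core200.end) == (49_900, 50_100)
        assert not e.clipped

    def test_span_clipped_at_chromosome_start_is_recorded(self):
        e = enhancer(2_000)
        assert e.clipped
        assert e.span.start == 0 and e.span.length == 6_000


class TestClassifyRepeats:
    def test_rule_examples(self):
        enhancers = [enhancer(5_000)]
        repeats = [
            ann(4_900, 5_100, "core"),  # contains the anchor
            ann(8_500, 8_700, "linked"),  # inside the span only
            ann(20_000, 20_200, "far"),
        ]
        labels = {c.annotation_id: c.label for c in clf.classify_repeats(enhancers, repeats)}
        assert labels == {
            "core": clf.MIR_ENHANCER,
            "linked": clf.ENHANCER_MIR,
            "far": clf.NON_ENHANCER_MIR,
        }

    def test_anchor_on_boundary_uses_half_open_containment(self):
        enhancers = [enhancer(5_000)]
        starts_at_anchor = ann(5_000, 5_050, "a")
        ends_at_anchor = ann(4_950, 5_000, "b")
        labels = {
            c.annotation_id: c.label
            for c in clf.classify_repeats(enhancers, [starts_at_anchor, ends_at_anchor])
        }
        assert labels["a"] == clf.MIR_ENHANCER
        assert labels["b"] == clf.ENHANCER_MIR

    def test_matches_brute_force_on_random_instance(self, rng):
        layout = GenomeLayout({"chr1": 300_000, "chr2": 200_000})
        enhancers = [
            clf.Enhancer.from_anchor(c, int(a), id=f"e{i}", layout=layout)
            for i, (c, a) in enumerate(
                [("chr1", x) for x in rng.integers(4_000, 296_000, 30)]
                + [("chr2", x) for x in rng.integers(4_000, 196_000, 20)]
            )
        ]
        repeats = []
        for i in range(400):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            start = int(rng.integers(0, layout[chrom] - 500))
            repeats.append(ann(start, start + int(rng.integers(50, 500)), f"r{i}", chrom))

        got = {c.annotation_id: c.label for c in clf.classify_repeats(enhancers, repeats)}
        for rep in repeats:
            iv = rep.interval
            if any(e.chrom == iv.chrom and iv.start <= e.anchor < iv.end for e in enhancers):
                expected = clf.MIR_ENHANCER
            elif any(e.span.overlaps(iv) for e in enhancers):
                expected = clf.ENHANCER_MIR
            else:
                expected = clf.NON_ENHANCER_MIR
            assert got[rep.id] == expected

    def test_labels_partition_the_repeat_set(self, rng):
        enhancers = [enhancer(int(a)) for a in rng.integers(4_000, 996_000, 40)]
        repeats = [
            ann(int(s), int(s) + 200, f"r{i}")
            for i, s in enumerate(rng.integers(0, 999_000, 500))
        ]
        classes = clf.classify_repeats(enhancers, repeats)
        assert len(classes) == len(repeats)
        assert {c.annotation_id for c in classes} == {r.id for r in repeats}
        for c in classes:
            if c.label == clf.MIR_ENHANCER:
                assert c.linked_enhancers


class TestExpectedCoreCount:
    def test_hand_evaluated_product(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        enhancers = [enhancer(a, layout=layout) for a in range(10_000, 1_000_000, 100_000)]
        assert len(enhancers) == 10
        repeats = [ann(i * 10_000, i * 10_000 + 1_000, f"r{i}") for i in range(50)]
        # 10 enhancers / 1e6 bp * 50,000 repeat bp = 0.5
        assert clf.expected_core_count(enhancers, repeats, layout) == pytest.approx(0.5)

    def test_no_repeats_gives_zero(self):
        assert clf.expected_core_count([enhancer(5_000)], [], LAYOUT) == 0.0

    def test_repeats_tiling_genome_give_enhancer_count(self):
        layout = GenomeLayout({"chr1": 100_000})
        enhancers = [enhancer(a, layout=layout) for a in (20_000, 50_000, 80_000)]
        repeats = [ann(i * 1_000, (i + 1) * 1_000, f"r{i}") for i in range(100)]
        assert clf.expected_core_count(enhancers, repeats, layout) == pytest.approx(3.0)

    def test_overlapping_repeats_are_merged_first(self):
        layout = GenomeLayout({"chr1": 100_000})
        enhancers = [enhancer(50_000, layout=layout)]
        repeats = [ann(0, 10_000, "a"), ann(5_000, 10_000, "b")]
        assert clf.expected_core_count(enhancers, repeats, layout) == pytest.approx(0.1)


class TestExpectedEnhancersWithRepeats:
    def test_empty_repeat_set_gives_zero(self):
        assert clf.expected_enhancers_with_repeats([enhancer(5_000)], [], LAYOUT, 10, 0) == 0.0

    def test_span_covering_genome_gives_certain_overlap(self):
        layout = GenomeLayout({"chr1": 8_000})
        e = clf.Enhancer.from_anchor("chr1", 4_000, layout=layout)
        got = clf.expected_enhancers_with_repeats([e], [ann(0, 100, "r")], layout, 50, 0)
        assert got == 1.0

    def test_matches_closed_form_placement_probability(self):
        # one site of length L vs one interior span of length S on a linear
        # chromosome: P(overlap) = (S + L - 1) / (G - L + 1)
        G, L = 100_000, 500
        layout = GenomeLayout({"chr1": G})
        e = clf.Enhancer.from_anchor("chr1", 50_000, layout=layout)
        S = e.span.length
        p_exact = (S + L - 1) / (G - L + 1)
        mean = clf.expected_enhancers_with_repeats(
            [e], [ann(0, L, "r")], layout, n_reps=2_000, rng=123
        )
        se = np.sqrt(p_exact * (1 - p_exact) / 2_000)
        assert abs(mean - p_exact) < 4 * se

    def test_standard_error_shrinks_with_replicates(self):
        layout = GenomeLayout({"chr1": 500_000})
        enhancers = [enhancer(a, layout=layout) for a in range(10_000, 490_000, 50_000)]
        repeats = [ann(i * 1_000, i * 1_000 + 300, f"r{i}") for i in range(20)]
        _, c_small = clf.expected_enhancers_with_repeats(
            enhancers, repeats, layout, n_reps=100, rng=0, return_replicates=True
        )
        _, c_big = clf.expected_enhancers_with_repeats(
            enhancers, repeats, layout, n_reps=10_000, rng=1, return_replicates=True
        )
        se_small = c_small.std(ddof=1) / np.sqrt(c_small.size)
        se_big = c_big.std(ddof=1) / np.sqrt(c_big.size)
        assert se_small / se_big == pytest.approx(10.0, rel=0.35)

    def test_site_longer_than_every_chromosome_rejected(self):
        layout = GenomeLayout({"chr1": 1_000})
        with pytest.raises(Exception, match="longer"):
            clf.expected_enhancers_with_repeats(
                [clf.Enhancer.from_anchor("chr1", 500, layout=layout)],
                [ann(0, 999, "r")],
                GenomeLayout({"chr1": 500}),
                10,
                0,
            )


class TestOneCellChiSq:
    @pytest.mark.parametrize(
        "observed, expected, statistic",
        [(934, 669, 105), (1429, 996, 188), (16144, 6559, 14007), (26520, 9320, 31742)],
    )
    def test_reproduces_printed_statistics(self, observed, expected, statistic):
        report = clf.one_cell_chi_sq(observed, expected)
        assert round(report.chi_sq) == statistic

    def test_identity_case(self):
        report = clf.one_cell_chi_sq(37.0, 37.0)
        assert report.chi_sq == 0.0
        assert report.p_value == 1.0

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            clf.one_cell_chi_sq(5, 0.0)

    def test_p_value_stays_positive_for_extreme_statistics(self):
        assert clf.one_cell_chi_sq(26_520, 9_320).p_value > 0.0


class TestSyntheticRecovery:
    def test_null_genome_rarely_significant(self):
        """With repeats placed uniformly (fold 1), the observed repeat-
        enhancer count should be compatible with the analytic expectation in
        at least 98 of 100 seeded replicates at alpha = 0.01."""
        significant = 0
        for seed in range(100):
            cfg = SyntheticConfig(
                seed=2_000 + seed, n_chroms=2, chrom_length=20_000_000,
                n_enhancers=2_000, n_repeats=5_000, repeat_length_median=1_250,
                repeat_length_sigma=0.3, enhancer_repeat_fold=1.0, n_genes=0,
            )
            layout, enhancers, repeats, _ = generate_annotations(cfg)
            observed = sum(
                1 for c in clf.classify_repeats(enhancers, repeats)
                if c.label == clf.MIR_ENHANCER
            )
            expected = clf.expected_core_count(enhancers, repeats, layout)
            if clf.one_cell_chi_sq(observed, expected).p_value < 0.01:
                significant += 1
        assert significant <= 2

    def test_planted_fold_recovered_from_observed_over_expected(self):
        """Planted threefold repeat density in spans: observed/expected core
        count recovers the fold within 15% on a genome where spans are a
        small fraction of the total."""
        cfg = SyntheticConfig(
            seed=7, n_chroms=2, chrom_length=160_000_000, n_enhancers=800,
            n_repeats=20_000, repeat_length_median=2_500, repeat_length_sigma=0.3,
            enhancer_repeat_fold=3.0, n_genes=0,
        )
        layout, enhancers, repeats, _ = generate_annotations(cfg)
        observed = sum(
            1 for c in clf.classify_repeats(enhancers, repeats)
            if c.label == clf.MIR_ENHANCER
        )
        expected = clf.expected_core_count(enhancers, repeats, layout)
        assert observed / expected == pytest.approx(3.0, rel=0.15)
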