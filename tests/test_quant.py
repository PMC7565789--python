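"""Classification, depletion metrics, downsampling, detection and correlation."""

import math

import numpy as np
import pytest

from embrseq.align import AlignmentRecord
from embrseq.quant import (
    ClassCounts,
    classify_and_count,
    depletion_metrics,
    detection_curve,
    detection_overlap,
    downsample,
    expression_correlation,
    pool_counts,
)


def aln(read_id, ref_id, pos=0):
    return AlignmentRecord(read_id, ref_id, pos, "+", 50, 0, True)


def counts_from(per_class, per_gene=None, sample_id="s"):
    c = ClassCounts(sample_id)
    c.per_class.update(per_class)
    c.per_gene = dict(per_gene or {})
    c.total_mapped = sum(per_class.values())
    return c


ANN = {"rrn": ("rRNA", "rrn"), "trn": ("tRNA", "trn"),
       "g1": ("mRNA", "g1"), "g2": ("mRNA", "g2")}


class TestClassify:
    def test_all_rrna_fraction_one(self):
        c = classify_and_count([aln(f"r{i}", "rrn") for i in range(5)], ANN)
        assert c.fractions["rRNA"] == 1.0

    def test_two_read_toy(self):
        c = classify_and_count([aln("a", "rrn"), aln("b", "g1")], ANN)
        assert c.total_mapped == 2
        assert c.fractions["rRNA"] == c.fractions["mRNA"] == 0.5

    def test_unmapped_ignored_and_fractions_sum_to_one(self):
        alns = [aln("a", "rrn"), aln("b", "g1"), AlignmentRecord.unmapped("c")]
        c = classify_and_count(alns, ANN)
        assert c.total_mapped == 2
        assert sum(c.fractions.values()) == pytest.approx(1.0)

    def test_unannotated_reference_listed_in_error(self):
        with pytest.raises(ValueError, match="mystery"):
            classify_and_count([aln("a", "mystery")], ANN)

    def test_simulated_fractions_equal_truth_exactly(self, control_sample):
        """End-to-end tally matches the TruthTable for reads that map uniquely."""
        truth_frac = (control_sample.truth["class"] == "rRNA").mean()
        observed = control_sample.counts.fractions["rRNA"]
        # identical up to the <0.2% of reads lost to ambiguous/error mapping
        assert observed == pytest.approx(truth_frac, abs=0.005)


class TestDepletionMetrics:
    def test_printed_fractions_give_fourfold(self):
        control = counts_from({"rRNA": 64, "tRNA": 0, "mRNA": 36}, sample_id="control")
        test = counts_from({"rRNA": 16, "tRNA": 0, "mRNA": 84}, sample_id="embr")
        m = depletion_metrics(test, control)
        assert m.fold_rRNA_depletion == pytest.approx(4.0)
        assert m.fold_mRNA_enrichment == pytest.approx(84 / 36)

    def test_identical_samples_fold_one(self):
        c = counts_from({"rRNA": 10, "tRNA": 1, "mRNA": 9})
        m = depletion_metrics(c, c)
        assert m.fold_rRNA_depletion == 1.0 and m.fold_mRNA_enrichment == 1.0

    def test_zero_test_rrna_flagged_infinite(self):
        control = counts_from({"rRNA": 50, "tRNA": 0, "mRNA": 50})
        test = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 100})
        m = depletion_metrics(test, control)
        assert math.isinf(m.fold_rRNA_depletion) and m.infinite_depletion


class TestDownsample:
    ALNS = [aln(f"r{i}", "g1") for i in range(20)]

    def test_full_depth_identity(self):
        assert downsample(self.ALNS, 20, seed=0) == self.ALNS

    def test_zero_depth_empty(self):
        assert downsample(self.ALNS, 0, seed=0) == []

    def test_excess_depth_rejected(self):
        with pytest.raises(ValueError):
            downsample(self.ALNS, 21, seed=0)

    def test_deterministic_under_seed(self):
        assert downsample(self.ALNS, 10, seed=3) == downsample(self.ALNS, 10, seed=3)

    def test_inclusion_frequency_matches_hypergeometric(self):
        """At depth n/2 every read is included with probability 1/2."""
        n_seeds = 200
        freq = np.zeros(len(self.ALNS))
        for seed in range(n_seeds):
            for a in downsample(self.ALNS, 10, seed=seed):
                freq[int(a.read_id[1:])] += 1
        freq /= n_seeds
        se = math.sqrt(0.5 * 0.5 / n_seeds)
        assert np.all(np.abs(freq - 0.5) < 3 * se + 1e-12)


class TestDetectionCurve:
    def test_rpm_arithmetic(self):
        c = counts_from({"rRNA": 9, "tRNA": 0, "mRNA": 1}, {"g1": 1})
        assert c.rpm("g1") == pytest.approx(100_000)
        curve = detection_curve(c, [500])
        assert curve.genes_detected == [1]

    def test_threshold_zero_counts_expressed_genes(self):
        c = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 10}, {"g1": 7, "g2": 3})
        curve = detection_curve(c, [0, math.inf])
        assert curve.genes_detected == [2, 0]

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        genes = {f"g{i}": int(rng.integers(1, 500)) for i in range(40)}
        c = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": sum(genes.values())}, genes)
        curve = detection_curve(c, [0, 10, 100, 1000, 10_000, 100_000])
        assert all(a >= b for a, b in zip(curve.genes_detected, curve.genes_detected[1:]))

    def test_negative_threshold_rejected(self):
        c = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 1}, {"g1": 1})
        with pytest.raises(ValueError):
            detection_curve(c, [-1])

    def test_deeper_sample_dominates_pointwise(self):
        """Multinomial expression sampled at two depths: more reads, more genes."""
        rng = np.random.default_rng(1)
        expr = rng.lognormal(0, 1.5, 300)
        expr /= expr.sum()
        thresholds = [0, 5, 50, 500]
        curves = {}
        for depth in (2_000, 50_000):
            draws = rng.multinomial(depth, expr)
            genes = {f"g{i}": int(n) for i, n in enumerate(draws) if n}
            c = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": depth}, genes)
            curves[depth] = detection_curve(c, thresholds).genes_detected
        assert all(hi >= lo for hi, lo in zip(curves[50_000], curves[2_000]))


class TestCorrelation:
    def _sampled(self, expr, n, seed, sample_id):
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(n, expr)
        genes = {f"g{i}": int(c) for i, c in enumerate(draws) if c}
        return counts_from({"rRNA": 0, "tRNA": 0, "mRNA": n}, genes, sample_id)

    def test_self_correlation_is_one(self):
        c = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 6}, {"g1": 1, "g2": 2, "g3": 3})
        assert expression_correlation(c, c).r == pytest.approx(1.0)

    def test_replicates_highly_correlated(self):
        rng = np.random.default_rng(4)
        expr = rng.lognormal(0, 1.2, 400)
        expr /= expr.sum()
        a = self._sampled(expr, 100_000, 10, "a")
        b = self._sampled(expr, 100_000, 11, "b")
        res = expression_correlation(a, b)
        assert res.defined and res.r > 0.95

    def test_independent_vectors_near_permutation_null(self):
        rng = np.random.default_rng(8)
        e1 = rng.lognormal(0, 1.2, 400); e1 /= e1.sum()
        e2 = rng.lognormal(0, 1.2, 400); e2 /= e2.sum()
        a = self._sampled(e1, 100_000, 20, "a")
        b = self._sampled(e2, 100_000, 21, "b")
        observed = abs(expression_correlation(a, b).r)
        # permutation null for |r|: shuffle one sample's gene labels
        genes = sorted(a.detected_genes() | b.detected_genes())
        xa = np.log10(np.array([a.rpm(g) for g in genes]) + 1)
        xb = np.log10(np.array([b.rpm(g) for g in genes]) + 1)
        null = []
        for seed in range(200):
            perm = np.random.default_rng(seed).permutation(len(xb))
            null.append(abs(np.corrcoef(xa, xb[perm])[0, 1]))
        assert observed < np.quantile(null, 0.99) + 0.1

    def test_zero_variance_flagged(self):
        a = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 3}, {"g1": 1, "g2": 1, "g3": 1})
        b = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 6}, {"g1": 1, "g2": 2, "g3": 3})
        assert not expression_correlation(a, b).defined

    def test_too_few_genes_rejected(self):
        a = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 1}, {"g1": 1})
        with pytest.raises(ValueError):
            expression_correlation(a, a)


class TestOverlap:
    def test_disjoint_and_subset_cases(self):
        a = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 2}, {"g1": 1, "g2": 1})
        b = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 2}, {"g3": 1, "g4": 1})
        assert detection_overlap(a, b) == (2, 2, 0)
        sub = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 1}, {"g1": 1})
        assert detection_overlap(sub, a) == (0, 1, 1)

    def test_planted_overlap_recovered(self):
        a = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 30}, {f"g{i}": 1 for i in range(30)})
        b = counts_from({"rRNA": 0, "tRNA": 0, "mRNA": 25}, {f"g{i}": 1 for i in range(10, 35)})
        only_a, only_b, both = detection_overlap(a, b)
        assert (only_a, only_b, both) == (10, 5, 20)
        assert only_a + only_b + both == 35

    def test_pooled_replicates_sum_counts(self):
        a = counts_from({"rRNA": 1, "tRNA": 0, "mRNA": 2}, {"g1": 2}, "a")
        b = counts_from({"rRNA": 0, "tRNA": 1, "mRNA": 3}, {"g1": 1, "g2": 2}, "b")
        pooled = pool_counts([a, b])
        assert pooled.total_mapped == 7
        assert pooled.per_gene == {"g1": 3, "g2": 2}
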