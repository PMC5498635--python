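"""Gold-standard construction, F1 metrics and validation procedures."""

import numpy as np
import pandas as pd
import pytest

from chromacc.gene_labeling import AccessibilityLabels, assign_accessibility
from chromacc.gold_standard_eval import (
    ConfusionCounts,
    GoldStandard,
    build_accessible_set,
    build_gold_standard,
    build_inaccessible_set,
    confusion,
    f1_score,
    f1_threshold_sweep,
    loo_validation,
    misclassification_profile,
    pearson_correlation,
    replicate_concordance,
)
from chromacc.hierarchical_model import fit_hierarchical
from chromacc.io_formats import ChromHmmSegment, GeneRecord, GenomicInterval
from chromacc.synthetic_data import SimulationParams, simulate_cell_type

from conftest import TINY_CONFIG, make_tiny_training_set


def _genes(n=20, spacing=10_000, length=4000):
    return [
        GeneRecord(f"g{i}", "chr1", i * spacing, i * spacing + length, "+")
        for i in range(n)
    ]


def _labels(mapping):
    return AccessibilityLabels(labels=pd.Series(mapping), source="predicted")


def _peak_inside(gene, offset=1500, length=200):
    return GenomicInterval(gene.chrom, gene.start + offset, gene.start + offset + length)


class TestAccessibleSet:
    def test_union_over_experiments(self):
        genes = _genes(3)
        sets = [[_peak_inside(genes[0])], [], [_peak_inside(genes[2])]]
        acc = build_accessible_set(sets, genes)
        assert acc == {"g0", "g2"}

    def test_equals_per_set_union_oracle(self):
        rng = np.random.default_rng(0)
        genes = _genes(20)
        sets = []
        for _ in range(3):
            chosen = rng.choice(20, size=5, replace=False)
            sets.append([_peak_inside(genes[i]) for i in chosen])
        acc = build_accessible_set(sets, genes)
        oracle = frozenset().union(
            *(assign_accessibility(s, genes).open_genes for s in sets)
        )
        assert acc == oracle


class TestInaccessibleSet:
    def _segment(self, gene, marks, state="Het"):
        return ChromHmmSegment(
            interval=_peak_inside(gene, length=500), state=state, marks=frozenset(marks)
        )

    def test_h3k9me3_alone_qualifies(self):
        genes = _genes(2)
        segs = [self._segment(genes[0], {"H3K9me3"})]
        assert build_inaccessible_set(segs, genes) == {"g0"}

    def test_three_mark_combination_qualifies(self):
        genes = _genes(2)
        segs = [self._segment(genes[1], {"H3K36me3", "H3K4me3", "H3K9me3"}, "ZNF/Rpts")]
        assert build_inaccessible_set(segs, genes) == {"g1"}

    def test_other_marks_do_not_qualify(self):
        genes = _genes(2)
        segs = [self._segment(genes[0], {"H3K27me3"})]
        assert build_inaccessible_set(segs, genes) == frozenset()

    def test_superset_matching_flag(self):
        genes = _genes(2)
        segs = [self._segment(genes[0], {"H3K9me3", "H3K27me3"})]
        assert build_inaccessible_set(segs, genes) == frozenset()
        assert build_inaccessible_set(segs, genes, superset_match=True) == {"g0"}


class TestGoldStandard:
    def test_conflicts_quarantined(self):
        gs = build_gold_standard({"a", "b"}, {"b", "c"})
        assert gs.accessible == {"a"}
        assert gs.inaccessible == {"c"}
        assert gs.conflicts == {"b"}

    def test_disjoint_inputs_unchanged(self):
        gs = build_gold_standard({"a"}, {"b"})
        assert (gs.accessible, gs.inaccessible, gs.conflicts) == ({"a"}, {"b"}, frozenset())

    def test_conservation(self):
        gs = build_gold_standard({"a", "b", "c"}, {"c", "d"})
        assert len(gs.accessible) + len(gs.inaccessible) + len(gs.conflicts) == 4

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_gold_standard(set(), set())


class TestConfusionAndF1:
    def test_perfect_prediction(self):
        gold = GoldStandard(
            accessible=frozenset(f"a{i}" for i in range(10)),
            inaccessible=frozenset(f"i{i}" for i in range(10)),
        )
        pred = _labels({**{f"a{i}": True for i in range(10)}, **{f"i{i}": False for i in range(10)}})
        c = confusion(pred, gold)
        assert (c.TP, c.TN, c.FP, c.FN) == (10, 10, 0, 0)
        assert f1_score(c).f1 == 1.0

    def test_all_open_prediction(self):
        gold = GoldStandard(accessible=frozenset({"a"}), inaccessible=frozenset({"b", "c"}))
        pred = _labels({"a": True, "b": True, "c": True})
        c = confusion(pred, gold)
        assert (c.FN, c.FP) == (0, 2)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(50)]
        in_acc = rng.random(50) < 0.5
        pred_open = rng.random(50) < 0.5
        gold = GoldStandard(
            accessible=frozenset(np.array(ids)[in_acc]),
            inaccessible=frozenset(np.array(ids)[~in_acc]),
        )
        pred = _labels(dict(zip(ids, pred_open)))
        c = confusion(pred, gold)
        tally = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
        for g, acc, po in zip(ids, in_acc, pred_open):
            tally["TP" if acc and po else "FP" if po else "FN" if acc else "TN"] += 1
        assert (c.TP, c.FP, c.FN, c.TN) == tuple(tally[k] for k in ("TP", "FP", "FN", "TN"))

    def test_gold_gene_without_prediction_is_error(self):
        gold = GoldStandard(accessible=frozenset({"a", "z"}), inaccessible=frozenset({"b"}))
        pred = _labels({"a": True, "b": False})
        with pytest.raises(ValueError):
            confusion(pred, gold)

    def test_f1_formula_and_conventions(self):
        r = f1_score(ConfusionCounts(TP=1, FP=1, FN=0, TN=5))
        assert r.precision == 0.5 and r.recall == 1.0
        assert r.f1 == pytest.approx(2 / 3)
        assert f1_score(ConfusionCounts(TP=0, FP=0, FN=0, TN=5)).f1 == 0.0

    def test_f1_harmonic_mean_identity(self):
        r = f1_score(ConfusionCounts(TP=30, FP=20, FN=10, TN=40))
        assert r.f1 == pytest.approx(2 / (1 / r.precision + 1 / r.recall))


class TestThresholdSweep:
    GOLD = GoldStandard(
        accessible=frozenset({"a1", "a2"}), inaccessible=frozenset({"i1", "i2"})
    )
    EXPR = pd.Series({"a1": 5.0, "a2": 0.05, "i1": 0.0, "i2": 0.2})
    # a2 misclassified; errors sit below 0.1 FPKM
    PRED = _labels({"a1": True, "a2": False, "i1": False, "i2": False})

    def test_low_cutoff_identical_to_unrestricted(self):
        res = f1_threshold_sweep(self.PRED, self.GOLD, self.EXPR, [0.0])
        full = f1_score(confusion(self.PRED, self.GOLD))
        assert res[0].f1 == full.f1

    def test_cutoff_above_max_is_undefined(self):
        res = f1_threshold_sweep(self.PRED, self.GOLD, self.EXPR, [100.0])
        assert res[0].undefined

    def test_f1_improves_once_low_expression_errors_excluded(self):
        res = f1_threshold_sweep(self.PRED, self.GOLD, self.EXPR, [0.0, 0.1])
        assert res[1].f1 == 1.0
        assert res[0].f1 < res[1].f1

    def test_evaluated_gene_count_non_increasing(self):
        cutoffs = [0.0, 0.01, 0.1, 1.0]
        res = f1_threshold_sweep(self.PRED, self.GOLD, self.EXPR, cutoffs)
        sizes = [r.counts.TP + r.counts.FP + r.counts.FN + r.counts.TN for r in res]
        assert sizes == sorted(sizes, reverse=True)

    def test_unsorted_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            f1_threshold_sweep(self.PRED, self.GOLD, self.EXPR, [1.0, 0.1])


class TestMisclassificationProfile:
    def _setup(self):
        genes = [
            GeneRecord("a1", "chr1", 0, 1000, "+", gene_type="protein_coding", gc_content=0.4),
            GeneRecord("a2", "chr2", 0, 1000, "+", gene_type="lincRNA", gc_content=0.6),
            GeneRecord("i1", "chr1", 5000, 6000, "+", gene_type="protein_coding", gc_content=0.5),
            GeneRecord("i2", "chr2", 5000, 6000, "+", gene_type="lincRNA", gc_content=0.5),
        ]
        gold = GoldStandard(
            accessible=frozenset({"a1", "a2"}), inaccessible=frozenset({"i1", "i2"})
        )
        expr = pd.Series({"a1": 5.0, "a2": 1.0, "i1": 0.0, "i2": 0.0})
        return genes, gold, expr

    def test_perfect_prediction_all_zero(self):
        genes, gold, expr = self._setup()
        pred = _labels({"a1": True, "a2": True, "i1": False, "i2": False})
        prof = misclassification_profile(pred, gold, genes, expr, "chromosome")
        assert (prof["frac_misclassified"] == 0).all()

    def test_errors_localized_to_one_chromosome(self):
        genes, gold, expr = self._setup()
        pred = _labels({"a1": True, "a2": False, "i1": False, "i2": True})
        prof = misclassification_profile(pred, gold, genes, expr, "chromosome")
        assert prof.loc["chr2", "frac_misclassified"] == 1.0
        assert prof.loc["chr1", "frac_misclassified"] == 0.0

    @pytest.mark.parametrize("attribute", ["gene_type", "expression_bin", "gc"])
    def test_matches_counting_oracle(self, attribute):
        genes, gold, expr = self._setup()
        pred = _labels({"a1": True, "a2": False, "i1": False, "i2": True})
        prof = misclassification_profile(pred, gold, genes, expr, attribute)
        assert int(prof["n_misclassified"].sum()) == 2
        assert int(prof["n_gold"].sum()) == 4
        assert prof["error_share"].sum() == pytest.approx(1.0)

    def test_missing_gc_named(self):
        genes, gold, expr = self._setup()
        genes[0] = GeneRecord("a1", "chr1", 0, 1000, "+", gene_type="protein_coding")
        pred = _labels({"a1": True, "a2": True, "i1": False, "i2": False})
        with pytest.raises(ValueError, match="gc"):
            misclassification_profile(pred, gold, genes, expr, "gc")


class TestPearson:
    def test_identity_and_inversion(self):
        x = [1.0, 2.0, 4.0, 8.0]
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_five_point_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson_correlation(x, y) == pytest.approx(num / den)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestValidationProcedures:
    def test_loo_duplicated_samples_perfect_correlation(self):
        _, _, training = make_tiny_training_set(n_samples=1, seed=6)
        trio = [training[0]] * 3
        corr = loo_validation(trio, TINY_CONFIG, partition_by="cell_type")
        assert all(c > 0.999 for c in corr.values())

    def test_chromosome_mode_returns_one_fold_per_chromosome(self):
        _, samples, training = make_tiny_training_set(n_samples=3, seed=7)
        corr = loo_validation(
            training, TINY_CONFIG, partition_by="chromosome", genes=samples[0].genes
        )
        assert set(corr) == {"chr1", "chr2"}

    def test_replicate_concordance_identity_and_order_invariance(self):
        _, _, training = make_tiny_training_set(n_samples=2, seed=8)
        model = fit_hierarchical(training, TINY_CONFIG)
        e = training[0][0]
        assert replicate_concordance(model, e, e) == pytest.approx(1.0)
        shuffled = e.sample(frac=1.0, random_state=0)
        assert replicate_concordance(model, e, shuffled) == pytest.approx(1.0)

    def test_concordance_rises_as_replicate_noise_vanishes(self):
        _, _, training = make_tiny_training_set(n_samples=2, seed=9)
        model = fit_hierarchical(training, TINY_CONFIG)
        e = training[0][0]
        rng = np.random.default_rng(1)
        noise = rng.normal(0.0, 1.0, size=len(e))
        corr = [
            replicate_concordance(model, e, e * np.exp(sigma * noise))
            for sigma in (0.8, 0.2, 0.05)
        ]
        assert corr == sorted(corr)
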