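"""Cross-validation planning, confusion metrics with degenerate conventions,
AUC formulations, residue- vs protein-based aggregation, rank comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnaiface.evaluation import (
    ConfusionCounts,
    ProteinResult,
    aggregate_protein_based,
    aggregate_residue_based,
    average_ranks,
    compute_metrics,
    mann_whitney_auc,
    roc_pr_auc,
    run_cv,
    split_folds,
)
from rnaiface.features import EncodingConfig
from rnaiface.models import TrainConfig


class TestSplitFolds:
    def test_partition_properties(self):
        keys = [f"c{i}" for i in range(10)]
        plan = split_folds(keys, k=5, seed=1)
        assert [len(f) for f in plan.folds] == [2] * 5
        flat = sorted(k for f in plan.folds for k in f)
        assert flat == sorted(keys)

    def test_same_seed_identical(self):
        keys = list("abcdefghijk")
        assert split_folds(keys, 5, seed=9).folds == split_folds(keys, 5, seed=9).folds

    def test_uneven_sizes(self):
        plan = split_folds(range(11), k=5, seed=0)
        assert sorted(len(f) for f in plan.folds) == [2, 2, 2, 2, 3]

    def test_too_many_folds_raises(self):
        with pytest.raises(ValueError):
            split_folds(range(3), k=5, seed=0)


class TestComputeMetrics:
    def test_degenerate_no_positive_predictions(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=5))
        assert m.specificity == 1.0
        assert m.sensitivity == 0.0
        assert m.fmeasure == 0.0
        assert m.mcc == 0.0

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (m.specificity, m.sensitivity, m.fmeasure, m.mcc) == (1, 1, 1, 1)

    def test_hand_computed_mcc(self):
        m = compute_metrics(ConfusionCounts(tp=60, fp=20, tn=15, fn=5))
        assert m.mcc == pytest.approx(800 / math.sqrt(65 * 80 * 35 * 20))
        assert m.mcc == pytest.approx(0.419, abs=5e-4)

    @given(
        tp=st.integers(0, 200),
        tn=st.integers(0, 200),
        fp=st.integers(0, 200),
        fn=st.integers(0, 200),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_direct_formula_evaluation(self, tp, tn, fp, fn):
        m = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        assert m.specificity == pytest.approx(prec)
        assert m.sensitivity == pytest.approx(rec)
        if prec + rec > 0:
            assert m.fmeasure == pytest.approx(2 * prec * rec / (prec + rec))
        else:
            assert m.fmeasure == 0.0
        denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
        expected_mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
        assert m.mcc == pytest.approx(expected_mcc)
        assert 0 <= m.specificity <= 1 and 0 <= m.sensitivity <= 1
        assert -1 <= m.mcc <= 1

    def test_adding_correct_positive_never_hurts(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            base = compute_metrics(ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn)))
            more = compute_metrics(
                ConfusionCounts(tp=int(tp) + 1, tn=int(tn), fp=int(fp), fn=int(fn))
            )
            assert more.sensitivity >= base.sensitivity - 1e-12
            assert more.mcc >= base.mcc - 1e-12


class TestAuc:
    def test_exhaustive_pair_counting_example(self):
        labels = [1, 1, 0, 0]
        scores = [0.9, 0.4, 0.6, 0.2]
        assert mann_whitney_auc(scores, labels) == 0.75  # 3 wins of 4 pairs

    def test_perfect_separation(self):
        assert mann_whitney_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half_credit(self):
        assert mann_whitney_auc([1.0] * 8, [1, 1, 1, 0, 0, 0, 0, 0]) == 0.5

    def test_matches_exhaustive_pair_loop(self, rng):
        scores = rng.choice(np.round(rng.normal(size=10), 1), size=60)  # force ties
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        wins = half = 0
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        for sp in pos:
            for sn in neg:
                if sp > sn:
                    wins += 1
                elif sp == sn:
                    half += 1
        expected = (wins + 0.5 * half) / (len(pos) * len(neg))
        assert mann_whitney_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_equals_trapezoidal_roc_area(self, rng):
        for _ in range(20):
            scores = np.round(rng.normal(size=50), 1)
            labels = rng.integers(0, 2, size=50)
            labels[:2] = [0, 1]
            roc, pr, auc = roc_pr_auc(scores, labels)
            trap = np.trapezoid(roc[:, 1], roc[:, 0])
            assert auc == pytest.approx(trap, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        labels[:2] = [0, 1]
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([1, 2], [1, 1])


def protein(fold, key, tp, fp, fn, tn, scores=None, labels=None):
    if scores is None:
        # synthesize scores consistent with nothing in particular; both classes
        labels = [1] * (tp + fn) + [0] * (fp + tn)
        scores = list(np.linspace(1, 0, len(labels)))
    return ProteinResult(
        chain_key=key,
        fold=fold,
        counts=ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn),
        scores=np.asarray(scores, float),
        labels=np.asarray(labels, int),
    )


class TestAggregation:
    def _fixture(self):
        a = protein(0, "A", tp=5, fp=5, fn=0, tn=10)
        b = protein(0, "B", tp=0, fp=0, fn=5, tn=15)
        return [a, b]

    def test_residue_based_pools_counts(self):
        report = aggregate_residue_based(self._fixture())
        # pooled: TP=5 FP=5 FN=5 TN=25
        assert report.overall.specificity == pytest.approx(0.5)
        assert report.overall.sensitivity == pytest.approx(0.5)

    def test_protein_based_averages_metrics(self):
        report = aggregate_protein_based(self._fixture())
        # A: spec 0.5, sens 1; B: spec 1 (degenerate), sens 0
        assert report.overall.specificity == pytest.approx(0.75)
        assert report.overall.sensitivity == pytest.approx(0.5)

    def test_zero_positive_protein_contributes_degenerate_values(self):
        b = protein(0, "B", tp=0, fp=0, fn=5, tn=15)
        report = aggregate_protein_based([b])
        assert report.overall.specificity == 1.0
        assert report.overall.fmeasure == 0.0
        assert report.overall.mcc == 0.0

    def test_one_protein_per_fold_aggregations_coincide(self, rng):
        results = []
        for fold in range(4):
            tp, fp, fn, tn = (int(v) + 1 for v in rng.integers(0, 20, size=4))
            labels = rng.integers(0, 2, size=30)
            labels[:2] = [0, 1]
            scores = rng.normal(size=30)
            results.append(
                ProteinResult(
                    chain_key=f"c{fold}",
                    fold=fold,
                    counts=ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn),
                    scores=scores,
                    labels=labels,
                )
            )
        res = aggregate_residue_based(results)
        prot = aggregate_protein_based(results)
        assert res.overall == prot.overall
        assert res.overall_auc == pytest.approx(prot.overall_auc)

    def test_duplicating_protein_counts_leaves_residue_metrics_unchanged(self):
        a = protein(0, "A", tp=5, fp=5, fn=0, tn=10)
        doubled = protein(0, "A2", tp=10, fp=10, fn=0, tn=20)
        r1 = aggregate_residue_based([a])
        r2 = aggregate_residue_based([a, doubled])
        assert r1.overall == r2.overall

    def test_identical_proteins_protein_equals_residue(self):
        a = protein(0, "A", tp=5, fp=5, fn=2, tn=10)
        b = protein(0, "B", tp=5, fp=5, fn=2, tn=10)
        res = aggregate_residue_based([a, b])
        prot = aggregate_protein_based([a, b])
        assert res.overall == prot.overall

    def test_single_class_protein_excluded_from_auc(self):
        a = protein(0, "A", tp=5, fp=5, fn=2, tn=10)
        only_neg = ProteinResult(
            chain_key="B",
            fold=0,
            counts=ConfusionCounts(tp=0, fp=3, fn=0, tn=7),
            scores=np.linspace(0, 1, 10),
            labels=np.zeros(10, int),
        )
        report = aggregate_protein_based([a, only_neg])
        assert report.per_fold[0].n_auc_excluded == 1
        assert report.overall_auc is not None


class TestRunCv:
    def test_folds_chain_disjoint_and_deterministic(self, bench):
        ds, profiles = bench["dataset"], bench["profiles"]
        config = EncodingConfig(window=11)
        tc = TrainConfig(algorithm="nb", balance=False)
        r1, p1 = run_cv(ds, profiles, config, tc, k=5, seed=3)
        r2, p2 = run_cv(ds, profiles, config, tc, k=5, seed=3)
        assert r1.as_dict() == r2.as_dict()
        assert p1.as_dict() == p2.as_dict()
        # every chain scored exactly once over all folds
        plan = split_folds(sorted(c.chain_key for c in ds.chains), k=5, seed=3)
        flat = [k for f in plan.folds for k in f]
        assert len(flat) == len(set(flat)) == len(ds.chains)

    def test_planted_signal_recovered_by_nb(self, bench):
        ds, profiles = bench["dataset"], bench["profiles"]
        res, prot = run_cv(
            ds, profiles, EncodingConfig(window=11), TrainConfig(algorithm="nb", balance=False),
            k=5, seed=3,
        )
        assert res.overall_auc > 0.9
        assert prot.overall_auc > 0.9

    def test_fold_with_single_class_training_raises(self):
        from test_labeling import make_chain
        from rnaiface.labeling import make_dataset

        chains = [make_chain([0] * 10, key=("t", c)) for c in "ABCDE"]
        ds = make_dataset(chains, "sequence")
        with pytest.raises(ValueError, match="single class"):
            run_cv(ds, None, EncodingConfig(encoding="IDSeq", window=3),
                   TrainConfig(algorithm="nb", balance=False), k=5, seed=0)


class TestAverageRanks:
    # AUC rows for the nine sequence-window methods on the three benchmark
    # datasets, with their published tie-averaged ranks
    TABLE = {
        "RB106Seq": ([0.74, 0.72, 0.73, 0.76, 0.78, 0.80, 0.75, 0.76, 0.78],
                     [7, 9, 8, 4.5, 2.5, 1, 6, 4.5, 2.5]),
        "RB144Seq": ([0.73, 0.72, 0.73, 0.74, 0.79, 0.80, 0.75, 0.77, 0.79],
                     [7.5, 9, 7.5, 6, 2.5, 1, 5, 4, 2.5]),
        "RB198Seq": ([0.72, 0.72, 0.72, 0.73, 0.78, 0.80, 0.74, 0.77, 0.78],
                     [8, 8, 8, 6, 2.5, 1, 5, 4, 2.5]),
    }

    def _scores(self):
        methods = ["IDSeq_NB", "IDSeq_LK", "IDSeq_RBFK", "PSSMSeq_NB", "PSSMSeq_LK",
                   "PSSMSeq_RBFK", "SmoPSSMSeq_NB", "SmoPSSMSeq_LK", "SmoPSSMSeq_RBFK"]
        return pd.DataFrame(
            {m: [self.TABLE[d][0][i] for d in self.TABLE] for i, m in enumerate(methods)},
            index=list(self.TABLE),
        )

    def test_reproduces_published_tie_averaged_ranks(self):
        result = average_ranks(self._scores())
        for d, (_, expected) in self.TABLE.items():
            assert result.ranks.loc[d].tolist() == expected

    def test_average_ranks_match_published_row(self):
        result = average_ranks(self._scores())
        expected = [7.5, 8.7, 7.8, 5.5, 2.5, 1.0, 5.3, 4.2, 2.5]
        assert [round(v, 1) for v in result.average] == expected

    def test_total_tie_gives_midrank(self):
        df = pd.DataFrame({f"m{i}": [0.5] for i in range(5)}, index=["d"])
        result = average_ranks(df)
        assert (result.ranks.loc["d"] == 3.0).all()

    def test_rank_conservation(self, rng):
        df = pd.DataFrame(rng.random((4, 6)), columns=[f"m{i}" for i in range(6)])
        result = average_ranks(df)
        np.testing.assert_allclose(result.ranks.sum(axis=1), 6 * 7 / 2)

    def test_missing_cell_raises(self):
        df = pd.DataFrame({"a": [0.5, np.nan], "b": [0.4, 0.6]})
        with pytest.raises(ValueError, match="missing"):
            average_ranks(df)
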