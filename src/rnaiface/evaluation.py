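"""Sequence-based cross-validation and performance evaluation.

Folds are whole protein chains (never windows), so training and test sets are
disjoint at the sequence level. Confusion-count metrics follow the
precision-style conventions used throughout this problem area:

* Specificity = TP / (TP + FP) (precision), with the degenerate convention
  Specificity = 1 when TP + FP = 0;
* Sensitivity = TP / (TP + FN) (recall / TPR);
* F-measure and MCC are 0 whenever a denominator vanishes.

Two aggregations are reported. Residue-based evaluation pools confusion
counts over the proteins of each fold before computing metrics, then averages
over folds. Protein-based evaluation computes metrics per protein, averages
them within each fold, then averages over folds; it is the stricter view and
is sensitive to proteins with no positive predictions.

AUC uses the Mann-Whitney rank formulation (ties get half credit), which
equals the trapezoidal area under the threshold-swept ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import EncodingConfig, encode_chain, instances_to_arrays, undersample
from .labeling import Dataset
from .models import TrainConfig, score, train_nb, train_svm

__all__ = [
    "FoldPlan",
    "ConfusionCounts",
    "Metrics",
    "FoldReport",
    "MetricsReport",
    "ProteinResult",
    "RankTable",
    "split_folds",
    "compute_metrics",
    "mann_whitney_auc",
    "roc_pr_auc",
    "aggregate_residue_based",
    "aggregate_protein_based",
    "run_cv",
    "average_ranks",
]


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    k: int
    folds: list[list]  # chain keys per fold
    seed: int

    def __post_init__(self) -> None:
        flat = [key for fold in self.folds for key in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("folds are not disjoint")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes {sizes} differ by more than 1")


def split_folds(chain_keys: Sequence, k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded permutation + round-robin assignment into k near-equal folds."""
    keys = list(chain_keys)
    if k > len(keys):
        raise ValueError(f"cannot split {len(keys)} chains into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    folds: list[list] = [[] for _ in range(k)]
    for i, idx in enumerate(order):
        folds[i % k].append(keys[idx])
    return FoldPlan(k=k, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class Metrics:
    specificity: float
    sensitivity: float
    fpr: float
    fmeasure: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "fpr": self.fpr,
            "fmeasure": self.fmeasure,
            "mcc": self.mcc,
        }


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Precision-style specificity, sensitivity, F, MCC with degenerate rules.

    TP + FP = 0 gives Specificity 1 (no positive predictions to be wrong
    about); any vanishing denominator gives F = 0 or MCC = 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    specificity = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0
    denom_f = specificity + sensitivity
    fmeasure = 2.0 * specificity * sensitivity / denom_f if denom_f > 0 else 0.0
    denom_m = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom_m) if denom_m > 0 else 0.0
    return Metrics(
        specificity=specificity,
        sensitivity=sensitivity,
        fpr=fpr,
        fmeasure=fmeasure,
        mcc=mcc,
    )


def _mean_metrics(items: Sequence[Metrics]) -> Metrics:
    arr = np.array([[m.specificity, m.sensitivity, m.fpr, m.fmeasure, m.mcc] for m in items])
    return Metrics(*arr.mean(axis=0))


# ---------------------------------------------------------------------------
# ROC / PR / AUC
# ---------------------------------------------------------------------------

def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic; tied scores receive half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_pr_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve, PR curve and AUC swept over all distinct score thresholds.

    Returns (roc, pr, auc) where roc is an array of (FPR, TPR) points, pr an
    array of (recall, precision) points.
    """
    from sklearn.metrics import precision_recall_curve, roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    precision, recall, _ = precision_recall_curve(labels, scores)
    roc = np.column_stack((fpr, tpr))
    pr = np.column_stack((recall[::-1], precision[::-1]))
    return roc, pr, mann_whitney_auc(scores, labels)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class ProteinResult:
    chain_key: tuple
    fold: int
    counts: ConfusionCounts
    scores: np.ndarray
    labels: np.ndarray


@dataclass
class FoldReport:
    fold: int
    metrics: Metrics
    auc: float | None
    roc: np.ndarray | None = None
    pr: np.ndarray | None = None
    n_auc_excluded: int = 0


@dataclass
class MetricsReport:
    aggregation: str  # "residue" | "protein"
    per_fold: list[FoldReport]
    overall: Metrics
    overall_auc: float | None
    pooled_auc: float | None = None  # residue aggregation, global pooling across folds

    def as_dict(self) -> dict:
        return {
            "aggregation": self.aggregation,
            "overall": {**self.overall.as_dict(), "auc": self.overall_auc},
            "pooled_auc": self.pooled_auc,
            "per_fold": [
                {
                    "fold": f.fold,
                    **f.metrics.as_dict(),
                    "auc": f.auc,
                    "n_auc_excluded": f.n_auc_excluded,
                    "roc": None if f.roc is None else f.roc.tolist(),
                    "pr": None if f.pr is None else f.pr.tolist(),
                }
                for f in self.per_fold
            ],
        }


def _group_by_fold(results: Sequence[ProteinResult]) -> dict[int, list[ProteinResult]]:
    grouped: dict[int, list[ProteinResult]] = {}
    for r in results:
        grouped.setdefault(r.fold, []).append(r)
    if not grouped:
        raise ValueError("no per-protein results to aggregate")
    for fold, items in grouped.items():
        if not items:
            raise ValueError(f"fold {fold} is empty")
    return grouped


def aggregate_residue_based(
    results: Sequence[ProteinResult], keep_curves: bool = False
) -> MetricsReport:
    """Pool counts over the proteins of each fold, then average over folds.

    Fold-level ROC/AUC are computed on the pooled scores of the fold; a
    globally pooled AUC across all folds is reported alongside.
    """
    grouped = _group_by_fold(results)
    fold_reports = []
    for fold in sorted(grouped):
        items = grouped[fold]
        pooled = ConfusionCounts()
        for r in items:
            pooled = pooled + r.counts
        scores = np.concatenate([r.scores for r in items])
        labels = np.concatenate([r.labels for r in items])
        if len(np.unique(labels)) == 2:
            roc, pr, auc = roc_pr_auc(scores, labels)
        else:
            roc = pr = None
            auc = None
        fold_reports.append(
            FoldReport(
                fold=fold,
                metrics=compute_metrics(pooled),
                auc=auc,
                roc=roc if keep_curves else None,
                pr=pr if keep_curves else None,
            )
        )
    aucs = [f.auc for f in fold_reports if f.auc is not None]
    all_scores = np.concatenate([r.scores for r in results])
    all_labels = np.concatenate([r.labels for r in results])
    pooled_auc = (
        mann_whitney_auc(all_scores, all_labels)
        if len(np.unique(all_labels)) == 2
        else None
    )
    return MetricsReport(
        aggregation="residue",
        per_fold=fold_reports,
        overall=_mean_metrics([f.metrics for f in fold_reports]),
        overall_auc=float(np.mean(aucs)) if aucs else None,
        pooled_auc=pooled_auc,
    )


def aggregate_protein_based(results: Sequence[ProteinResult]) -> MetricsReport:
    """Per-protein metrics averaged within each fold, then across folds.

    Per-protein AUC is defined only when the protein has residues of both
    classes; single-class proteins are excluded from the fold's AUC average
    and counted in ``n_auc_excluded``.
    """
    grouped = _group_by_fold(results)
    fold_reports = []
    for fold in sorted(grouped):
        items = grouped[fold]
        metrics = [compute_metrics(r.counts) for r in items]
        aucs = []
        excluded = 0
        for r in items:
            if len(np.unique(r.labels)) == 2:
                aucs.append(mann_whitney_auc(r.scores, r.labels))
            else:
                excluded += 1
        fold_reports.append(
            FoldReport(
                fold=fold,
                metrics=_mean_metrics(metrics),
                auc=float(np.mean(aucs)) if aucs else None,
                n_auc_excluded=excluded,
            )
        )
    aucs = [f.auc for f in fold_reports if f.auc is not None]
    return MetricsReport(
        aggregation="protein",
        per_fold=fold_reports,
        overall=_mean_metrics([f.metrics for f in fold_reports]),
        overall_auc=float(np.mean(aucs)) if aucs else None,
    )


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

def run_cv(
    dataset: Dataset,
    profiles,
    enc_config: EncodingConfig,
    train_config: TrainConfig,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.0,
) -> tuple[MetricsReport, MetricsReport]:
    """Sequence-based k-fold cross-validation.

    Chains (never windows) are partitioned into folds; for each fold the
    classifier is trained on the other folds' residues (balancing, when
    configured, applies to training data only) and scores every residue of
    the held-out chains. Returns the residue-based and protein-based reports.
    """
    chains = {c.chain_key: c for c in dataset.chains}
    plan = split_folds(sorted(chains), k=k, seed=seed)

    # encode each chain once
    encoded: dict[tuple, list] = {}
    for key, chain in chains.items():
        profile = None
        if enc_config.channel == "pssm":
            if profiles is None or key not in profiles:
                raise ValueError(f"missing PSSM profile for chain {key}")
            profile = profiles[key]
        if enc_config.spatial and dataset.variant != "structure":
            raise ValueError(f"{enc_config.encoding} requires a structure-variant dataset")
        targets = [r.position for r in dataset.eligible_residues(chain)]
        encoded[key] = encode_chain(chain, profile, enc_config, targets)

    results: list[ProteinResult] = []
    for fold_idx, test_keys in enumerate(plan.folds):
        test_set = set(test_keys)
        train_instances = [
            inst for key, insts in encoded.items() if key not in test_set for inst in insts
        ]
        labels = {i.label for i in train_instances}
        if labels != {0, 1}:
            raise ValueError(f"fold {fold_idx}: training data has a single class")
        fold_seed = seed * 1009 + fold_idx
        if train_config.algorithm == "nb":
            if train_config.balance:
                train_instances = undersample(train_instances, seed=fold_seed)
            model = train_nb(train_instances)
        else:
            model = train_svm(
                train_instances,
                TrainConfig(
                    algorithm="svm",
                    kernel=train_config.kernel,
                    C=train_config.C,
                    balance=train_config.balance,
                    seed=fold_seed,
                ),
            )
        for key in test_keys:
            X, y, _ = instances_to_arrays(encoded[key])
            s = np.asarray(score(model, X), dtype=float)
            preds = (s >= threshold).astype(int)
            results.append(
                ProteinResult(
                    chain_key=key,
                    fold=fold_idx,
                    counts=ConfusionCounts.from_labels(y, preds),
                    scores=s,
                    labels=y,
                )
            )
    return aggregate_residue_based(results), aggregate_protein_based(results)


# ---------------------------------------------------------------------------
# Rank comparison
# ---------------------------------------------------------------------------

@dataclass
class RankTable:
    scores: pd.DataFrame  # rows = datasets, columns = methods
    ranks: pd.DataFrame  # tie-averaged, 1 = best (highest score)
    average: pd.Series  # mean rank per method

    def __post_init__(self) -> None:
        n = self.scores.shape[1]
        expected = n * (n + 1) / 2.0
        sums = self.ranks.sum(axis=1)
        if not np.allclose(sums, expected):
            raise ValueError("per-dataset ranks do not sum to n(n+1)/2")


def average_ranks(score_table: pd.DataFrame) -> RankTable:
    """Tie-averaged ranks per dataset (rank 1 = best), averaged per method.

    ``score_table`` has one row per dataset and one column per method; a
    missing cell is an error.
    """
    if score_table.isna().any().any():
        raise ValueError("rank table has missing cells")
    ranks = score_table.rank(axis=1, ascending=False, method="average")
    return RankTable(scores=score_table, ranks=ranks, average=ranks.mean(axis=0))
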