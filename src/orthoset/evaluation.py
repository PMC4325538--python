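"""Scoring of posterior predictions against a binary gold standard.

Cells of the gene set x stimulus matrices are flattened and scored with
threshold-free rank metrics (AUROC by midrank/trapezoid, AUPR by step-wise
precision-recall) and fixed-threshold metrics (balanced accuracy and
Matthews correlation at posterior >= 0.5).  A stratified-resampling
robustness summary ranks competing prediction sets by their sum of ranks
over AUPR, Pearson and BAC on repeated 10% subsamples of the gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    matthews_corrcoef,
    roc_auc_score,
)

from orthoset.diffexpr import ActivationMatrix, GeneSetScoreMatrix
from orthoset.translator import PredictionMatrix

__all__ = ["EvaluationReport", "RobustnessSummary", "score", "robustness_resample"]


@dataclass
class EvaluationReport:
    aupr: float | None
    auroc: float | None
    pearson_binary: float | None
    pearson_continuous: float | None
    bac: float
    mcc: float
    n_positives: int
    n_negatives: int

    def to_dict(self) -> dict:
        return {
            "aupr": self.aupr,
            "auroc": self.auroc,
            "pearson_binary": self.pearson_binary,
            "pearson_continuous": self.pearson_continuous,
            "bac": self.bac,
            "mcc": self.mcc,
            "n_positives": self.n_positives,
            "n_negatives": self.n_negatives,
        }


@dataclass
class RobustnessSummary:
    method_names: list[str]
    rank_distribution: pd.DataFrame  # method x rank -> fraction of resamples
    frac_first: dict[str, float]
    resample_fraction: float
    n_resamples: int
    seed: int | None = None


def _align(predictions: PredictionMatrix, gold: ActivationMatrix) -> tuple[np.ndarray, np.ndarray]:
    g = gold.on
    p = predictions.p_on
    if not (set(g.index) <= set(p.index) and set(g.columns) <= set(p.columns)):
        raise ValueError("gold labels are not covered by the prediction matrix")
    p = p.loc[g.index, g.columns]
    return p.to_numpy(dtype=float).ravel(), g.to_numpy(dtype=bool).ravel()


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(stats.pearsonr(a, b)[0])


def _score_cells(p: np.ndarray, y: np.ndarray, cont: np.ndarray | None) -> EvaluationReport:
    both_classes = bool(y.any() and not y.all())
    auroc = float(roc_auc_score(y, p)) if both_classes else None
    aupr = float(average_precision_score(y, p)) if both_classes else None
    hard = p >= 0.5
    bac = float(balanced_accuracy_score(y, hard))
    mcc = float(matthews_corrcoef(y, hard))
    return EvaluationReport(
        aupr=aupr,
        auroc=auroc,
        pearson_binary=_safe_pearson(p, y.astype(float)),
        pearson_continuous=_safe_pearson(p, cont) if cont is not None else None,
        bac=bac,
        mcc=mcc,
        n_positives=int(y.sum()),
        n_negatives=int((~y).sum()),
    )


def score(
    predictions: PredictionMatrix,
    gold: ActivationMatrix,
    gold_fdr: GeneSetScoreMatrix | pd.DataFrame | None = None,
) -> EvaluationReport:
    """Score a posterior prediction matrix against binary gold labels.

    When the gold FDR matrix is available, a second Pearson correlation
    against the continuous ``1 - FDR`` scale is reported.  Metrics that are
    undefined on the input (single-class gold, constant predictions) are
    reported as missing rather than zero.
    """
    p, y = _align(predictions, gold)
    cont = None
    if gold_fdr is not None:
        fdr = gold_fdr.fdr if isinstance(gold_fdr, GeneSetScoreMatrix) else gold_fdr
        fdr = fdr.loc[gold.on.index, gold.on.columns]
        cont = 1.0 - fdr.to_numpy(dtype=float).ravel()
    return _score_cells(p, y, cont)


def _rank_methods(metric_rows: np.ndarray) -> np.ndarray:
    """Sum-of-ranks aggregation: rank per metric (1 = best, average ties),
    then rank methods by their metric-rank sum."""
    per_metric = np.stack(
        [stats.rankdata(-metric_rows[:, j]) for j in range(metric_rows.shape[1])], axis=1
    )
    sums = per_metric.sum(axis=1)
    return stats.rankdata(sums)


def robustness_resample(
    prediction_sets: dict[str, PredictionMatrix],
    gold: ActivationMatrix,
    fraction: float = 0.1,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> RobustnessSummary:
    """Rank prediction sets on repeated stratified subsamples of the gold cells.

    Each resample draws ``fraction`` of the gold cells preserving the
    positive/negative proportion, rescoring every method on AUPR, Pearson
    (binary) and BAC and ranking them by their sum of ranks.  The summary
    records the distribution of final ranks per method.
    """
    if len(prediction_sets) < 2:
        raise ValueError("need >= 2 prediction sets to rank")
    names = list(prediction_sets)
    flat = {}
    y_ref = None
    for name in names:
        p, y = _align(prediction_sets[name], gold)
        if y_ref is None:
            y_ref = y
        flat[name] = p
    pos_idx = np.flatnonzero(y_ref)
    neg_idx = np.flatnonzero(~y_ref)
    n_pos = int(round(fraction * len(pos_idx)))
    n_neg = int(round(fraction * len(neg_idx)))
    if n_pos < 1 or n_neg < 1:
        raise ValueError("resample fraction leaves a class empty")

    rng = np.random.default_rng(seed)
    n_methods = len(names)
    rank_counts = np.zeros((n_methods, n_methods))
    first_counts = np.zeros(n_methods)
    for _ in range(n_resamples):
        take = np.concatenate(
            [
                rng.choice(pos_idx, size=n_pos, replace=False),
                rng.choice(neg_idx, size=n_neg, replace=False),
            ]
        )
        y = y_ref[take]
        metrics = np.empty((n_methods, 3))
        for i, name in enumerate(names):
            p = flat[name][take]
            metrics[i, 0] = average_precision_score(y, p)
            r = _safe_pearson(p, y.astype(float))
            metrics[i, 1] = -np.inf if r is None else r
            metrics[i, 2] = balanced_accuracy_score(y, p >= 0.5)
        ranks = _rank_methods(metrics)
        best = ranks.min()
        for i in range(n_methods):
            rank_counts[i, int(np.floor(ranks[i])) - 1] += 1
            if ranks[i] == best:
                first_counts[i] += 1 / np.sum(ranks == best)
    dist = pd.DataFrame(
        rank_counts / n_resamples,
        index=names,
        columns=[f"rank_{k + 1}" for k in range(n_methods)],
    )
    return RobustnessSummary(
        method_names=names,
        rank_distribution=dist,
        frac_first={n: float(first_counts[i] / n_resamples) for i, n in enumerate(names)},
        resample_fraction=fraction,
        n_resamples=n_resamples,
        seed=seed,
    )
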