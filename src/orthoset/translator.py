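"""PCA + pooled-diagonal-Gaussian translation of gene-set activation.

The translator reduces the combined (train + test stimuli) rat NES matrix to
its leading principal components — stimuli are the samples, gene sets the
variables — and, per human gene set, fits a two-class Gaussian model on the
training-stimulus scores: one mean per class, a single pooled per-dimension
variance, zero covariances, empirical class priors.  The prediction for a
test stimulus is the posterior probability of the "on" class, averaged over
the classifiers obtained by leaving out each training stimulus in turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from orthoset.diffexpr import ActivationMatrix, GeneSetScoreMatrix

__all__ = [
    "PCAModel",
    "GenesetClassifier",
    "PredictionMatrix",
    "fit_pca",
    "train_genesets_classifier",
    "predict_posteriors",
    "predict_loo_ensemble",
    "select_n_components",
]

VARIANCE_FLOOR_FACTOR = 1e-8


@dataclass
class PCAModel:
    """Principal components of a gene set x stimulus score matrix.

    ``loadings`` columns are orthonormal directions over gene sets;
    ``scores`` are the projections of the (gene-set-mean-centred) stimuli.
    """

    loadings: np.ndarray  # (n_genesets, n_components)
    scores: np.ndarray  # (n_stimuli, n_components)
    component_variances: np.ndarray  # (n_components,)
    center: np.ndarray  # (n_genesets,)
    n_components_kept: int
    geneset_ids: list[str]
    stimulus_ids: list[str]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.component_variances) > 1e-9):
            raise ValueError("component variances must be non-increasing")

    def transform(self, nes: pd.DataFrame) -> np.ndarray:
        """Project new stimuli (columns of a gene set x stimulus matrix)
        onto the fitted components."""
        if list(nes.index) != self.geneset_ids:
            nes = nes.loc[self.geneset_ids]
        return (nes.to_numpy(dtype=float).T - self.center) @ self.loadings

    def extended(self, nes: pd.DataFrame) -> "PCAModel":
        """A copy whose score table additionally covers the given stimuli
        (projected, not refitted) — used by the non-transductive ablation."""
        new = [s for s in nes.columns if s not in set(self.stimulus_ids)]
        if not new:
            return self
        extra = self.transform(nes[new])
        return PCAModel(
            loadings=self.loadings,
            scores=np.vstack([self.scores, extra]),
            component_variances=self.component_variances,
            center=self.center,
            n_components_kept=self.n_components_kept,
            geneset_ids=self.geneset_ids,
            stimulus_ids=list(self.stimulus_ids) + new,
        )

    def scores_for(self, stimulus_ids: Sequence[str], n_components: int | None = None) -> np.ndarray:
        n = self.n_components_kept if n_components is None else n_components
        if n > self.n_components_kept:
            raise ValueError("requested more components than the model keeps")
        pos = {s: i for i, s in enumerate(self.stimulus_ids)}
        try:
            rows = [pos[s] for s in stimulus_ids]
        except KeyError as exc:
            raise KeyError(f"stimulus not in PCA model: {exc.args[0]}") from None
        return self.scores[rows, :n]


@dataclass
class GenesetClassifier:
    """Per-gene-set two-class pooled-diagonal Gaussian models.

    Arrays are stacked over gene sets.  ``degenerate`` marks gene sets whose
    training labels contain a single class; their posterior is the empirical
    prior (0 or 1).
    """

    mean_on: np.ndarray  # (n_genesets, n_components)
    mean_off: np.ndarray
    pooled_var: np.ndarray  # (n_genesets, n_components) diagonal; or
    pooled_cov: np.ndarray | None  # (n_genesets, n_components, n_components) if full
    prior_on: np.ndarray  # (n_genesets,)
    degenerate: np.ndarray  # (n_genesets,) bool
    geneset_ids: list[str]
    n_components: int
    covariance: str = "diagonal"


@dataclass
class PredictionMatrix:
    """Posterior on-probabilities per gene set and test stimulus."""

    p_on: pd.DataFrame  # gene set x stimulus, values in [0, 1]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.p_on.to_numpy(dtype=float)
        if np.isnan(v).any() or (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("posteriors must lie in [0, 1]")


def fit_pca(rat_nes_combined, n_components: int) -> PCAModel:
    """PCA of the combined rat NES matrix, stimuli as samples.

    Accepts a :class:`GeneSetScoreMatrix` or a gene set x stimulus DataFrame.
    Columns (stimuli) are the observations; each gene-set row is mean-centred
    over all stimuli and no variance scaling is applied.  Loadings signs are
    fixed so each component's largest-magnitude loading is positive.
    """
    nes = rat_nes_combined.nes if isinstance(rat_nes_combined, GeneSetScoreMatrix) else rat_nes_combined
    X = nes.to_numpy(dtype=float).T  # (stimuli, genesets)
    n_stim, n_sets = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > n_stim:
        raise ValueError("n_components cannot exceed the number of stimuli")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(len(s)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    loadings = Vt[:n_components].T
    scores = U[:, :n_components] * s[:n_components]
    variances = s[:n_components] ** 2 / max(n_stim - 1, 1)
    return PCAModel(
        loadings=loadings,
        scores=scores,
        component_variances=variances,
        center=center,
        n_components_kept=n_components,
        geneset_ids=list(nes.index),
        stimulus_ids=list(nes.columns),
    )


def _fit_pooled_gaussian(
    X: np.ndarray, Y: np.ndarray, geneset_ids: list[str], covariance: str
) -> GenesetClassifier:
    """Vectorized per-gene-set fit.  X: (n, N) scores; Y: (G, n) bool labels."""
    n, N = X.shape
    Yf = Y.astype(float)
    n_on = Yf.sum(axis=1)
    n_off = n - n_on
    degenerate = (n_on == 0) | (n_off == 0)
    prior_on = n_on / n

    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = (Yf @ X) / n_on[:, None]
        mu0 = ((1 - Yf) @ X) / n_off[:, None]
    mu1[n_on == 0] = 0.0
    mu0[n_off == 0] = 0.0

    pooled_cov = None
    if covariance == "diagonal":
        sq = X**2
        ss = (Yf @ sq) - n_on[:, None] * mu1**2 + ((1 - Yf) @ sq) - n_off[:, None] * mu0**2
        dof = max(n - 2, 1)
        var = ss / dof
        floor = VARIANCE_FLOOR_FACTOR * max(float(np.nanmean(var[var > 0])) if (var > 0).any() else 1.0, 1e-300)
        var = np.maximum(var, floor)
        pooled_var = var
    elif covariance == "full":
        G = Y.shape[0]
        pooled_cov = np.empty((G, N, N))
        dof = max(n - 2, 1)
        for g in range(G):
            resid = X - np.where(Y[g][:, None], mu1[g], mu0[g])
            C = resid.T @ resid / dof
            # regularize toward the diagonal to keep it invertible
            C += np.eye(N) * (VARIANCE_FLOOR_FACTOR * max(np.trace(C) / N, 1e-300) + 1e-12)
            pooled_cov[g] = C
        pooled_var = np.stack([np.diag(pooled_cov[g]) for g in range(G)])
    else:
        raise ValueError("covariance must be 'diagonal' or 'full'")

    return GenesetClassifier(
        mean_on=mu1,
        mean_off=mu0,
        pooled_var=pooled_var,
        pooled_cov=pooled_cov,
        prior_on=prior_on,
        degenerate=degenerate,
        geneset_ids=geneset_ids,
        n_components=N,
        covariance=covariance,
    )


def train_genesets_classifier(
    pca: PCAModel,
    train_stimulus_ids: Sequence[str],
    human_labels: ActivationMatrix,
    n_components: int | None = None,
    covariance: str = "diagonal",
) -> GenesetClassifier:
    """Fit the per-gene-set two-class Gaussian model on training scores.

    Class means come from the N leading score coordinates of the training
    stimuli; the variance estimate is pooled across both classes, per
    dimension (diagonal) or full; priors are the empirical class frequencies.
    """
    N = pca.n_components_kept if n_components is None else n_components
    X = pca.scores_for(train_stimulus_ids, N)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 training stimuli")
    missing = [s for s in train_stimulus_ids if s not in set(human_labels.stimulus_ids)]
    if missing:
        raise KeyError(f"labels missing for training stimuli: {missing[:10]}")
    Y = human_labels.on[list(train_stimulus_ids)].to_numpy(dtype=bool)
    return _fit_pooled_gaussian(X, Y, list(human_labels.item_ids), covariance)


def predict_posteriors(clf: GenesetClassifier, X: np.ndarray) -> np.ndarray:
    """Posterior on-probability for each gene set at each score row of X.

    Returns a (n_genesets, n_points) array.  Degenerate gene sets emit their
    prior (0 or 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != clf.n_components:
        raise ValueError("score dimensionality does not match the classifier")
    G = len(clf.geneset_ids)
    T = X.shape[0]

    if clf.covariance == "diagonal":
        inv = 1.0 / clf.pooled_var  # (G, N)
        d1 = X[None, :, :] - clf.mean_on[:, None, :]
        d0 = X[None, :, :] - clf.mean_off[:, None, :]
        q1 = np.einsum("gtn,gn->gt", d1**2, inv)
        q0 = np.einsum("gtn,gn->gt", d0**2, inv)
    else:
        q1 = np.empty((G, T))
        q0 = np.empty((G, T))
        for g in range(G):
            Ci = np.linalg.inv(clf.pooled_cov[g])
            d1 = X - clf.mean_on[g]
            d0 = X - clf.mean_off[g]
            q1[g] = np.einsum("tn,nm,tm->t", d1, Ci, d1)
            q0[g] = np.einsum("tn,nm,tm->t", d0, Ci, d0)

    # shared covariance cancels the normalizing constant between classes
    with np.errstate(divide="ignore"):
        log_odds = (
            np.log(clf.prior_on)[:, None]
            - np.log(1.0 - clf.prior_on)[:, None]
            - 0.5 * (q1 - q0)
        )
    p_on = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
    deg = clf.degenerate
    p_on[deg] = np.round(clf.prior_on[deg])[:, None]
    return p_on


def predict_loo_ensemble(
    pca: PCAModel,
    human_labels: ActivationMatrix,
    test_stimulus_ids: Sequence[str],
    n_components: int | None = None,
    covariance: str = "diagonal",
    train_stimulus_ids: Sequence[str] | None = None,
) -> PredictionMatrix:
    """Average the posteriors of all leave-one-training-stimulus-out models.

    Each fold drops one training stimulus, refits every gene set's classifier
    on the rest and evaluates posteriors on all test stimuli; the prediction
    is the arithmetic mean over folds.  Folds whose labels collapse to one
    class contribute their prior (0 or 1).
    """
    train = list(train_stimulus_ids) if train_stimulus_ids is not None else list(
        human_labels.stimulus_ids
    )
    if len(train) < 3:
        raise ValueError("need >= 3 training stimuli for leave-one-out ensembling")
    N = pca.n_components_kept if n_components is None else n_components
    X_test = pca.scores_for(test_stimulus_ids, N)
    acc = np.zeros((len(human_labels.item_ids), len(test_stimulus_ids)))
    for held_out in range(len(train)):
        fold = train[:held_out] + train[held_out + 1 :]
        clf = train_genesets_classifier(pca, fold, human_labels, N, covariance)
        acc += predict_posteriors(clf, X_test)
    p = np.clip(acc / len(train), 0.0, 1.0)
    df = pd.DataFrame(p, index=list(human_labels.item_ids), columns=list(test_stimulus_ids))
    return PredictionMatrix(
        p_on=df,
        provenance={
            "n_components": N,
            "n_folds": len(train),
            "covariance": covariance,
            "train_stimuli": train,
        },
    )


def _pearson_or_nan(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def select_n_components(
    rat_nes_combined,
    human_labels: ActivationMatrix,
    candidate_ns: Sequence[int],
    metric: str = "auroc",
    human_fdr: pd.DataFrame | None = None,
    covariance: str = "diagonal",
) -> tuple[int, pd.DataFrame]:
    """Pick the component count by internal leave-one-out on the training set.

    For each candidate N and each training stimulus, a single classifier is
    trained on the remaining training stimuli and used to predict the
    held-out one.  Pooled over gene sets and held-out stimuli, AUROC, Pearson
    (binary and, when FDR is supplied, continuous 1-FDR) and the Matthews
    correlation at the 0.5 cut are tabulated; the best N maximizes the
    designated metric.  Candidates on which the metric is undefined are
    skipped.
    """
    nes = rat_nes_combined.nes if isinstance(rat_nes_combined, GeneSetScoreMatrix) else rat_nes_combined
    train = list(human_labels.stimulus_ids)
    n_train = len(train)
    if not candidate_ns:
        raise ValueError("candidate_ns is empty")
    if max(candidate_ns) > n_train - 1:
        raise ValueError("candidate N must be <= n_train - 1")
    if metric not in ("auroc", "pearson_binary", "pearson_continuous", "mcc"):
        raise ValueError(f"unknown selection metric: {metric}")

    pca = fit_pca(nes, max(candidate_ns))
    labels = human_labels.on[train].to_numpy(dtype=bool)
    rows = []
    for N in candidate_ns:
        preds = np.zeros_like(labels, dtype=float)
        for held in range(n_train):
            fold = train[:held] + train[held + 1 :]
            clf = train_genesets_classifier(pca, fold, human_labels, N, covariance)
            X_h = pca.scores_for([train[held]], N)
            preds[:, held] = predict_posteriors(clf, X_h)[:, 0]
        y = labels.ravel()
        p = preds.ravel()
        row = {"n_components": N}
        row["auroc"] = float(roc_auc_score(y, p)) if (y.any() and not y.all()) and np.std(p) > 0 else float("nan")
        row["pearson_binary"] = _pearson_or_nan(p, y.astype(float))
        if human_fdr is not None:
            cont = (1.0 - human_fdr[train].to_numpy(dtype=float)).ravel()
            row["pearson_continuous"] = _pearson_or_nan(p, cont)
        else:
            row["pearson_continuous"] = float("nan")
        hard = p >= 0.5
        row["mcc"] = float(matthews_corrcoef(y, hard)) if np.std(hard) > 0 else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    usable = table.dropna(subset=[metric])
    if usable.empty:
        raise ValueError(f"metric {metric} undefined for every candidate N")
    best_n = int(usable.loc[usable[metric].idxmax(), "n_components"])
    return best_n, table
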